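"""Bounded composition decomposition of observed peaks."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycomark import (
    SODIUM,
    Composition,
    DecompositionBounds,
    annotate_peaklist,
    decompose,
    ion_mz,
)
from glycomark.fingerprint import builtin_profiles

BOUNDS = DecompositionBounds(max_hex=9, min_hexnac=2, max_hexnac=2, max_pent=3, max_dhex=1, max_methyl=3)


def test_major_peak_yields_both_isobars():
    result = decompose(1049.365, SODIUM, 1, tol=0.3, bounds=BOUNDS)
    assert Composition(hex=2, hexnac=2, pent=2, methyl=1) in result
    assert Composition(hex=2, hexnac=2, pent=1, dhex=1) in result


def test_sodiated_water_decomposes_to_empty_composition():
    free = DecompositionBounds(max_hex=2, min_hexnac=0, max_hexnac=2, max_pent=2, max_dhex=1, max_methyl=2)
    result = decompose(40.99978, SODIUM, 1, tol=0.001, bounds=free)
    assert [c.composition for c in result] == [Composition()]


def test_satellite_903_contains_me_free_pentose_composition():
    result = decompose(903.31, SODIUM, 1, tol=0.05, bounds=BOUNDS)
    assert Composition(hex=2, hexnac=2, pent=1) in result


def test_empty_lattice_is_empty_result_not_error():
    empty = DecompositionBounds(max_hex=0, min_hexnac=2, max_hexnac=2, max_pent=0, max_dhex=0, max_methyl=0)
    result = decompose(5000.0, bounds=empty, tol=0.1)
    assert len(result) == 0


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        decompose(-5.0)
    with pytest.raises(ValueError):
        decompose(1000.0, tol=0.0)
    with pytest.raises(ValueError):
        DecompositionBounds(max_hex=-1)


def small_compositions():
    def with_methyl(counts):
        h, n, p, d = counts
        return st.integers(0, min(3, 3 * (h + n + p + d))).map(
            lambda me: Composition(hex=h, hexnac=n, pent=p, dhex=d, methyl=me)
        )

    return st.tuples(
        st.integers(0, 3), st.integers(0, 3), st.integers(0, 3), st.integers(0, 1)
    ).flatmap(with_methyl)


@given(small_compositions())
def test_round_trip_recovers_generating_composition(c):
    bounds = DecompositionBounds(
        max_hex=3, min_hexnac=0, max_hexnac=3, max_pent=3, max_dhex=1, max_methyl=3
    )
    result = decompose(ion_mz(c, SODIUM, 1), SODIUM, 1, tol=1e-6, bounds=bounds)
    assert c in result


def _brute_force(mz, tol, maxima):
    """Independent nested-loop oracle with explicit mass constants."""
    hits = set()
    for h in range(maxima + 1):
        for n in range(maxima + 1):
            for p in range(maxima + 1):
                for d in range(maxima + 1):
                    for me in range(maxima + 1):
                        if me > 3 * (h + n + p + d):
                            continue
                        m = (
                            h * 162.05282
                            + n * 203.07937
                            + p * 132.04226
                            + d * 146.05791
                            + me * 14.01565
                            + 18.01056
                            + 22.98922
                        )
                        if abs(m - mz) <= tol:
                            hits.add((h, n, p, d, me))
    return hits


@pytest.mark.parametrize("mz", [579.2, 771.26, 903.31, 1049.365, 500.0])
def test_matches_brute_force_oracle_on_small_bounds(mz):
    bounds = DecompositionBounds(
        max_hex=3, min_hexnac=0, max_hexnac=3, max_pent=3, max_dhex=3, max_methyl=3
    )
    got = {c.composition.as_tuple() for c in decompose(mz, SODIUM, 1, tol=0.3, bounds=bounds)}
    assert got == _brute_force(mz, 0.3, 3)


def test_monotone_in_tolerance_and_bounds():
    tight = {c.composition for c in decompose(1049.4, tol=0.05, bounds=BOUNDS)}
    loose = {c.composition for c in decompose(1049.4, tol=0.3, bounds=BOUNDS)}
    assert tight <= loose
    wider = DecompositionBounds(max_hex=9, min_hexnac=0, max_hexnac=4, max_pent=4, max_dhex=2, max_methyl=4)
    widened = {c.composition for c in decompose(1049.4, tol=0.3, bounds=wider)}
    assert loose <= widened


def test_isobaric_pairs_cooccur():
    result = decompose(1049.365, SODIUM, 1, tol=0.3, bounds=BOUNDS)
    for cand in result:
        c = cand.composition
        if c.dhex >= 1 and c.pent + 1 <= BOUNDS.max_pent and c.methyl + 1 <= BOUNDS.max_methyl:
            assert (
                Composition(hex=c.hex, hexnac=c.hexnac, pent=c.pent + 1, dhex=c.dhex - 1, methyl=c.methyl + 1)
                in result
            )


def test_candidates_sorted_by_error_then_lexicographically():
    result = decompose(1049.365, tol=0.3, bounds=BOUNDS)
    keys = [(abs(c.error_mda), c.composition.as_tuple()) for c in result]
    assert keys == sorted(keys)


def test_annotate_reference_profile_recovers_table_codes():
    from glycomark import parse_oscode

    raa = next(p for p in builtin_profiles() if p.name == "Raa")
    annotated = annotate_peaklist(raa.as_peaklist(), tol=0.3)
    assert len(annotated) == len(raa.peaks)
    by_mz = {p.mz: p.code for p in raa.peaks}
    for (mz, _intensity), result in annotated:
        assert parse_oscode(by_mz[mz]) in result


def test_peak_below_any_glycan_gets_empty_candidates():
    annotated = annotate_peaklist([(100.0, 1.0)], tol=0.01)
    assert len(annotated) == 1
    assert len(annotated[0][1]) == 0
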