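"""Glycosidic fragment enumeration, annotation, and the exhaustive oracle."""

from itertools import combinations

import pytest

from glycomark import (
    MASSES,
    PROTON,
    SODIUM,
    annotate_spectrum,
    discriminating_fragments,
    enumerate_fragments,
    ion_mz,
    parse_structure,
    to_composition,
)
from conftest import random_topology


def _mz_of(fragments, ion_type, target, tol=5e-4):
    return [f for f in fragments if f.ion_type == ion_type and abs(f.mz - target) <= tol]


def test_pentosylated_chitobiose_y_ion(raa_free):
    # reducing-end fragment keeping both GlcNAc and the GlcNAc-linked arabinose
    frags = enumerate_fragments(raa_free, SODIUM, max_cleavages=1)
    hits = _mz_of(frags, "Y", 579.2008)
    assert hits and set(hits[0].residues) == {"GlcNAc", "Ara"}
    assert len(hits[0].residue_ids) == 3


def test_loss_of_reducing_glcnac_b_ion(raa_free):
    frags = enumerate_fragments(raa_free, SODIUM, max_cleavages=1)
    hits = _mz_of(frags, "B", 828.2744)
    assert hits and len(hits[0].residue_ids) == 5  # everything but the root


def test_nonreducing_half_b_and_c_ions(raa_free, now):
    # Hex2 Pent1 Me1: the methylated-mannose arm in one structure, the
    # methylxylosylated-mannose arm in the other — same masses in both.
    for t in (raa_free, now):
        frags = enumerate_fragments(t, SODIUM, max_cleavages=1)
        assert _mz_of(frags, "B", 493.1528)
        assert _mz_of(frags, "C", 511.1633)


def test_methylpentose_loss_only_from_xylose_structure(raa_free, now):
    frags_now = enumerate_fragments(now, SODIUM, max_cleavages=1)
    assert _mz_of(frags_now, "Y", 903.3064)
    frags_raa = enumerate_fragments(raa_free, SODIUM, max_cleavages=2)
    assert not any(abs(f.mz - 903.3064) < 0.05 for f in frags_raa)


def test_single_residue_has_no_b_ion():
    t = parse_structure("Manp(a1-r)")
    frags = enumerate_fragments(t, SODIUM, max_cleavages=1)
    assert frags == []  # no glycosidic bond, no fragment


def test_reduced_root_shifts_y_but_not_b(raa, raa_free):
    fr = enumerate_fragments(raa, SODIUM, 1)
    ff = enumerate_fragments(raa_free, SODIUM, 1)
    b_r = sorted(f.mz for f in fr if f.ion_type == "B")
    b_f = sorted(f.mz for f in ff if f.ion_type == "B")
    assert b_r == b_f
    y_r = sorted(f.mz for f in fr if f.ion_type == "Y")
    y_f = sorted(f.mz for f in ff if f.ion_type == "Y")
    assert all(a - b == pytest.approx(2.01565, abs=1e-9) for a, b in zip(y_r, y_f))


@pytest.mark.parametrize("fixture_name", ["raa_free", "now", "muxf3"])
def test_b_y_complementarity(fixture_name, request):
    t = request.getfixturevalue(fixture_name)
    precursor = ion_mz(to_composition(t), SODIUM, 1)
    frags = enumerate_fragments(t, SODIUM, max_cleavages=1)
    all_ids = set(range(len(t)))
    b_by_ids = {frozenset(f.residue_ids): f.mz for f in frags if f.ion_type == "B"}
    y_by_ids = {frozenset(f.residue_ids): f.mz for f in frags if f.ion_type == "Y"}
    assert b_by_ids
    for ids, b in b_by_ids.items():
        y = y_by_ids[frozenset(all_ids - ids)]
        assert b + y == pytest.approx(precursor + 22.98922, abs=1e-9)


@pytest.mark.parametrize("seed", range(15))
def test_c_minus_b_and_y_minus_z_are_water(seed):
    t = random_topology(seed)
    frags = enumerate_fragments(t, SODIUM, max_cleavages=2)
    by_key = {(f.ion_type, f.residue_ids): f.mz for f in frags}
    for (ion, ids), mz in by_key.items():
        if ion == "B":
            assert by_key[("C", ids)] - mz == pytest.approx(MASSES.water, abs=1e-9)
        if ion == "Z":
            assert by_key[("Y", ids)] - mz == pytest.approx(MASSES.water, abs=1e-9)


@pytest.mark.parametrize("n", [2, 3, 4, 5])
def test_linear_chain_single_cleavage_count(n):
    chain = "".join(f"Manp(a1-4)" for _ in range(n - 1)) + "Manp(a1-r)"
    frags = enumerate_fragments(parse_structure(chain), SODIUM, max_cleavages=1)
    assert len(frags) == 4 * (n - 1)


def _oracle_fragments(t, adduct, max_cleavages):
    """Exhaustive connected-subset enumeration, independent of the cut-set walk."""
    nodes = t.residues()
    n = len(nodes)
    ids = {id(r): i for i, r in enumerate(nodes)}
    edges = set()
    for r in nodes:
        for c in r.children:
            edges.add(frozenset((ids[id(r)], ids[id(c)])))
    out = set()
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            s = set(subset)
            # connectivity within the induced subgraph
            internal = [e for e in edges if e <= s]
            if size > 1:
                comp = {subset[0]}
                grown = True
                while grown:
                    grown = False
                    for e in internal:
                        a, b = tuple(e)
                        if (a in comp) != (b in comp):
                            comp |= {a, b}
                            grown = True
                if comp != s:
                    continue
            boundary = [e for e in edges if len(e & s) == 1]
            if not boundary or len(boundary) > max_cleavages:
                continue
            mass = sum(nodes[i].mass() for i in s) + adduct.mass_shift
            if 0 in s:  # contains root: reducing-side ion
                red = MASSES.alditol if t.reduced else 0.0
                out.add(("Y", tuple(sorted(s)), round(mass + MASSES.water + red, 6)))
                out.add(("Z", tuple(sorted(s)), round(mass + red, 6)))
            elif len(boundary) == 1:
                out.add(("B", tuple(sorted(s)), round(mass, 6)))
                out.add(("C", tuple(sorted(s)), round(mass + MASSES.water, 6)))
            else:
                out.add(("internal", tuple(sorted(s)), round(mass, 6)))
    return out


@pytest.mark.parametrize("seed", range(20))
@pytest.mark.parametrize("max_cleavages", [1, 2])
def test_enumeration_matches_exhaustive_oracle(seed, max_cleavages):
    t = random_topology(seed)
    got = {
        (f.ion_type, f.residue_ids, round(f.mz, 6))
        for f in enumerate_fragments(t, SODIUM, max_cleavages)
    }
    assert got == _oracle_fragments(t, SODIUM, max_cleavages)


def test_fixture_enumeration_matches_oracle(raa_free, now, muxf3):
    for t in (raa_free, now, muxf3):
        got = {
            (f.ion_type, f.residue_ids, round(f.mz, 6))
            for f in enumerate_fragments(t, SODIUM, 2)
        }
        assert got == _oracle_fragments(t, SODIUM, 2)


def test_annotate_classic_fragment_quartet(raa_free):
    ann = annotate_spectrum([(579.2, 1.0), (828.3, 1.0), (493.2, 1.0), (511.2, 1.0)], raa_free, tol=0.1)
    assert not ann.unassigned
    assigned_mzs = {a.peak[0] for a in ann.assignments}
    assert assigned_mzs == {579.2, 828.3, 493.2, 511.2}
    assert all(a.confidence == "high" for a in ann.assignments)


def test_annotate_methylpentose_loss_discriminates(raa_free, now):
    ann_now = annotate_spectrum([(903.3, 1.0)], now, tol=0.1)
    assert ann_now.assignments and not ann_now.unassigned
    ann_raa = annotate_spectrum([(903.3, 1.0)], raa_free, tol=0.1)
    assert ann_raa.unassigned == ((903.3, 1.0),)


def test_annotate_empty_peaklist(raa_free):
    ann = annotate_spectrum([], raa_free, tol=0.1)
    assert ann.assignments == () and ann.unassigned == ()


def test_proton_adduct_assignments_flagged_low_confidence(raa_free):
    frags = enumerate_fragments(raa_free, PROTON, 1)
    ann = annotate_spectrum([(frags[0].mz, 1.0)], raa_free, PROTON, tol=0.01)
    assert ann.assignments and all(a.confidence == "low" for a in ann.assignments)


def test_shared_and_exclusive_fragments(raa_free, now):
    part = discriminating_fragments(raa_free, now, SODIUM, tol=0.05)
    assert any(abs(m - 579.2008) < 0.05 for m in part.shared)
    assert any(abs(m - 828.2744) < 0.05 for m in part.shared)
    # the methylpentose-loss Y ion is diagnostic for the xylose structure
    assert any(abs(m - 903.3064) < 0.05 for m in part.only_second)
    assert not any(abs(m - 903.3064) < 0.05 for m in part.only_first + part.shared)


def test_structure_vs_itself_has_no_exclusive_fragments(now):
    part = discriminating_fragments(now, now)
    assert part.only_first == () and part.only_second == ()
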