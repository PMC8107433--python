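"""Composition decomposition of observed peaks.

Given an observed m/z, enumerate every glycan composition on a bounded
integer lattice whose theoretical adduct m/z falls within tolerance — the
GlycoMod-style step that turns a MALDI peak list into "H N P me" codes.
Because dHex is exactly isobaric with Pent + CH2, ambiguous peaks always
surface both readings; resolving them is the job of MS/MS and linkage
analysis, not of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .glycomath import (
    MASSES,
    SODIUM,
    Adduct,
    Composition,
    ResidueMassTable,
    ion_mz,
)

__all__ = ["DecompositionBounds", "DecompositionResult", "decompose", "annotate_peaklist"]


@dataclass(frozen=True)
class DecompositionBounds:
    """Search-space bounds per residue class.

    Defaults reflect the glycans seen in methylated microalgal N-glycan
    profiles: oligomannosidic species up to Man9 (hex <= 9), exactly two
    core GlcNAc residues, at most 3 pentoses and 1 core fucose.
    """

    max_hex: int = 9
    min_hexnac: int = 2
    max_hexnac: int = 2
    max_pent: int = 3
    max_dhex: int = 1
    max_methyl: int = 9
    min_hex: int = 0
    min_pent: int = 0
    min_dhex: int = 0
    min_methyl: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.min_hex, self.max_hex),
            (self.min_hexnac, self.max_hexnac),
            (self.min_pent, self.max_pent),
            (self.min_dhex, self.max_dhex),
            (self.min_methyl, self.max_methyl),
        ):
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid bounds: need 0 <= min <= max, got {lo}..{hi}")


@dataclass(frozen=True)
class Candidate:
    composition: Composition
    mz: float
    error_mda: float  # theoretical - target, in mDa


@dataclass(frozen=True)
class DecompositionResult:
    target_mz: float
    tolerance: float
    candidates: tuple[Candidate, ...] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __contains__(self, c: Composition) -> bool:
        return any(cand.composition == c for cand in self.candidates)


def decompose(
    mz: float,
    adduct: Adduct = SODIUM,
    z: int = 1,
    tol: float = 0.3,
    bounds: DecompositionBounds | None = None,
    table: ResidueMassTable = MASSES,
) -> DecompositionResult:
    """Exhaustively enumerate compositions matching ``mz`` within ``tol`` Da.

    The lattice walk is plain nested iteration with an upper-mass prune;
    the search spaces of interest (a handful of residues per class) are tiny.
    Candidates are ordered by |error|, then lexicographically by
    (hex, hexnac, pent, dhex, methyl) so output is reproducible.
    """
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    b = bounds or DecompositionBounds()
    target_neutral = mz * z - z * adduct.mass_shift
    hits: list[Candidate] = []
    for h in range(b.min_hex, b.max_hex + 1):
        mass_h = h * table.hex
        if mass_h + table.water > target_neutral + tol:
            break
        for n in range(b.min_hexnac, b.max_hexnac + 1):
            mass_n = mass_h + n * table.hexnac
            if mass_n + table.water > target_neutral + tol:
                break
            for p in range(b.min_pent, b.max_pent + 1):
                mass_p = mass_n + p * table.pent
                if mass_p + table.water > target_neutral + tol:
                    break
                for d in range(b.min_dhex, b.max_dhex + 1):
                    mass_d = mass_p + d * table.dhex
                    if mass_d + table.water > target_neutral + tol:
                        break
                    for me in range(b.min_methyl, b.max_methyl + 1):
                        if me > 3 * (h + n + p + d):
                            break
                        comp = Composition(hex=h, hexnac=n, pent=p, dhex=d, methyl=me)
                        theo = ion_mz(comp, adduct, z, table)
                        err = theo - mz
                        if abs(err) <= tol:
                            hits.append(Candidate(comp, theo, err * 1000.0))
                        elif err > tol:
                            break
    hits.sort(key=lambda c: (abs(c.error_mda), c.composition.as_tuple()))
    return DecompositionResult(target_mz=mz, tolerance=tol, candidates=tuple(hits))


def annotate_peaklist(
    peaks,
    adduct: Adduct = SODIUM,
    z: int = 1,
    tol: float = 0.3,
    bounds: DecompositionBounds | None = None,
) -> list[tuple[tuple[float, float], DecompositionResult]]:
    """Decompose every (m/z, intensity) peak of a peak list, preserving order."""
    out = []
    for mz, intensity in peaks.pairs() if hasattr(peaks, "pairs") else peaks:
        out.append(((mz, intensity), decompose(mz, adduct, z, tol, bounds)))
    return out
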