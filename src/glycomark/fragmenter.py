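"""Glycosidic fragment enumeration and MS/MS peak annotation.

Fragments follow the Domon-Costello glycosidic types: B and C ions keep the
non-reducing side of a cleaved bond, Y and Z the reducing side (C = B + H2O,
Y = Z + H2O). Two simultaneous cleavages additionally produce internal
fragments (a B-type end on top, a Y-type end below) and doubly truncated
Y ions. Cross-ring A/X cleavages are out of model, as are fragment
intensities — only masses are predicted.

Proton-adduct assignments are flagged low-confidence: protonated glycan
ions are prone to gas-phase rearrangements, so a matching mass is weaker
evidence than for sodium adducts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .glycomath import MASSES, SODIUM, Adduct, exact_mass_sum
from .topology import GlycanTopology, Residue

__all__ = [
    "Fragment",
    "FragmentAssignment",
    "SpectrumAnnotation",
    "FragmentPartition",
    "enumerate_fragments",
    "annotate_spectrum",
    "discriminating_fragments",
]

ION_TYPES = ("B", "C", "Y", "Z", "internal")


@dataclass(frozen=True)
class Fragment:
    """A theoretical glycosidic fragment of one topology.

    ``residue_ids`` indexes residues in preorder of the source topology;
    ``residues`` carries their identities for display.
    """

    ion_type: str
    residue_ids: tuple[int, ...]
    residues: tuple[str, ...]
    cleavages: int
    adduct: Adduct
    mz: float

    @property
    def label(self) -> str:
        return f"{self.ion_type}{{{'-'.join(self.residues)}}}"


@dataclass(frozen=True)
class FragmentAssignment:
    peak: tuple[float, float]  # (m/z, intensity)
    fragment: Fragment
    error_mda: float
    confidence: str  # 'high' | 'low' (proton adducts rearrange in the gas phase)


@dataclass(frozen=True)
class SpectrumAnnotation:
    assignments: tuple[FragmentAssignment, ...]
    unassigned: tuple[tuple[float, float], ...]


def _index(t: GlycanTopology):
    """Preorder node list, parent map and subtree sets."""
    nodes: list[Residue] = []
    parent: list[int | None] = []

    def visit(r: Residue, par: int | None):
        idx = len(nodes)
        nodes.append(r)
        parent.append(par)
        for c in r.children:
            visit(c, idx)

    visit(t.root, None)
    n = len(nodes)
    subtree: list[set[int]] = [set() for _ in range(n)]

    def collect(idx: int) -> set[int]:
        s = {idx}
        child_ids = [i for i, p in enumerate(parent) if p == idx]
        for ci in child_ids:
            s |= collect(ci)
        subtree[idx] = s
        return s

    collect(0)
    return nodes, parent, subtree


def _subset_terms(ids, nodes, table=MASSES) -> list[float]:
    terms: list[float] = []
    for i in ids:
        terms.extend(nodes[i].mass_terms(table))
    return terms


def enumerate_fragments(
    t: GlycanTopology,
    adduct: Adduct = SODIUM,
    max_cleavages: int = 2,
    table=MASSES,
) -> list[Fragment]:
    """All distinct fragments from cutting at most ``max_cleavages`` bonds.

    Masses (singly charged): B = residue sum + adduct; C = B + water;
    Y = residue sum + water + adduct (+ alditol increment when the topology
    is reduced); Z = Y - water; internal = residue sum + adduct. Fragments
    with identical residue subset and ion type are reported once, with the
    minimal cleavage count.
    """
    if max_cleavages not in (1, 2):
        raise ValueError(f"max_cleavages must be 1 or 2, got {max_cleavages}")
    nodes, parent, subtree = _index(t)
    n = len(nodes)
    all_ids = frozenset(range(n))
    shift = adduct.mass_shift
    water = table.water
    red = table.alditol if t.reduced else 0.0

    seen: dict[tuple[str, frozenset[int]], Fragment] = {}

    def emit(ion_type: str, ids: frozenset[int], cleavages: int):
        if not ids:
            return
        key = (ion_type, ids)
        if key in seen:
            return
        terms = _subset_terms(ids, nodes, table) + [shift]
        if ion_type in ("C", "Y"):
            terms.append(water)
        if ion_type in ("Y", "Z") and red:
            terms.append(red)
        mz = exact_mass_sum(terms)  # order-independent, isobar-exact
        ordered = tuple(sorted(ids))
        seen[key] = Fragment(
            ion_type=ion_type,
            residue_ids=ordered,
            residues=tuple(nodes[i].identity for i in ordered),
            cleavages=cleavages,
            adduct=adduct,
            mz=mz,
        )

    edges = [i for i in range(n) if parent[i] is not None]
    for c in edges:
        sub = frozenset(subtree[c])
        emit("B", sub, 1)
        emit("C", sub, 1)
        rest = all_ids - sub
        emit("Y", rest, 1)
        emit("Z", rest, 1)
    if max_cleavages == 2:
        for i, c1 in enumerate(edges):
            for c2 in edges[i + 1 :]:
                s1, s2 = subtree[c1], subtree[c2]
                if c2 in s1:
                    emit("internal", frozenset(s1 - s2), 2)
                elif c1 in s2:
                    emit("internal", frozenset(s2 - s1), 2)
                else:
                    emit("Y", all_ids - s1 - s2, 2)
                    emit("Z", all_ids - s1 - s2, 2)
    return sorted(seen.values(), key=lambda f: (f.mz, f.ion_type, f.residue_ids))


def annotate_spectrum(
    peaks,
    t: GlycanTopology,
    adduct: Adduct = SODIUM,
    tol: float = 0.3,
    max_cleavages: int = 2,
) -> SpectrumAnnotation:
    """Match every observed peak against the theoretical fragment list.

    Each peak is paired with *all* fragments within ``tol`` Da; peaks with
    no match are reported separately. Ordering: observed m/z, then |error|.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    frags = enumerate_fragments(t, adduct, max_cleavages)
    confidence = "low" if adduct.label == "proton" else "high"
    assignments: list[FragmentAssignment] = []
    unassigned: list[tuple[float, float]] = []
    pairs = peaks.pairs() if hasattr(peaks, "pairs") else list(peaks)
    for mz, intensity in pairs:
        matches = [f for f in frags if abs(f.mz - mz) <= tol]
        if not matches:
            unassigned.append((mz, intensity))
            continue
        matches.sort(key=lambda f: (abs(f.mz - mz), f.ion_type, f.residue_ids))
        for f in matches:
            assignments.append(
                FragmentAssignment(
                    peak=(mz, intensity),
                    fragment=f,
                    error_mda=(f.mz - mz) * 1000.0,
                    confidence=confidence,
                )
            )
    assignments.sort(key=lambda a: (a.peak[0], abs(a.error_mda)))
    return SpectrumAnnotation(tuple(assignments), tuple(unassigned))


@dataclass(frozen=True)
class FragmentPartition:
    only_first: tuple[float, ...]
    only_second: tuple[float, ...]
    shared: tuple[float, ...]


def discriminating_fragments(
    t1: GlycanTopology,
    t2: GlycanTopology,
    adduct: Adduct = SODIUM,
    tol: float = 0.05,
    max_cleavages: int = 2,
) -> FragmentPartition:
    """Partition theoretical fragment masses into exclusive and shared sets.

    Masses within ``tol`` of each other across the two fragment lists are
    considered the same ion; the shared set reports the mass from ``t1``.
    Exclusive masses are the structure-diagnostic ions.
    """
    m1 = sorted({round(f.mz, 6) for f in enumerate_fragments(t1, adduct, max_cleavages)})
    m2 = sorted({round(f.mz, 6) for f in enumerate_fragments(t2, adduct, max_cleavages)})
    shared, only1 = [], []
    matched2: set[float] = set()
    for a in m1:
        hit = next((b for b in m2 if abs(a - b) <= tol), None)
        if hit is None:
            only1.append(a)
        else:
            shared.append(a)
            matched2.add(hit)
    only2 = [b for b in m2 if b not in matched2 and not any(abs(a - b) <= tol for a in m1)]
    return FragmentPartition(tuple(only1), tuple(only2), tuple(shared))
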