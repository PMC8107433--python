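"""Prediction of methylation (linkage) analysis outcomes.

Permethylation followed by hydrolysis, reduction and acetylation converts
each residue of a glycan into a partially methylated alditol acetate (PMAA)
whose acetylation pattern marks exactly the carbons that carried glycosidic
bonds (plus the ring oxygen). The GC-MS readout therefore reports, per
residue, its set of substitution positions — "terminal" for leaves,
"4-substituted", "3,4-di-substituted", and so on. Natural O-methyl groups
survive as such and are distinguishable from permethylation-introduced ones
when deuterated iodomethane is used, so they appear in the descriptor label
(e.g. "terminal 3-O-methyl xylose").

This module predicts that outcome from a topology and compares it, as a
label-count multiset, against an observed PMAA table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .topology import GlycanTopology

__all__ = [
    "PMAADescriptor",
    "PMAAComparison",
    "predict_pmaa",
    "compare_pmaa",
    "builtin_linkage_tables",
]

_SUGAR_NAME = {
    "Man": "mannose",
    "Glc": "glucose",
    "Hex": "hexose",
    "GlcNAc": "GlcNAc",
    "Ara": "arabinose",
    "Xyl": "xylose",
    "Fuc": "fucose",
}

_MULTI = {2: "di-", 3: "tri-", 4: "tetra-"}


@dataclass(frozen=True, order=True)
class PMAADescriptor:
    """Per-residue linkage-analysis outcome.

    ``substitutions``: carbons bearing child glycosidic bonds (sorted; the
    anomeric attachment to the residue's own parent does not count).
    ``methyls``: natural O-methyl positions (disjoint from substitutions by
    construction of the topology).
    """

    sugar: str
    substitutions: tuple[int, ...] = ()
    methyls: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if set(self.substitutions) & set(self.methyls):
            raise ValueError("substitution and O-methyl positions must be disjoint")

    @property
    def label(self) -> str:
        """Canonical display label, string-comparable with printed PMAA tables."""
        if self.substitutions:
            pos = ",".join(str(p) for p in self.substitutions)
            multi = _MULTI.get(len(self.substitutions), "")
            head = f"{pos}-{multi}substituted"
        else:
            head = "Terminal"
        me = "".join(f"{p}-O-methyl " for p in self.methyls)
        return f"{head} {me}{_SUGAR_NAME.get(self.sugar, self.sugar)}"

    def __str__(self) -> str:
        return self.label


def predict_pmaa(t: GlycanTopology) -> Counter:
    """Multiset of :class:`PMAADescriptor`, one per residue of the topology.

    The ring form does not enter the label (GC-MS of the open-chain alditol
    acetates does not preserve it) and an alditol root reports as the plain
    sugar, matching how reduced preparations are tabulated.
    """
    out: Counter = Counter()
    for r in t.root.walk():
        out[
            PMAADescriptor(
                sugar=r.identity,
                substitutions=tuple(sorted(c.link_to_parent for c in r.children)),
                methyls=tuple(sorted(r.o_methyl)),
            )
        ] += 1
    return out


def _label_counter(items) -> Counter:
    """Normalize descriptors / labels / (label, count) pairs to a casefolded counter."""
    c: Counter = Counter()
    if isinstance(items, Counter):
        items = items.items()
    for entry in items:
        if isinstance(entry, tuple) and len(entry) == 2 and isinstance(entry[1], int):
            key, count = entry
        else:
            key, count = entry, 1
        label = key.label if isinstance(key, PMAADescriptor) else str(key)
        c[label.casefold()] += count
    return c


@dataclass(frozen=True)
class PMAAComparison:
    """Multiset comparison of predicted vs observed PMAA labels (counts included)."""

    matched: tuple[tuple[str, int], ...]
    missing: tuple[tuple[str, int], ...]  # observed but not predicted
    unexpected: tuple[tuple[str, int], ...]  # predicted but not observed

    @property
    def is_match(self) -> bool:
        return not self.missing and not self.unexpected

    @property
    def n_missing(self) -> int:
        return sum(n for _, n in self.missing)

    @property
    def n_unexpected(self) -> int:
        return sum(n for _, n in self.unexpected)


def compare_pmaa(predicted, observed) -> PMAAComparison:
    """Two-sided multiset difference on (casefolded) labels.

    Accepts counters or iterables of descriptors, labels or (label, count)
    pairs on either side.
    """
    p = _label_counter(predicted)
    o = _label_counter(observed)
    matched = {k: min(p[k], o[k]) for k in p.keys() & o.keys()}
    missing = o - p
    unexpected = p - o
    return PMAAComparison(
        matched=tuple(sorted((k, v) for k, v in matched.items() if v)),
        missing=tuple(sorted(missing.items())),
        unexpected=tuple(sorted(unexpected.items())),
    )


#: Observed GC-MS linkage tables for the two major os2221 glycans:
#: (label, retention time in min, molar estimate). Retention times are data
#: carried along for display; comparisons use labels and counts only.
_OBSERVED_TABLES = {
    "Raa": (
        ("Terminal arabinose", 8.82, 2),
        ("4-substituted 3-O-methyl mannose", 16.87, 1),
        ("3-substituted mannose", 17.16, 1),
        ("4-substituted GlcNAc", 27.41, 1),
        ("3,4-di-substituted GlcNAc", 30.70, 1),
    ),
    "Now": (
        ("Terminal xylose", 9.63, 1),
        ("Terminal 3-O-methyl xylose", 9.63, 1),
        ("Terminal mannose", 13.44, 1),
        ("2,6-di-substituted mannose", 21.19, 1),
        ("4-substituted GlcNAc", 27.41, 1),
        ("3,4-di-substituted GlcNAc", 30.70, 1),
    ),
}


def builtin_linkage_tables() -> dict[str, tuple[tuple[str, float, int], ...]]:
    """The reference observed PMAA tables for the "Raa" and "Now" glycans."""
    return dict(_OBSERVED_TABLES)


def observed_label_counts(name: str) -> Counter:
    rows = _OBSERVED_TABLES[name]
    return Counter({label: count for label, _rt, count in rows})
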