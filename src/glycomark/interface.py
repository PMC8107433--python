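"""Peak-list container, delimited-text I/O and the umbrella report.

Every mass-spectrometric input to this workflow is a short peak list, so
the interchange format is deliberately plain: delimited text (tab or comma),
two or more columns (m/z, intensity), ``#`` comment lines, optional header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

from . import __version__ as _version
from .decomposer import DecompositionBounds, annotate_peaklist
from .fragmenter import annotate_spectrum
from .glycomath import SODIUM, Adduct, format_composition
from .pmaa import predict_pmaa
from .topology import GlycanTopology, format_structure, to_composition

__all__ = ["PeakList", "PeakListFormatError", "read_peaklist", "write_peaklist", "run_report", "render_report"]


class PeakListFormatError(ValueError):
    """A peak-list file had malformed rows; the message lists line numbers."""


@dataclass(frozen=True)
class PeakList:
    """An observed spectrum: sorted (m/z, intensity) pairs plus metadata."""

    mz: tuple[float, ...]
    intensity: tuple[float, ...]
    sample_id: str = ""
    mode: str = "MALDI-positive"
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("m/z and intensity arrays differ in length")
        pairs = sorted(zip(self.mz, self.intensity))
        object.__setattr__(self, "mz", tuple(m for m, _ in pairs))
        object.__setattr__(self, "intensity", tuple(i for _, i in pairs))
        for m in self.mz:
            if m <= 0:
                raise ValueError(f"non-positive m/z {m}")
        for a, b in zip(self.mz, self.mz[1:]):
            if a == b:
                raise ValueError(f"duplicate m/z {a}; peak lists must be strictly increasing")
        for i in self.intensity:
            if i < 0:
                raise ValueError(f"negative intensity {i}")

    @classmethod
    def from_pairs(cls, pairs, **kw) -> "PeakList":
        pairs = list(pairs)
        return cls(mz=tuple(p[0] for p in pairs), intensity=tuple(p[1] for p in pairs), **kw)

    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.mz, self.intensity))

    def __len__(self) -> int:
        return len(self.mz)

    def base_peak(self) -> tuple[float, float]:
        i = max(range(len(self.mz)), key=lambda k: self.intensity[k])
        return self.mz[i], self.intensity[i]

    def rescaled(self, factor: float) -> "PeakList":
        return replace(self, intensity=tuple(i * factor for i in self.intensity))


def read_peaklist(path) -> PeakList:
    """Read a delimited peak list; '#' comments and one optional header allowed.

    Malformed data rows abort the read with a :class:`PeakListFormatError`
    naming every offending line number.
    """
    p = Path(path)
    try:
        text = p.read_text()
    except OSError as exc:
        raise PeakListFormatError(f"cannot read {p}: {exc}") from exc
    pairs: list[tuple[float, float]] = []
    bad: list[str] = []
    header_allowed = True
    metadata: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                metadata[k.strip()] = v.strip()
            continue
        fields = [f for f in line.replace(",", "\t").split("\t") if f.strip()] or line.split()
        if len(fields) == 1:
            fields = line.split()
        try:
            mz = float(fields[0])
            intensity = float(fields[1]) if len(fields) > 1 else 1.0
        except (ValueError, IndexError):
            if header_allowed:
                header_allowed = False  # first non-numeric row is a header
                continue
            bad.append(f"line {lineno}: {raw!r}")
            continue
        header_allowed = False
        pairs.append((mz, intensity))
    if bad:
        raise PeakListFormatError(f"malformed rows in {p}: " + "; ".join(bad))
    return PeakList.from_pairs(pairs, sample_id=p.stem, metadata=metadata)


def write_peaklist(peaks: PeakList, path) -> None:
    """Write tab-delimited with a header; m/z printed with 4 decimals."""
    p = Path(path)
    lines = [f"# sample_id = {peaks.sample_id}", f"# mode = {peaks.mode}"]
    for k, v in peaks.metadata.items():
        lines.append(f"# {k} = {v}")
    lines.append("mz\tintensity")
    for mz, intensity in peaks.pairs():
        lines.append(f"{mz:.4f}\t{intensity:.6g}")
    p.write_text("\n".join(lines) + "\n")


def run_report(
    peaks: PeakList,
    profiles=None,
    structure: GlycanTopology | None = None,
    adduct: Adduct = SODIUM,
    tol: float = 0.3,
    bounds: DecompositionBounds | None = None,
    max_cleavages: int = 2,
) -> dict:
    """The full inference chain on one peak list, as a JSON-serializable dict.

    Stages: per-peak composition candidates; glyco-group classification when
    profiles are given (skipped with a warning otherwise); fragment
    annotation and PMAA prediction when a candidate structure is supplied.
    """
    from .fingerprint import classify  # local import: fingerprint imports PeakList

    report: dict = {
        "tool": "glycomark",
        "version": _version,
        "sample": peaks.sample_id,
        "mode": peaks.mode,
        "n_peaks": len(peaks),
        "config": {
            "adduct": adduct.label,
            "tol": tol,
            "max_cleavages": max_cleavages,
        },
        "warnings": [],
    }
    annotated = annotate_peaklist(peaks, adduct=adduct, tol=tol, bounds=bounds)
    report["peaks"] = [
        {
            "mz": round(mz, 4),
            "intensity": intensity,
            "candidates": [
                {
                    "code": format_composition(c.composition),
                    "theoretical_mz": round(c.mz, 4),
                    "error_mda": round(c.error_mda, 2),
                }
                for c in result
            ],
        }
        for (mz, intensity), result in annotated
    ]
    if profiles:
        cls = classify(peaks, profiles, tol=tol)
        report["classification"] = {
            "best": cls.best,
            "margin": round(cls.margin, 6),
            "scores": {name: round(score, 6) for name, score in cls.scores},
            "matched_peaks": dict(cls.matched_counts),
        }
    else:
        report["classification"] = None
        report["warnings"].append("no reference profiles supplied; classification skipped")
    if structure is not None:
        ann = annotate_spectrum(peaks, structure, adduct=adduct, tol=tol, max_cleavages=max_cleavages)
        report["structure"] = format_structure(structure)
        report["structure_composition"] = format_composition(to_composition(structure))
        report["fragment_assignments"] = [
            {
                "observed_mz": round(a.peak[0], 4),
                "ion_type": a.fragment.ion_type,
                "residues": list(a.fragment.residues),
                "theoretical_mz": round(a.fragment.mz, 4),
                "error_mda": round(a.error_mda, 2),
                "confidence": a.confidence,
            }
            for a in ann.assignments
        ]
        report["unassigned_peaks"] = [round(mz, 4) for mz, _ in ann.unassigned]
        report["pmaa"] = sorted(
            f"{d.label} x{count}" for d, count in predict_pmaa(structure).items()
        )
    else:
        report["structure"] = None
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of :func:`run_report` output."""
    lines = [
        f"glycomark {report['version']} report — sample {report['sample'] or '<unnamed>'}",
        f"{report['n_peaks']} peaks, {report['mode']}, adduct {report['config']['adduct']}, "
        f"tol ±{report['config']['tol']} Da",
        "",
        "Peak annotation:",
    ]
    for peak in report["peaks"]:
        cands = ", ".join(
            f"{c['code']} ({c['theoretical_mz']:.4f}, {c['error_mda']:+.1f} mDa)"
            for c in peak["candidates"]
        )
        lines.append(f"  {peak['mz']:9.4f}  {cands or '—'}")
    cls = report.get("classification")
    if cls:
        lines += ["", f"Glyco group: {cls['best']} (margin {cls['margin']:.4f})"]
        for name, score in cls["scores"].items():
            lines.append(f"  {name}: similarity {score:.4f}, {cls['matched_peaks'].get(name, 0)} matched peaks")
    if report.get("structure"):
        lines += ["", f"Candidate structure: {report['structure']}"]
        lines.append(f"  composition {report['structure_composition']}")
        for a in report.get("fragment_assignments", []):
            lines.append(
                f"  {a['observed_mz']:9.4f}  {a['ion_type']:>8s} {'-'.join(a['residues'])}"
                f"  theo {a['theoretical_mz']:.4f} ({a['error_mda']:+.1f} mDa)"
            )
        if report.get("unassigned_peaks"):
            lines.append("  unassigned: " + ", ".join(f"{m:.4f}" for m in report["unassigned_peaks"]))
        lines.append("  PMAA: " + "; ".join(report.get("pmaa", [])))
    for w in report.get("warnings", []):
        lines.append(f"warning: {w}")
    return "\n".join(lines)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
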