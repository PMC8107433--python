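"""Seeded generators for MALDI-style peak lists and MS/MS spectra.

The generators emulate the statistical structure the downstream analysis
assumes about reflector MALDI-TOF data of small N-glycans:

* mass error — additive Gaussian per peak (the printed values of the
  dominating ion scatter by a few hundredths of a Da around theory);
* abundance noise — multiplicative log-normal (keeps intensities positive);
* chemical noise — a handful of uniform-random peaks across the displayed
  spectral window with small abundance;
* MS/MS detection — Bernoulli thinning of the theoretical fragment list.

Everything is driven by :class:`numpy.random.default_rng` under an integer
seed, so identical seeds give identical spectra on any platform. Isotope
envelopes, detector saturation and baseline are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fragmenter import enumerate_fragments
from .glycomath import SODIUM, Adduct
from .interface import PeakList
from .fingerprint import GlycoGroupProfile
from .topology import GlycanTopology

__all__ = ["NoiseModel", "simulate_profile_spectrum", "simulate_msms"]


@dataclass(frozen=True)
class NoiseModel:
    """Noise settings for spectrum simulation.

    mz_sigma        Gaussian mass-error SD in Da (default 0.05).
    abundance_cv    coefficient of variation of the log-normal abundance
                    factor (default 0.3).
    n_noise_peaks   number of uniform-random chemical-noise peaks.
    noise_mz_range  window the noise peaks fall in, Da.
    noise_ceiling   noise-peak abundance upper bound, as fraction of base peak.
    seed            default RNG seed; simulate_* calls may override it.
    """

    mz_sigma: float = 0.05
    abundance_cv: float = 0.3
    n_noise_peaks: int = 5
    noise_mz_range: tuple[float, float] = (700.0, 1600.0)
    noise_ceiling: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_sigma < 0 or self.abundance_cv < 0:
            raise ValueError("noise scales must be non-negative")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be non-negative")
        lo, hi = self.noise_mz_range
        if not lo < hi:
            raise ValueError(f"empty noise m/z range {self.noise_mz_range}")


def _abundance_factors(rng, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    # mean-one log-normal
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def simulate_profile_spectrum(
    profile: GlycoGroupProfile,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
) -> PeakList:
    """One synthetic MALDI peak list drawn from a reference profile.

    Every profile peak appears once, with perturbed m/z and abundance;
    ``noise.n_noise_peaks`` random peaks are appended. Metadata records the
    generating group and seed.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    used_seed = noise.seed if seed is None else seed
    mzs = np.array([p.mz for p in profile.peaks])
    abunds = np.array([p.abundance for p in profile.peaks])
    mzs = mzs + rng.normal(0.0, noise.mz_sigma, size=len(mzs)) if noise.mz_sigma else mzs
    abunds = abunds * _abundance_factors(rng, len(abunds), noise.abundance_cv)
    lo, hi = noise.noise_mz_range
    noise_mz = rng.uniform(lo, hi, size=noise.n_noise_peaks)
    noise_ab = (1.0 - rng.random(noise.n_noise_peaks)) * noise.noise_ceiling
    return PeakList.from_pairs(
        list(zip(mzs.tolist(), abunds.tolist())) + list(zip(noise_mz.tolist(), noise_ab.tolist())),
        sample_id=f"synthetic-{profile.name}-{used_seed}",
        metadata={"group": profile.name, "seed": used_seed, "generator": "profile"},
    )


def simulate_msms(
    t: GlycanTopology,
    adduct: Adduct = SODIUM,
    noise: NoiseModel = NoiseModel(),
    detection_prob: float = 1.0,
    max_cleavages: int = 2,
    seed: int | None = None,
) -> PeakList:
    """A synthetic fragment spectrum: Bernoulli-thinned theoretical ions.

    Each distinct theoretical fragment mass is detected with probability
    ``detection_prob``; detected ions get Gaussian mass error and log-normal
    abundance around 1. ``detection_prob=0`` yields an empty spectrum.
    """
    if not 0.0 <= detection_prob <= 1.0:
        raise ValueError(f"detection_prob must be in [0, 1], got {detection_prob}")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    used_seed = noise.seed if seed is None else seed
    masses = sorted({round(f.mz, 9) for f in enumerate_fragments(t, adduct, max_cleavages)})
    keep = rng.random(len(masses)) < detection_prob
    kept = np.array([m for m, k in zip(masses, keep) if k])
    if noise.mz_sigma and len(kept):
        kept = kept + rng.normal(0.0, noise.mz_sigma, size=len(kept))
    abunds = _abundance_factors(rng, len(kept), noise.abundance_cv)
    return PeakList.from_pairs(
        list(zip(kept.tolist(), abunds.tolist())),
        sample_id=f"synthetic-msms-{t.name or 'glycan'}-{used_seed}",
        mode="MALDI-positive",
        metadata={
            "structure": t.name or "",
            "seed": used_seed,
            "detection_prob": detection_prob,
            "generator": "msms",
        },
    )
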