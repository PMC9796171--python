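"""Synthetic cortical cell-length profiles for testing the zonation
analysis without microscopy data.

Profiles have piecewise-linear mean structure emulating the measured
cohorts: a near-flat proliferation-domain regime (cells of a few µm), a
moderate-slope transition-domain regime and a steep elongation-zone
regime, with additive Gaussian measurement noise and between-root
variability of the segment parameters.  Three presets mirror the observed
phenotypes: ``wt_like`` (3 regimes), ``mto2_like`` (2 regimes: the RAM
behaves as a single TD-like domain) and ``exhausted`` (1 regime, no
meristem/elongation boundary left).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .msc import CellLengthProfile

#: Minimum reportable cell length (µm); noise is truncated here.
MIN_LENGTH_UM = 0.5


@dataclass(frozen=True)
class Segment:
    """One linear regime: cell count, start length (µm) and slope
    (µm per cell index)."""

    n_cells: int
    start_length: float
    slope: float

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("segments need at least 3 cells")
        if self.start_length <= 0:
            raise ValueError("start lengths must be > 0")


PRESETS: dict[str, tuple[Segment, ...]] = {
    # PD ~4.5 um nearly flat, TD rising moderately, EZ rising steeply
    "wt_like": (Segment(25, 4.5, 0.05), Segment(10, 6.0, 1.5), Segment(12, 21.0, 12.0)),
    # single TD-like RAM regime followed by the EZ
    "mto2_like": (Segment(12, 6.0, 1.5), Segment(10, 24.0, 12.0)),
    # one monotone regime: no detectable RAM/EZ boundary
    "exhausted": (Segment(20, 6.0, 6.0),),
}


@dataclass(frozen=True)
class ProfileSpec:
    """Specification of a synthetic profile or cohort."""

    preset: str = "wt_like"
    segments: tuple[Segment, ...] = ()
    noise_sd: float = 0.4
    between_root_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset != "custom" and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset == "custom" and not self.segments:
            raise ValueError("custom specs must provide segments")
        if self.noise_sd < 0 or self.between_root_cv < 0:
            raise ValueError("noise_sd and between_root_cv must be >= 0")

    def resolved_segments(self) -> tuple[Segment, ...]:
        return self.segments if self.preset == "custom" else PRESETS[self.preset]

    def true_breakpoints(self) -> tuple[int, ...]:
        """1-based last cell index of each regime except the final one."""
        counts = np.cumsum([s.n_cells for s in self.resolved_segments()])
        return tuple(int(c) for c in counts[:-1])


def generate_profile(spec: ProfileSpec, root_id: str = "synthetic-0") -> CellLengthProfile:
    """One profile: piecewise-linear mean plus truncated Gaussian noise.

    Deterministic per seed; with ``noise_sd == 0`` the output is exactly
    piecewise-linear.
    """
    rng = np.random.default_rng(spec.seed)
    return _draw_profile(spec.resolved_segments(), spec.noise_sd, rng, root_id)


def _draw_profile(segments: tuple[Segment, ...], noise_sd: float,
                  rng: np.random.Generator, root_id: str) -> CellLengthProfile:
    mean = np.concatenate([
        seg.start_length + seg.slope * np.arange(seg.n_cells)
        for seg in segments
    ])
    lengths = mean + rng.normal(0.0, noise_sd, size=mean.size) if noise_sd > 0 else mean
    return CellLengthProfile(root_id, np.maximum(lengths, MIN_LENGTH_UM))


def generate_cohort(spec: ProfileSpec, k: int, seed: int | None = None) -> list[CellLengthProfile]:
    """``k`` profiles with between-root jitter of the segment parameters.

    Start lengths, slopes and cell counts are each scaled by independent
    factors ``max(0.2, 1 + cv * z)`` per root.  Reproducible per seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cv = spec.between_root_cv
    profiles = []
    for i in range(k):
        segments = []
        for seg in spec.resolved_segments():
            js, jl, jn = np.maximum(0.2, 1.0 + cv * rng.standard_normal(3))
            segments.append(Segment(
                n_cells=max(3, int(round(seg.n_cells * jn))),
                start_length=seg.start_length * js,
                slope=seg.slope * jl,
            ))
        profiles.append(_draw_profile(tuple(segments), spec.noise_sd, rng,
                                      f"{spec.preset}-{i}"))
    return profiles


def generate_mixed_cohort(
    k: int,
    fractions: dict[str, float] | None = None,
    noise_sd: float = 0.4,
    between_root_cv: float = 0.1,
    seed: int = 0,
) -> list[CellLengthProfile]:
    """Cohort mixing presets in fixed proportions (default mirrors the
    observed mutant breakpoint-class split: 5% exhausted, 66% mto2-like,
    29% wt-like)."""
    if fractions is None:
        fractions = {"exhausted": 0.05, "mto2_like": 0.66, "wt_like": 0.29}
    counts = {name: int(round(frac * k)) for name, frac in fractions.items()}
    # rounding drift lands on the largest class
    largest = max(counts, key=lambda n: counts[n])
    counts[largest] += k - sum(counts.values())
    profiles = []
    for j, (name, n) in enumerate(sorted(counts.items())):
        if n == 0:
            continue
        spec = ProfileSpec(preset=name, noise_sd=noise_sd,
                           between_root_cv=between_root_cv, seed=seed + j)
        profiles.extend(generate_cohort(spec, n))
    return profiles
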