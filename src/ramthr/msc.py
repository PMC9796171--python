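"""Multiple-structural-change (MSC) zonation of cell-length profiles.

A cortical cell-length profile (ordered from the cell adjacent to the
quiescent centre shootward) is segmented into linear regimes by placing
``m`` breakpoints that minimize the total residual sum of squares of
per-segment ordinary least-squares lines (regressors: intercept and slope
over 1-based cell index).  Placement is globally optimal via dynamic
programming over admissible segment ends; the most parsimonious ``m`` is
chosen by the Bayesian Information Criterion.

Segments must contain at least ``h`` cells.  ``h`` derives from a
sample-level fraction ``f``: ``f`` is the smallest two-decimal value with
``f * n_s >= 3`` (``n_s`` the smallest profile in the sample) and
``h = f * n`` per root, constrained to ``3 <= h < n/2`` because a linear
fit needs more points than its two regressors and a segment cannot cover
half the profile.

Domain annotation follows the breakpoint count: with two breakpoints the
segments are PD, TD and EZ; with one breakpoint the whole RAM behaves as
a TD (TD then EZ); with none, no boundary exists and cells are left
undetermined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

UNDETERMINED = "undetermined"

#: Segment labels by breakpoint count.
DOMAIN_SEQUENCES = {2: ("PD", "TD", "EZ"), 1: ("TD", "EZ"), 0: (UNDETERMINED,)}


@dataclass(frozen=True)
class CellLengthProfile:
    """Ordered cortical cell lengths (µm); index 0 is the cell adjacent
    to the cortex/cortex-endodermis initial."""

    root_id: str
    lengths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        if self.lengths.ndim != 1 or self.lengths.size == 0:
            raise ValueError("lengths must be a non-empty 1-D sequence")
        if np.any(self.lengths <= 0):
            raise ValueError("all cell lengths must be > 0")

    @property
    def n(self) -> int:
        return int(self.lengths.size)


class InfeasibleSegmentation(ValueError):
    """Raised when no admissible segmentation exists."""


def compute_f(sample: list[CellLengthProfile]) -> float:
    """Sample-level minimal segment fraction.

    The smallest two-decimal ``f`` with ``f * n_s >= 3``, where ``n_s`` is
    the size of the smallest profile: ``ceil(300 / n_s) / 100``.  Requires
    ``n_s >= 7`` (otherwise no ``h`` with ``3 <= h < n/2`` exists).
    """
    if not sample:
        raise ValueError("empty sample")
    n_s = min(p.n for p in sample)
    if n_s < 7:
        raise InfeasibleSegmentation(
            f"smallest profile has {n_s} cells; need at least 7 for 3 <= h < n/2")
    return math.ceil(300 / n_s) / 100


def compute_h(f: float, n: int) -> int:
    """Per-root minimal segment size ``h = max(3, floor(f * n))``.

    Raises :class:`InfeasibleSegmentation` when ``h >= n / 2``.  Uses
    integer arithmetic on the two-decimal ``f`` to avoid float flooring
    artefacts.
    """
    if n < 1:
        raise ValueError("n must be positive")
    h = max(3, (int(round(f * 100)) * n) // 100)
    if not h < n / 2:
        raise InfeasibleSegmentation(
            f"h={h} violates h < n/2 for a profile of n={n} cells")
    return h


@dataclass(frozen=True)
class BreakpointModel:
    """Optimal segmented regression for a fixed breakpoint count.

    ``breakpoints`` are 1-based cell indices of the last cell of each of
    the first ``m`` segments.  ``fits`` holds (intercept, slope) per
    segment, with the slope in µm per cell index.
    """

    m: int
    breakpoints: tuple[int, ...]
    fits: tuple[tuple[float, float], ...]
    rss: float
    bic: float
    h: int
    n: int

    def segments(self) -> list[tuple[int, int]]:
        """1-based (first, last) cell index per segment."""
        bounds = (0,) + self.breakpoints + (self.n,)
        return [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]


class _SegmentCosts:
    """O(1) OLS residual sums for any contiguous segment, from prefix sums."""

    def __init__(self, y: np.ndarray):
        x = np.arange(1, y.size + 1, dtype=float)
        z = np.zeros(1)
        self.sx = np.concatenate([z, np.cumsum(x)])
        self.sy = np.concatenate([z, np.cumsum(y)])
        self.sxx = np.concatenate([z, np.cumsum(x * x)])
        self.sxy = np.concatenate([z, np.cumsum(x * y)])
        self.syy = np.concatenate([z, np.cumsum(y * y)])

    def fit(self, i: int, j: int) -> tuple[float, float, float]:
        """(intercept, slope, rss) of OLS on cells i..j (0-based, incl.)."""
        n = j - i + 1
        sx = self.sx[j + 1] - self.sx[i]
        sy = self.sy[j + 1] - self.sy[i]
        sxx = self.sxx[j + 1] - self.sxx[i]
        sxy = self.sxy[j + 1] - self.sxy[i]
        syy = self.syy[j + 1] - self.syy[i]
        vxx = sxx - sx * sx / n
        vxy = sxy - sx * sy / n
        vyy = syy - sy * sy / n
        slope = vxy / vxx if vxx > 0 else 0.0
        intercept = (sy - slope * sx) / n
        rss = max(vyy - slope * vxy, 0.0) if vxx > 0 else max(vyy, 0.0)
        return intercept, slope, rss

    def rss(self, i: int, j: int) -> float:
        return self.fit(i, j)[2]


def _bic(rss: float, n: int, m: int) -> float:
    """BIC with npar = 2(m+1) segment coefficients + m breakpoints + the
    error variance; -inf for an exact (zero-residual) fit."""
    if rss <= 1e-12 * max(n, 1):
        return -np.inf
    ll = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    npar = 2 * (m + 1) + m + 1
    return -2.0 * ll + npar * math.log(n)


def fit_breakpoints(profile: CellLengthProfile, m: int, h: int) -> BreakpointModel:
    """Globally optimal placement of ``m`` breakpoints (minimum total RSS
    of per-segment OLS lines, every segment >= ``h`` cells) by dynamic
    programming.  Deterministic; exact RSS ties resolve to the earliest
    admissible previous segment end."""
    n = profile.n
    if m < 0:
        raise ValueError("m must be >= 0")
    if h < 3:
        raise InfeasibleSegmentation("h must be >= 3")
    if (m + 1) * h > n:
        raise InfeasibleSegmentation(
            f"cannot place {m} breakpoints with h={h} in n={n} cells")
    costs = _SegmentCosts(profile.lengths)
    # dp[k][j]: min RSS for k+1 segments covering cells 0..j
    dp = np.full((m + 1, n), np.inf)
    back = np.full((m + 1, n), -1, dtype=int)
    for j in range(h - 1, n):
        dp[0, j] = costs.rss(0, j)
    for k in range(1, m + 1):
        for j in range((k + 1) * h - 1, n):
            for i in range(k * h - 1, j - h + 1):
                cand = dp[k - 1, i] + costs.rss(i + 1, j)
                if cand < dp[k, j]:
                    dp[k, j] = cand
                    back[k, j] = i
    rss = float(dp[m, n - 1])
    cuts: list[int] = []
    j = n - 1
    for k in range(m, 0, -1):
        i = int(back[k, j])
        cuts.append(i)
        j = i
    cuts.reverse()
    breakpoints = tuple(c + 1 for c in cuts)  # 1-based last index of segment
    bounds = [0, *[c + 1 for c in cuts], n]
    fits = tuple(costs.fit(bounds[i], bounds[i + 1] - 1)[:2]
                 for i in range(len(bounds) - 1))
    return BreakpointModel(m, breakpoints, fits, rss, _bic(rss, n, m), h, n)


def select_model(profile: CellLengthProfile, h: int, m_max: int = 2) -> BreakpointModel:
    """Fit m = 0..m_max (skipping infeasible m) and return the
    minimum-BIC model; exact BIC ties go to the smaller m (parsimony)."""
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    best: BreakpointModel | None = None
    for m in range(m_max + 1):
        try:
            model = fit_breakpoints(profile, m, h)
        except InfeasibleSegmentation:
            continue
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise InfeasibleSegmentation(
            f"no feasible breakpoint count up to {m_max} for n={profile.n}, h={h}")
    return best


@dataclass(frozen=True)
class DomainAnnotation:
    """Per-cell domain labels and per-domain summary statistics."""

    labels: tuple[str, ...]
    per_domain: dict[str, dict[str, float]]
    model: BreakpointModel


def annotate_domains(
    profile: CellLengthProfile,
    model: BreakpointModel,
    force_m: int | None = None,
) -> DomainAnnotation:
    """Label cells as PD/TD/EZ according to the fitted breakpoint count.

    ``force_m`` refits with a fixed breakpoint count (the wild-type mode
    applies a two-breakpoint model to every root).  With m = 0 all cells
    are undetermined and domain statistics are empty.
    """
    if force_m is not None and force_m != model.m:
        model = fit_breakpoints(profile, force_m, model.h)
    if model.m not in DOMAIN_SEQUENCES:
        raise ValueError(f"domain annotation is defined for m <= 2, got m={model.m}")
    names = DOMAIN_SEQUENCES[model.m]
    labels: list[str] = []
    per_domain: dict[str, dict[str, float]] = {}
    for name, (first, last) in zip(names, model.segments()):
        seg = profile.lengths[first - 1:last]
        labels.extend([name] * seg.size)
        if name != UNDETERMINED:
            per_domain[name] = {
                "n_cells": int(seg.size),
                "total_length_um": float(seg.sum()),
                "mean_length_um": float(seg.mean()),
            }
    return DomainAnnotation(tuple(labels), per_domain, model)


def classify_sample(
    sample: list[CellLengthProfile],
    genotype_mode: str = "auto",
    m_max: int = 2,
    f: float | None = None,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Analyze a cohort of profiles with a shared ``f``.

    Returns a per-root table (selected m, breakpoints, per-domain counts,
    total and mean lengths) and the cohort percentages of each breakpoint
    count.  ``genotype_mode='wt'`` forces the two-breakpoint model on
    every root; ``'mutant'``/``'auto'`` select m by BIC.
    """
    if genotype_mode not in ("auto", "wt", "mutant"):
        raise ValueError(f"unknown genotype_mode {genotype_mode!r}")
    f_val = f if f is not None else compute_f(sample)
    rows = []
    for profile in sample:
        h = compute_h(f_val, profile.n)
        model = select_model(profile, h, m_max=m_max)
        annotation = annotate_domains(
            profile, model, force_m=2 if genotype_mode == "wt" else None)
        model = annotation.model
        row: dict[str, object] = {
            "root_id": profile.root_id, "n": profile.n, "f": f_val, "h": h,
            "m": model.m, "breakpoints": ",".join(map(str, model.breakpoints)),
            "rss": model.rss, "bic": model.bic,
        }
        for name in ("PD", "TD", "EZ"):
            stats = annotation.per_domain.get(name)
            row[f"{name}_n_cells"] = stats["n_cells"] if stats else 0
            row[f"{name}_total_um"] = stats["total_length_um"] if stats else 0.0
            row[f"{name}_mean_um"] = stats["mean_length_um"] if stats else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = table["m"].value_counts()
    percentages = {m: 100.0 * counts.get(m, 0) / len(table)
                   for m in range(m_max + 1)}
    return table, percentages
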