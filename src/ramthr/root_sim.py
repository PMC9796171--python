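"""Lattice-based simulator of Thr-gated root growth.

The root is a column of cells per tissue file (epidermis, cortex,
endodermis, stele); each cell is a contiguous run of grid rows anchored at
the quiescent centre (QC).  Zones are positional and fixed in the
QC-anchored frame: proliferation domain (PD) and transition domain (TD)
form the root apical meristem (RAM), followed by the elongation zone (EZ)
and differentiated cells.

Rules per time step:

- QC cells neither grow nor divide.
- The stem (proximal) initial grows one grid row every
  ``stem_cycle_factor``-th step and divides asymmetrically: the rootward
  daughter remains a stem initial, the shootward daughter becomes a
  transit-amplifying (TA) cell with a capacity of five division cycles.
- RAM cells (TA and exhausted TA) grow one row per step up to twice their
  birth length (the cycle-completion size); a TA cell in the PD whose
  length has doubled divides into two halves, provided free Thr at its
  midpoint is at or above the division threshold theta and its capacity
  is not exhausted.
- Cells displaced past the RAM boundary elongate by ``ez_increment`` rows
  per step until they reach ``final_length`` and differentiate.

Free Thr is supplied by a steady-state profile from
:mod:`ramthr.thr_model`, evaluated at each cell midpoint mapped onto the
gradient axis (grid distance from the QC divided by the initial root
length, clamped to [0, 1]).  The simulator is deterministic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gradients import GeneExpressionGradient, default_gradients, expression_at
from .thr_model import (
    MUTANT,
    WT,
    Genotype,
    ThrModelParams,
    profile_along_root,
    steady_state_synthesis,
)

QC = "QC"
STEM = "stem_initial"
TA = "transit_amplifying"
TA_EXHAUSTED = "ta_exhausted"
ELONGATING = "elongating"
DIFFERENTIATED = "differentiated"

#: Tissue files, index order; cortex is the analysis file (cortical cell
#: lengths are what the zonation analysis measures).
FILE_NAMES = ("epidermis", "cortex", "endodermis", "stele")

TA_DIVISION_CAPACITY = 5

#: Fraction of the gradient axis occupied by the RAM.  Zone extents are
#: proportional to real seedling roots, so the expression gradients are
#: anchored to the RAM: the axis spans ~1/0.17 RAM lengths, matching the
#: default initial root (RAM 168 of 973 grid rows).  This keeps the
#: gradient-relative zone layout invariant across growth-parameter sweeps.
RAM_AXIS_FRACTION = 0.17

Domain = Literal["PD", "TD", "RAM", "EZ+DZ"]


@dataclass
class Cell:
    """One cell: a contiguous run of grid rows in a tissue file."""

    id: int
    file_index: int
    type: str
    grid_start: int
    length: int
    birth_length: int
    divisions_used: int = 0

    @property
    def midpoint(self) -> float:
        return self.grid_start + self.length / 2.0

    def can_divide(self) -> bool:
        """Capacity/type check only (geometry and Thr are checked by the
        stepper)."""
        if self.type == STEM:
            return True
        return self.type == TA and self.divisions_used < TA_DIVISION_CAPACITY


@dataclass(frozen=True)
class ZoneMap:
    """Fixed zone boundaries, grid distance from the QC anchor."""

    pd_end: int
    td_end: int
    ez_end: int

    def __post_init__(self) -> None:
        if not (0 < self.pd_end < self.td_end < self.ez_end):
            raise ValueError("zone boundaries must satisfy 0 < pd_end < td_end < ez_end")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``division_length_threshold`` is the birth length of meristematic
    cells (division occurs at twice this size); ``thr_division_threshold``
    (theta) defaults to half the wild-type steady-state Thr at the stem
    cell niche under default model parameters.
    """

    division_length_threshold: int = 4
    ram_growth_increment: int = 1
    ez_increment: int = 5
    final_length: int = 80
    stem_cycle_factor: int = 2
    thr_division_threshold: float | None = None
    genotype: Genotype = WT
    dt: float = 0.1
    t_max: float = 5.0
    n_files: int = 4
    analysis_file: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.division_length_threshold < 1 or self.ez_increment < 1:
            raise ValueError("growth parameters must be positive integers")
        if self.final_length <= 2 * self.division_length_threshold:
            raise ValueError("final_length must exceed the division size")
        if not 0 <= self.analysis_file < self.n_files:
            raise ValueError("analysis_file out of range")

    @property
    def theta(self) -> float:
        if self.thr_division_threshold is not None:
            return self.thr_division_threshold
        return default_thr_threshold()


@dataclass
class RootState:
    """Ordered cells per tissue file plus the zone map and axis scale."""

    files: list[list[Cell]]
    zone_map: ZoneMap
    position_scale: float
    step_count: int = 0
    _id_counter: "itertools.count" = field(default_factory=itertools.count)

    def new_id(self) -> int:
        return next(self._id_counter)

    def total_length(self, file_index: int = 0) -> int:
        return sum(c.length for c in self.files[file_index])


@dataclass
class Trajectory:
    """Recorded time course of one simulation."""

    genotype: Genotype
    times: np.ndarray
    total_length: np.ndarray
    n_cells: np.ndarray
    total_thr: np.ndarray
    snapshots: list[dict[str, np.ndarray]]
    final_state: RootState
    config: SimConfig

    def at_time(self, t: float) -> int:
        """Index of the recorded time closest to ``t``."""
        return int(np.argmin(np.abs(self.times - t)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "total_length": self.total_length,
            "n_cells": self.n_cells,
            "total_thr": self.total_thr,
            "genotype": self.genotype,
        })


def default_thr_threshold(fraction: float = 0.5) -> float:
    """Division threshold theta: ``fraction`` of the wild-type SCN
    steady-state Thr under default parameters and gradients."""
    g = default_gradients()
    scn = steady_state_synthesis(
        ThrModelParams(), expression_at(g["MTO2"], 0.0), expression_at(g["TSY2"], 0.0)
    )
    return fraction * scn


def make_thr_fn(
    params: ThrModelParams | None = None,
    gradients: dict[str, GeneExpressionGradient] | None = None,
    variant: str = "synthesis_only",
) -> Callable[[np.ndarray], np.ndarray]:
    """Build a vectorized position -> steady-state Thr function.

    Synthesis-only profiles are evaluated in closed form; extended
    profiles are precomputed on a fine grid and linearly interpolated.
    """
    params = params if params is not None else ThrModelParams()
    gradients = gradients if gradients is not None else default_gradients()
    if variant == "synthesis_only":
        def thr_fn(x: np.ndarray) -> np.ndarray:
            xa = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
            e_m = expression_at(gradients["MTO2"], xa)
            e_t = expression_at(gradients["TSY2"], xa)
            return np.atleast_1d(steady_state_synthesis(params, e_m, e_t))
        return thr_fn
    grid = np.linspace(0.0, 1.0, 257)
    prof = profile_along_root(params, gradients, grid, variant="extended")

    def thr_fn(x: np.ndarray) -> np.ndarray:
        xa = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        return np.interp(xa, grid, prof.thr)

    return thr_fn


def _initial_file(config: SimConfig, state_ids: "itertools.count",
                  file_index: int) -> list[Cell]:
    ld = config.division_length_threshold
    cells: list[Cell] = []

    def add(type_: str, length: int, birth: int) -> None:
        cells.append(Cell(next(state_ids), file_index, type_, 0, length, birth))

    add(QC, ld, ld)
    add(STEM, ld, ld)
    for _ in range(32):  # proliferation domain
        add(TA, ld, ld)
    for _ in range(8):  # transition domain
        add(TA, ld, ld)
    # graded elongation zone: 8 cells from the doubled meristematic size
    length = 2 * ld
    for _ in range(8):
        add(ELONGATING, length, ld)
        length += config.ez_increment
    # partially elongated tail up to the differentiated size
    while length < config.final_length:
        add(ELONGATING, length, ld)
        length += config.ez_increment
    for _ in range(2):
        add(DIFFERENTIATED, config.final_length, ld)
    _retile(cells)
    return cells


def _retile(cells: list[Cell]) -> None:
    """Recompute grid_start so cells tile the axis without gaps."""
    pos = 0
    for c in cells:
        c.grid_start = pos
        pos += c.length


def init_root(config: SimConfig) -> RootState:
    """Initial condition shared by both genotypes.

    Per file: one QC cell and one stem initial at birth length, 32 PD and
    8 TD transit-amplifying cells, 8 graded EZ cells, a partially
    elongated tail and two differentiated cells.  The zone map is derived
    from the same geometry so initial cells fall in their intended zones.
    """
    ld = config.division_length_threshold
    base = 2 * ld  # QC + stem initial
    pd_end = base + 32 * ld
    td_end = pd_end + 8 * ld
    ez_len = sum(2 * ld + k * config.ez_increment for k in range(8))
    zone = ZoneMap(pd_end=pd_end, td_end=td_end, ez_end=td_end + ez_len)
    counter = itertools.count()
    files = [_initial_file(config, counter, i) for i in range(config.n_files)]
    ram = [c for c in files[0] if c.type == TA and c.midpoint <= td_end]
    if len(ram) != 40:  # geometry is derived, so this should be impossible
        raise ValueError("zone map inconsistent with initial cell counts")
    return RootState(files=files, zone_map=zone,
                     position_scale=td_end / RAM_AXIS_FRACTION,
                     _id_counter=counter)


def step(
    state: RootState,
    config: SimConfig,
    thr_fn: Callable[[np.ndarray], np.ndarray],
) -> RootState:
    """Advance the root by one simulation step (in place)."""
    zone = state.zone_map
    theta = config.theta
    stem_grows = state.step_count % config.stem_cycle_factor == 0
    for cells in state.files:
        mids = np.array([c.midpoint for c in cells]) / state.position_scale
        thr = np.asarray(thr_fn(mids))
        new_cells: list[Cell] = []
        for c, thr_here in zip(cells, thr):
            cap = 2 * c.birth_length
            if c.type == QC:
                new_cells.append(c)
                continue
            if c.type == STEM:
                if stem_grows and c.length < cap:
                    c.length += config.ram_growth_increment
                if c.length >= cap and thr_here >= theta:
                    new_cells.extend(_divide(state, c, asymmetric=True))
                else:
                    new_cells.append(c)
                continue
            if c.type in (TA, TA_EXHAUSTED) and c.midpoint > zone.td_end:
                c.type = ELONGATING  # displaced out of the RAM
            if c.type in (TA, TA_EXHAUSTED):
                if c.length < cap:
                    c.length += config.ram_growth_increment
                in_pd = c.midpoint < zone.pd_end
                if (c.type == TA and in_pd and c.can_divide()
                        and c.length >= cap and thr_here >= theta):
                    new_cells.extend(_divide(state, c, asymmetric=False))
                else:
                    new_cells.append(c)
                continue
            if c.type == ELONGATING:
                c.length = min(c.length + config.ez_increment, config.final_length)
                if c.length >= config.final_length:
                    c.type = DIFFERENTIATED
            new_cells.append(c)
        _retile(new_cells)
        cells[:] = new_cells
    state.step_count += 1
    return state


def _divide(state: RootState, parent: Cell, asymmetric: bool) -> list[Cell]:
    """Split a cell in two; the rootward daughter gets any odd extra row."""
    shootward_len = parent.length // 2
    rootward_len = parent.length - shootward_len
    if asymmetric:
        rootward = Cell(state.new_id(), parent.file_index, STEM, 0,
                        rootward_len, rootward_len)
        shootward = Cell(state.new_id(), parent.file_index, TA, 0,
                         shootward_len, shootward_len, divisions_used=0)
    else:
        used = parent.divisions_used + 1
        kind = TA_EXHAUSTED if used >= TA_DIVISION_CAPACITY else TA
        rootward = Cell(state.new_id(), parent.file_index, kind, 0,
                        rootward_len, rootward_len, divisions_used=used)
        shootward = Cell(state.new_id(), parent.file_index, kind, 0,
                         shootward_len, shootward_len, divisions_used=used)
    return [rootward, shootward]


def cell_lengths(state: RootState, domain: Domain, file_index: int | None = None) -> np.ndarray:
    """Ordered lengths (grid units) of cells whose midpoint lies in a
    domain.  QC and stem-initial cells belong to the stem cell niche and
    are excluded from all domains."""
    fi = file_index if file_index is not None else 0
    zone = state.zone_map
    out = []
    for c in state.files[fi]:
        if c.type in (QC, STEM):
            continue
        m = c.midpoint
        if domain == "PD" and m < zone.pd_end:
            out.append(c.length)
        elif domain == "TD" and zone.pd_end <= m <= zone.td_end:
            out.append(c.length)
        elif domain == "RAM" and m <= zone.td_end:
            out.append(c.length)
        elif domain == "EZ+DZ" and m > zone.td_end:
            out.append(c.length)
    return np.array(out, dtype=float)


def total_free_thr(state: RootState, thr_fn: Callable[[np.ndarray], np.ndarray]) -> float:
    """Total free Thr over all cells: midpoint steady-state value times
    cell length, summed over every file."""
    total = 0.0
    for cells in state.files:
        mids = np.array([c.midpoint for c in cells]) / state.position_scale
        lengths = np.array([c.length for c in cells], dtype=float)
        total += float(np.sum(np.asarray(thr_fn(mids)) * lengths))
    return total


def simulate(
    config: SimConfig,
    thr_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    params: ThrModelParams | None = None,
    gradients: dict[str, GeneExpressionGradient] | None = None,
    variant: str = "synthesis_only",
) -> Trajectory:
    """Run the simulator to ``t_max``, recording every step.

    If ``thr_fn`` is not given it is built from ``params``/``gradients``
    with the config's genotype.  Deterministic given the configuration.
    """
    if config.t_max <= 0:
        raise ValueError("t_max must be > 0")
    if thr_fn is None:
        p = params if params is not None else ThrModelParams()
        thr_fn = make_thr_fn(p.as_genotype(config.genotype), gradients, variant)
    state = init_root(config)
    n_steps = int(round(config.t_max / config.dt))
    times, lengths, counts, totals, snaps = [], [], [], [], []

    def record(t: float) -> None:
        times.append(t)
        lengths.append(state.total_length(config.analysis_file))
        counts.append(len(state.files[config.analysis_file]))
        totals.append(total_free_thr(state, thr_fn))
        snaps.append({d: cell_lengths(state, d, config.analysis_file)
                      for d in ("PD", "TD", "RAM", "EZ+DZ")})

    record(0.0)
    for k in range(1, n_steps + 1):
        step(state, config, thr_fn)
        record(k * config.dt)
    return Trajectory(config.genotype, np.array(times), np.array(lengths, float),
                      np.array(counts), np.array(totals), snaps, state, config)


# ---------------------------------------------------------------------------
# statistics on simulated cell-length distributions

def compare_distributions(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected) and
    unpaired two-tailed t-test p-values for two length samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample must contain at least 3 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return (1.0, 1.0)
    with warnings.catch_warnings():
        # near-identical samples trigger a harmless precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        mwu = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        tt = stats.ttest_ind(a, b, equal_var=True)
    t_p = float(tt.pvalue)
    if np.isnan(t_p):  # zero pooled variance with distinct means
        t_p = 0.0 if a.mean() != b.mean() else 1.0
    return (float(mwu.pvalue), t_p)


@dataclass(frozen=True)
class WindowResult:
    """Indistinguishability window of mutant RAM vs wild-type TD cells."""

    t1: float | None
    t2: float | None
    times: np.ndarray
    p_td: np.ndarray
    p_pd: np.ndarray
    alpha: float

    @property
    def found(self) -> bool:
        return self.t1 is not None

    @property
    def pd_separated_fraction(self) -> float:
        """Fraction of in-window times where the mutant RAM is also
        significantly different from the wild-type PD."""
        if not self.found:
            return float("nan")
        inside = (self.times >= self.t1) & (self.times <= self.t2)
        return float(np.mean(self.p_pd[inside] <= self.alpha))

    @property
    def simultaneous_times(self) -> np.ndarray:
        """Times where mutant RAM is indistinguishable from Wt TD while
        separated from Wt PD."""
        ok = (self.p_td > self.alpha) & (self.p_pd <= self.alpha)
        return self.times[ok]


def find_indistinguishable_window(
    traj_mut: Trajectory,
    traj_wt: Trajectory,
    alpha: float = 0.05,
) -> WindowResult:
    """Maximal contiguous time interval where mutant RAM cell lengths are
    statistically indistinguishable (Mann-Whitney p > alpha) from Wt TD
    cell lengths.  Also reports the per-time comparison against Wt PD.

    Times where either sample has fewer than 3 cells are excluded.  An
    empty window is flagged (t1 = t2 = None), not an exception.
    """
    if traj_mut.times.shape != traj_wt.times.shape or not np.allclose(
            traj_mut.times, traj_wt.times):
        raise ValueError("trajectories must share recording times")
    times, p_td, p_pd = [], [], []
    for i, t in enumerate(traj_mut.times):
        ram = traj_mut.snapshots[i]["RAM"]
        td = traj_wt.snapshots[i]["TD"]
        pd_ = traj_wt.snapshots[i]["PD"]
        if min(ram.size, td.size, pd_.size) < 3:
            continue
        times.append(t)
        p_td.append(compare_distributions(ram, td)[0])
        p_pd.append(compare_distributions(ram, pd_)[0])
    times = np.array(times)
    p_td = np.array(p_td)
    p_pd = np.array(p_pd)
    runs: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(np.concatenate([p_td > alpha, [False]])):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i - 1))
            start = None
    if not runs:
        return WindowResult(None, None, times, p_td, p_pd, alpha)
    # prefer the run where the mutant RAM is also separated from the Wt PD
    # (early on both genotypes are still identical, so p = 1 against both
    # domains; that trivial run is not the t1-t2 window); ties go to length
    def score(run: tuple[int, int]) -> tuple[int, int]:
        lo, hi = run
        return (int(np.sum(p_pd[lo:hi + 1] <= alpha)), hi - lo)

    best = max(runs, key=score)
    return WindowResult(float(times[best[0]]), float(times[best[1]]),
                        times, p_td, p_pd, alpha)


def classify_growth(traj: Trajectory, rel_threshold: float = 1e-3,
                    window: float = 1.0) -> str:
    """Classify a trajectory as determinate (growth plateau) or
    indeterminate: relative total-length increase below ``rel_threshold``
    over the trailing ``window`` time units means a plateau."""
    k = max(1, int(round(window / traj.config.dt)))
    if k >= traj.total_length.size:
        raise ValueError("trajectory shorter than the plateau window")
    l0, l1 = traj.total_length[-k - 1], traj.total_length[-1]
    return "determinate" if (l1 - l0) / l0 < rel_threshold else "indeterminate"


# ---------------------------------------------------------------------------
# robustness and expression-scaling experiments

def _run_pair(config: SimConfig, params: ThrModelParams,
              gradients: dict[str, GeneExpressionGradient] | None,
              variant: str) -> tuple[Trajectory, Trajectory]:
    wt = simulate(replace(config, genotype=WT), params=params,
                  gradients=gradients, variant=variant)
    mut = simulate(replace(config, genotype=MUTANT), params=params,
                   gradients=gradients, variant=variant)
    return wt, mut


def shared_features(
    config: SimConfig,
    params: ThrModelParams | None = None,
    gradients: dict[str, GeneExpressionGradient] | None = None,
    variant: str = "synthesis_only",
    mid_time: float | None = None,
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Evaluate the four shared robustness features for one configuration:

    1. Wt grows indeterminately while the mutant growth is determinate.
    2. Mutant whole-root free Thr exceeds Wt at a matched mid-growth time.
    3. Mutant SCN free Thr is below the Wt SCN level.
    4. A time exists where mutant RAM cell lengths are Mann-Whitney
       indistinguishable from Wt TD cells yet separated from Wt PD cells.
    """
    params = params if params is not None else ThrModelParams()
    wt, mut = _run_pair(config, params, gradients, variant)
    t_mid = mid_time if mid_time is not None else 0.68 * config.t_max
    i = wt.at_time(t_mid)
    window = find_indistinguishable_window(mut, wt, alpha=alpha)
    scn = np.array([0.0])
    wt_fn = make_thr_fn(params.as_genotype(WT), gradients, variant)
    mut_fn = make_thr_fn(params.as_genotype(MUTANT), gradients, variant)
    return {
        "wt_indeterminate_mutant_determinate": (
            classify_growth(wt) == "indeterminate"
            and classify_growth(mut) == "determinate"),
        "mutant_total_thr_higher": bool(mut.total_thr[i] > wt.total_thr[i]),
        "mutant_scn_thr_lower": bool(mut_fn(scn)[0] < wt_fn(scn)[0]),
        "indistinguishability_window": window.simultaneous_times.size > 0,
    }


def robustness_sweep(
    division_thresholds: Sequence[int] = (2, 4, 6, 8, 10),
    ez_increments: Sequence[int] = (3, 4, 5, 6, 7, 8),
    final_lengths: Sequence[int] = (75, 80, 85, 90),
    base_config: SimConfig | None = None,
    params: ThrModelParams | None = None,
    gradients: dict[str, GeneExpressionGradient] | None = None,
    variant: str = "synthesis_only",
) -> pd.DataFrame:
    """Grid sweep over cell-growth parameters; one row of shared-feature
    booleans per configuration."""
    base = base_config if base_config is not None else SimConfig()
    rows = []
    for ld, ez, fl in itertools.product(division_thresholds, ez_increments,
                                        final_lengths):
        config = replace(base, division_length_threshold=ld, ez_increment=ez,
                         final_length=fl)
        feats = shared_features(config, params, gradients, variant)
        rows.append({"division_length_threshold": ld, "ez_increment": ez,
                     "final_length": fl, **feats})
    return pd.DataFrame(rows)


def expression_scaling_experiment(
    scales: Sequence[float],
    base_config: SimConfig | None = None,
    params: ThrModelParams | None = None,
    variant: str = "synthesis_only",
) -> pd.DataFrame:
    """Scale all expression gradients while keeping theta fixed, and
    classify growth per genotype.

    Scale 0 abolishes Thr production (wild-type roots stop growing);
    large scales restore indeterminate growth in the mutant.
    """
    base = base_config if base_config is not None else SimConfig()
    params = params if params is not None else ThrModelParams()
    theta = base.theta  # fixed at the unscaled default
    rows = []
    for scale in scales:
        if scale < 0:
            raise ValueError("scales must be >= 0")
        gradients = default_gradients(scale=scale)
        for genotype in (WT, MUTANT):
            config = replace(base, genotype=genotype,
                             thr_division_threshold=theta)
            traj = simulate(config, params=params, gradients=gradients,
                            variant=variant)
            rows.append({"scale": scale, "genotype": genotype,
                         "classification": classify_growth(traj)})
    return pd.DataFrame(rows)
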