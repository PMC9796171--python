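"""Parameter-sweep robustness analysis of the Thr steady-state model.

Parameter sets are sampled by Latin hypercube over wide kinetic ranges
(Km 1-1000 and delta 1-10 for the synthesis model; Km3/Km4/Km5 1-100 for
the extended model).  Each set is evaluated for both genotypes; a set is
*accepted* when the mutant/wild-type whole-root Thr ratio reaches the
experimentally established ~1.5-fold enrichment.  Wild-type sets must
respect the two-orders-of-magnitude activity difference between the
synthases (Km2 >= 100 * Km1); violating draws are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .gradients import GeneExpressionGradient, default_gradients
from .thr_model import (
    MUTANT,
    WT,
    AminoAcidProfile,
    ThrModelParams,
    classify_pattern,
    profile_along_root,
    whole_root_thr,
)

#: Sweep ranges mirroring the published exploration.
SYNTHESIS_RANGES: dict[str, tuple[float, float]] = {
    "Km1": (1.0, 1000.0),
    "Km2": (1.0, 1000.0),
    "delta": (1.0, 10.0),
}
EXTENDED_RANGES: dict[str, tuple[float, float]] = {
    **SYNTHESIS_RANGES,
    "Km3": (1.0, 100.0),
    "Km4": (1.0, 100.0),
    "Km5": (1.0, 100.0),
}

#: Published sweep sizes (scaled down in tests).
DEFAULT_N_SETS = {"synthesis_only": 10_000, "extended": 125_000}

ACCEPTANCE_FOLD = 1.5


@dataclass(frozen=True)
class SweepResult:
    """Outcome of one sampled parameter set, evaluated for both genotypes."""

    params: ThrModelParams
    whole_root_thr_ratio: float
    scn_thr_ratio: float
    pattern_flags: dict[str, bool]
    accepted: bool


def _evaluate_set(
    params: ThrModelParams,
    gradients: dict[str, GeneExpressionGradient],
    positions: np.ndarray | None,
    variant: str,
    tail_weight: float,
) -> SweepResult:
    wt = profile_along_root(params.as_genotype(WT), gradients, positions, variant)
    mut = profile_along_root(params.as_genotype(MUTANT), gradients, positions, variant)
    wt_total = whole_root_thr(wt, tail_weight)
    mut_total = whole_root_thr(mut, tail_weight)
    ratio = mut_total / wt_total if wt_total > 0 else np.inf
    scn_ratio = mut.thr[0] / wt.thr[0] if wt.thr[0] > 0 else np.inf
    wt_flags = classify_pattern(wt)
    mut_flags = classify_pattern(mut)
    flags = {
        "wt_max_at_scn": wt_flags["wt_max_at_scn"],
        "mutant_ez_elevated": mut_flags["mutant_ez_elevated"],
        "mutant_scn_deficient": mut_flags["mutant_scn_deficient"],
        "gly_ile_max_at_scn": wt_flags["gly_ile_max_at_scn"],
    }
    accepted = bool(ratio >= ACCEPTANCE_FOLD and mut.thr[0] < wt.thr[0])
    return SweepResult(params, float(ratio), float(scn_ratio), flags, accepted)


def sweep_parameters(
    ranges: dict[str, tuple[float, float]] | None = None,
    n_sets: int = 100,
    seed: int = 0,
    variant: str = "synthesis_only",
    gradients: dict[str, GeneExpressionGradient] | None = None,
    positions: np.ndarray | None = None,
    tail_weight: float = 10.0,
    base_params: ThrModelParams | None = None,
) -> list[SweepResult]:
    """Latin-hypercube sweep over kinetic parameters.

    Each sampled set is evaluated for Wt and *mto2-2*; sets whose Wt
    parameterization violates ``Km2 >= 100 * Km1`` are resampled
    (uniformly within the ranges) until the constraint holds.  Seeded and
    fully reproducible.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if variant not in DEFAULT_N_SETS:
        raise ValueError(f"unknown variant {variant!r}")
    if ranges is None:
        ranges = SYNTHESIS_RANGES if variant == "synthesis_only" else EXTENDED_RANGES
    if not ranges:
        raise ValueError("empty parameter ranges")
    for name, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
    gradients = gradients if gradients is not None else default_gradients()
    base = base_params if base_params is not None else ThrModelParams()

    names = sorted(ranges)
    lows = np.array([ranges[n][0] for n in names])
    highs = np.array([ranges[n][1] for n in names])
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    samples = qmc.scale(sampler.random(n_sets), lows, highs)

    rng = np.random.default_rng(seed + 1)
    constrained = "Km1" in names and "Km2" in names
    results = []
    for row in samples:
        values = dict(zip(names, row))
        if constrained:
            guard = 0
            while values["Km2"] < 100.0 * values["Km1"]:
                values["Km1"], values["Km2"] = rng.uniform(lows[:2], highs[:2])
                guard += 1
                if guard > 100_000:  # pragma: no cover
                    raise RuntimeError("could not satisfy Km2 >= 100*Km1")
        params = replace(base, **values)
        results.append(_evaluate_set(params, gradients, positions, variant, tail_weight))
    return results


def sweep_to_frame(results: list[SweepResult]) -> pd.DataFrame:
    """Tabulate sweep results (one row per parameter set)."""
    rows = []
    for r in results:
        row = {
            "S": r.params.S, "Km1": r.params.Km1, "Km2": r.params.Km2,
            "Km3": r.params.Km3, "Km4": r.params.Km4, "Km5": r.params.Km5,
            "delta": r.params.delta,
            "tsy2_compensation": r.params.tsy2_compensation,
            "whole_root_thr_ratio": r.whole_root_thr_ratio,
            "scn_thr_ratio": r.scn_thr_ratio,
            "accepted": r.accepted,
        }
        row.update(r.pattern_flags)
        rows.append(row)
    return pd.DataFrame(rows)
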