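"""End-to-end recomputation of the headline results.

Runs the default wild-type and *mto2-2* simulations, the MSC analysis on
synthetic cohorts, the f/h-rule enumeration and the sweep pattern checks,
and reports each quantity with its pass/fail verdict.  Everything is
recomputed from scratch; nothing is read from disk.
"""

from __future__ import annotations

from ramthr.msc import CellLengthProfile, compute_f, compute_h
from ramthr.root_sim import (
    SimConfig,
    classify_growth,
    find_indistinguishable_window,
    simulate,
)
from ramthr.sweep import sweep_parameters
from ramthr.synthetic import ProfileSpec, generate_cohort
from ramthr.msc import classify_sample
from ramthr.thr_model import MUTANT, WT

#: Comparison time within the t1-t2 indistinguishability window.
MID_GROWTH_TIME = 3.4


def whole_root_thr_ratio(mid_time: float = MID_GROWTH_TIME) -> dict:
    """Mutant/Wt ratio of total free Thr at a matched mid-growth time,
    from the default simulations."""
    wt = simulate(SimConfig(genotype=WT))
    mut = simulate(SimConfig(genotype=MUTANT))
    i = wt.at_time(mid_time)
    ratio = float(mut.total_thr[i] / wt.total_thr[i])
    window = find_indistinguishable_window(mut, wt)
    return {
        "ratio": ratio,
        "time": float(wt.times[i]),
        "n_cells": int(wt.n_cells[i] + mut.n_cells[i]),
        "wt_classification": classify_growth(wt),
        "mutant_classification": classify_growth(mut),
        "window": (window.t1, window.t2),
    }


def minimal_segment_size(n_max: int = 200) -> dict:
    """Smallest h the f/h rule produces over profiles of n = 7..n_max,
    each treated as its own smallest sample profile."""
    h_values = []
    for n in range(7, n_max + 1):
        profile = CellLengthProfile(f"n{n}", [1.0] * n)
        f = compute_f([profile])
        h_values.append(compute_h(f, n))
    return {"min_h": min(h_values), "max_h": max(h_values), "n_range": (7, n_max)}


def reproduce_all(seed: int = 1) -> dict:
    """Recompute headline quantities plus qualitative checks."""
    ratio = whole_root_thr_ratio()
    seg = minimal_segment_size()

    sweep = sweep_parameters(n_sets=200, seed=seed)
    wt_scn_frac = sum(r.pattern_flags["wt_max_at_scn"] for r in sweep) / len(sweep)

    wt_cohort = generate_cohort(ProfileSpec(preset="wt_like"), 50, seed=seed)
    _, wt_pct = classify_sample(wt_cohort)
    mut_cohort = generate_cohort(ProfileSpec(preset="mto2_like"), 50, seed=seed + 1)
    _, mut_pct = classify_sample(mut_cohort)

    checks = {
        "whole_root_thr_ratio_ge_1.5": {
            "value": ratio["ratio"], "passed": ratio["ratio"] >= 1.5},
        "wt_indeterminate_mutant_determinate": {
            "value": (ratio["wt_classification"], ratio["mutant_classification"]),
            "passed": (ratio["wt_classification"] == "indeterminate"
                       and ratio["mutant_classification"] == "determinate")},
        "indistinguishability_window_found": {
            "value": ratio["window"], "passed": ratio["window"][0] is not None},
        "min_h_is_3": {"value": seg["min_h"], "passed": seg["min_h"] == 3},
        "wt_thr_max_at_scn_fraction": {
            "value": wt_scn_frac, "passed": wt_scn_frac >= 0.95},
        "wt_cohort_two_breakpoints": {
            "value": wt_pct, "passed": wt_pct.get(2, 0) >= 90.0},
        "mutant_cohort_one_breakpoint_majority": {
            "value": mut_pct, "passed": mut_pct.get(1, 0) > 50.0},
    }
    return {"seed": seed,
            "quantities": {"whole_root_thr_ratio": ratio,
                           "minimal_segment_size": seg},
            "checks": checks}
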