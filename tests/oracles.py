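"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: segmentation by
exhaustive enumeration of breakpoint placements, the extended steady
state by long-time ODE integration, and Mann-Whitney p-values by exact
enumeration of the permutation distribution of U.
"""

import itertools

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp


def best_segmentation(y, m, h):
    """Exhaustive search over admissible placements of m breakpoints."""
    n = y.size
    x = np.arange(1, n + 1, dtype=float)

    def seg_rss(i, j):
        if j - i + 1 < 2:
            return 0.0
        coeff, res, *_ = np.polyfit(x[i:j + 1], y[i:j + 1], 1, full=True)
        return float(res[0]) if res.size else 0.0

    best_rss, best_cuts = np.inf, None
    for cuts in itertools.combinations(range(n - 1), m):
        bounds = [-1, *cuts, n - 1]
        if any(bounds[k + 1] - bounds[k] < h for k in range(len(bounds) - 1)):
            continue
        rss = sum(seg_rss(bounds[k] + 1, bounds[k + 1])
                  for k in range(len(bounds) - 1))
        if rss < best_rss - 1e-12:
            best_rss, best_cuts = rss, cuts
    return best_rss, tuple(c + 1 for c in best_cuts)  # 1-based last indices


def integrate_extended(params, e_m, e_t, e_a, e_o, t_end=400.0):
    """Long-time integration of the synthesis + catabolism ODE system."""
    from ramthr.thr_model import _production

    P = float(_production(params, e_m, e_t))
    a = e_a / (params.Km3 + e_a) if e_a > 0 else 0.0
    b = e_o / (params.Km4 + e_o) if e_o > 0 else 0.0
    d = params.delta

    def rhs(_, y):
        thr, gly, ile = y
        flux_ile = b * thr * params.Km5 / (params.Km5 + ile)
        return [P - a * thr - flux_ile - d * thr,
                a * thr - d * gly,
                flux_ile - d * ile]

    sol = solve_ivp(rhs, (0, t_end), [0.0, 0.0, 0.0], rtol=1e-10, atol=1e-12)
    return sol.y[:, -1]


def exact_mwu_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled ranks to the first sample (tie-free samples only)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    mean = n1 * n2 / 2.0
    rank_sums = np.array([sum(c) for c in
                          itertools.combinations(ranks, n1)])
    u_all = rank_sums - n1 * (n1 + 1) / 2
    p = float(np.mean(np.abs(u_all - mean) >= abs(u_obs - mean) - 1e-9))
    return min(1.0, p)
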