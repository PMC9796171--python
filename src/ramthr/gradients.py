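"""Linear gene-expression gradients along the root axis.

Enzyme expression along the longitudinal root axis is described by linear
functions of normalized position (0 = quiescent centre, 1 = shootward end
of the modelled axis), clamped at zero.  The wild-type patterns are: *MTO2*
(threonine synthase 1) high at the tip and decreasing shootward, *TSY2*
(threonine synthase 2) low at the tip and increasing shootward, and the
catabolic enzymes *THA1/2* and *OMR1* decreasing shootward.  The default
coefficients are configurable model inputs, chosen to reproduce these
qualitative patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Genes with a modelled expression gradient.
GENES = ("MTO2", "TSY2", "THA12", "OMR1")


@dataclass(frozen=True)
class GeneExpressionGradient:
    """Linear expression-vs-position function for one enzyme gene.

    Parameters
    ----------
    gene
        One of ``MTO2``, ``TSY2``, ``THA12``, ``OMR1``.
    intercept
        Expression (a.u.) at the quiescent centre (position 0).
    slope
        Expression change (a.u.) per unit normalized position.
    scale
        Dimensionless multiplier applied to the whole gradient; used by
        expression-scaling experiments.  Default 1.
    """

    gene: str
    intercept: float
    slope: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}; expected one of {GENES}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    def __call__(self, x):
        return expression_at(self, x)

    def rescaled(self, scale: float) -> "GeneExpressionGradient":
        """Return a copy with a new overall `scale`."""
        return replace(self, scale=scale)


def expression_at(gradient: GeneExpressionGradient, x):
    """Evaluate a gradient at normalized position(s) ``x`` in [0, 1].

    Returns ``scale * max(0, intercept + slope * x)``.  Accepts scalars or
    arrays; raises ``ValueError`` for positions outside [0, 1].
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > 1):
        raise ValueError("position must lie in [0, 1]")
    value = gradient.scale * np.maximum(0.0, gradient.intercept + gradient.slope * xa)
    if np.isscalar(x) or xa.ndim == 0:
        return float(value)
    return value


def default_gradients(scale: float = 1.0) -> dict[str, GeneExpressionGradient]:
    """Default wild-type expression gradients for all four modelled genes.

    MTO2 decreases tipward-high to zero at the shootward end; TSY2 mirrors
    it (low at the tip, high shootward); the catabolic enzymes THA1/2 and
    OMR1 are tip-enriched.
    """
    return {
        "MTO2": GeneExpressionGradient("MTO2", intercept=10.0, slope=-10.0, scale=scale),
        "TSY2": GeneExpressionGradient("TSY2", intercept=1.0, slope=9.0, scale=scale),
        "THA12": GeneExpressionGradient("THA12", intercept=8.0, slope=-8.0, scale=scale),
        "OMR1": GeneExpressionGradient("OMR1", intercept=8.0, slope=-8.0, scale=scale),
    }
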