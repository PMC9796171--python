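"""Steady-state free threonine (Thr) distribution along the root.

Free Thr in each cell is modelled by an ODE with Michaelis-Menten
production from two threonine synthases (MTO2 and TSY2, fed by a constant
substrate supply ``S``) and first-order usage ``delta``:

    d[Thr]/dt = S * ( E_M / (Km1 + E_M) + E_T / (Km2 + E_T) ) - delta * [Thr]

where ``E_M`` and ``E_T`` are position-dependent enzyme expression levels
and ``Km1``, ``Km2`` the enzyme activity at which production is
half-maximal.  In the wild type MTO2 activity exceeds TSY2 activity by two
orders of magnitude (``Km2 >> Km1``).  The *mto2-2* mutant removes the
MTO2 term and applies a compensatory increase of TSY2 activity
(``Km2 / tsy2_compensation``).

The extended variant adds Thr catabolism to glycine (via THA1/2) and to
isoleucine (via OMR1, feedback-inhibited by Ile):

    d[Thr]/dt = P - a*[Thr] - b*[Thr]*Km5/(Km5+[Ile]) - delta*[Thr]
    d[Gly]/dt = a*[Thr] - delta*[Gly]
    d[Ile]/dt = b*[Thr]*Km5/(Km5+[Ile]) - delta*[Ile]

with ``a = E_THA/(Km3+E_THA)``, ``b = E_OMR/(Km4+E_OMR)`` and ``P`` the
production term above.  Steady states are found exactly (synthesis-only)
or by bracketing root-finding on the scalar Ile balance (extended).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .gradients import GeneExpressionGradient, expression_at

Genotype = Literal["Wt", "mto2-2"]

WT: Genotype = "Wt"
MUTANT: Genotype = "mto2-2"


@dataclass(frozen=True)
class ThrModelParams:
    """Kinetic parameters of the Thr synthesis/catabolism model.

    All concentrations and activities are in arbitrary units on a shared
    scale.  ``tsy2_compensation`` (>= 1) divides ``Km2`` in the mutant
    only, representing the putative compensatory TSY2 activity.
    """

    S: float = 1.0
    Km1: float = 10.0
    Km2: float = 1000.0
    Km3: float = 10.0
    Km4: float = 10.0
    Km5: float = 10.0
    delta: float = 1.0
    genotype: Genotype = WT
    tsy2_compensation: float = 100.0

    def __post_init__(self) -> None:
        for name in ("S", "Km1", "Km2", "Km3", "Km4", "Km5", "delta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.tsy2_compensation < 1:
            raise ValueError("tsy2_compensation must be >= 1")
        if self.genotype not in (WT, MUTANT):
            raise ValueError(f"unknown genotype {self.genotype!r}")

    @property
    def km2_effective(self) -> float:
        """TSY2 half-activity constant after mutant compensation."""
        if self.genotype == MUTANT:
            return self.Km2 / self.tsy2_compensation
        return self.Km2

    @property
    def wt_activity_ratio_ok(self) -> bool:
        """Whether the wild-type two-orders-of-magnitude activity
        difference (Km2 >= 100 * Km1) holds."""
        return self.Km2 >= 100.0 * self.Km1

    def as_genotype(self, genotype: Genotype) -> "ThrModelParams":
        return replace(self, genotype=genotype)


@dataclass(frozen=True)
class AminoAcidProfile:
    """Per-position steady-state amino-acid levels along the root axis."""

    positions: np.ndarray
    thr: np.ndarray
    gly: np.ndarray = field(default_factory=lambda: np.empty(0))
    ile: np.ndarray = field(default_factory=lambda: np.empty(0))
    model_variant: str = "synthesis_only"
    genotype: Genotype = WT

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "thr", np.asarray(self.thr, dtype=float))
        object.__setattr__(self, "gly", np.asarray(self.gly, dtype=float))
        object.__setattr__(self, "ile", np.asarray(self.ile, dtype=float))
        if self.thr.shape != self.positions.shape:
            raise ValueError("thr and positions must have the same shape")
        if np.any(self.thr < 0) or np.any(self.gly < 0) or np.any(self.ile < 0):
            raise ValueError("concentrations must be non-negative")
        if self.model_variant == "synthesis_only" and (self.gly.size or self.ile.size):
            raise ValueError("synthesis_only profiles carry empty gly/ile")


def _production(params: ThrModelParams, e_mto2: float, e_tsy2: float):
    """Michaelis-Menten Thr production term (genotype-dependent)."""
    e_m = np.asarray(e_mto2, dtype=float)
    e_t = np.asarray(e_tsy2, dtype=float)
    if np.any(e_m < 0) or np.any(e_t < 0):
        raise ValueError("expression levels must be >= 0")
    tsy2_term = np.where(e_t > 0, e_t / (params.km2_effective + e_t), 0.0)
    if params.genotype == MUTANT:
        return params.S * tsy2_term
    mto2_term = np.where(e_m > 0, e_m / (params.Km1 + e_m), 0.0)
    return params.S * (mto2_term + tsy2_term)


def steady_state_synthesis(params: ThrModelParams, e_mto2: float, e_tsy2: float):
    """Steady-state free Thr for the synthesis-only model.

    Closed form ``Thr* = P / delta`` with P the Michaelis-Menten
    production; bounded by ``2 S / delta``.  Accepts scalar or array
    expression levels.
    """
    value = _production(params, e_mto2, e_tsy2) / params.delta
    if value.ndim == 0:
        return float(value)
    return value


class SteadyStateError(RuntimeError):
    """Raised when the extended steady state cannot be located."""


def steady_state_extended(
    params: ThrModelParams,
    e_mto2: float,
    e_tsy2: float,
    e_tha12: float,
    e_omr1: float,
    tol: float = 1e-12,
) -> tuple[float, float, float]:
    """Steady state (Thr, Gly, Ile) of the synthesis + catabolism model.

    At steady state the system reduces to a single scalar balance for Ile:
    with ``f(I) = Km5/(Km5+I)``,

        Thr(I) = P / (a + b*f(I) + delta)
        Ile    = b * f(I) * Thr(I) / delta

    whose residual is strictly decreasing in I, positive at 0 and negative
    at the flux bound ``b*P/delta**2``; it is solved with Brent's method.
    With zero catabolic expression this reduces exactly to the
    synthesis-only model.
    """
    if e_tha12 < 0 or e_omr1 < 0:
        raise ValueError("expression levels must be >= 0")
    P = float(_production(params, e_mto2, e_tsy2))
    a = e_tha12 / (params.Km3 + e_tha12) if e_tha12 > 0 else 0.0
    b = e_omr1 / (params.Km4 + e_omr1) if e_omr1 > 0 else 0.0
    d = params.delta

    def thr_at(ile: float) -> float:
        f = params.Km5 / (params.Km5 + ile)
        return P / (a + b * f + d)

    if P == 0.0:
        return (0.0, 0.0, 0.0)
    if b == 0.0:
        ile = 0.0
    else:
        def residual(ile: float) -> float:
            f = params.Km5 / (params.Km5 + ile)
            return b * f * thr_at(ile) / d - ile

        upper = b * P / d**2 + 1e-9
        try:
            ile = brentq(residual, 0.0, upper, xtol=tol, maxiter=200)
        except Exception as exc:  # pragma: no cover - bracketing is guaranteed
            raise SteadyStateError(
                f"Ile balance root-finding failed (P={P}, a={a}, b={b}, delta={d})"
            ) from exc
    thr = thr_at(ile)
    gly = a * thr / d
    return (float(thr), float(gly), float(ile))


def profile_along_root(
    params: ThrModelParams,
    gradients: dict[str, GeneExpressionGradient],
    positions: Sequence[float] | None = None,
    variant: str = "synthesis_only",
) -> AminoAcidProfile:
    """Evaluate per-position steady states along the root axis.

    ``gradients`` must contain MTO2 and TSY2 (plus THA12 and OMR1 for the
    extended variant).  Positions default to 101 evenly spaced points on
    [0, 1].  Deterministic for fixed inputs.
    """
    if variant not in ("synthesis_only", "extended"):
        raise ValueError(f"unknown variant {variant!r}")
    required = ("MTO2", "TSY2") + (("THA12", "OMR1") if variant == "extended" else ())
    missing = [g for g in required if g not in gradients]
    if missing:
        raise KeyError(f"missing required gradient(s): {missing}")
    x = np.linspace(0.0, 1.0, 101) if positions is None else np.asarray(positions, float)

    e_m = expression_at(gradients["MTO2"], x)
    e_t = expression_at(gradients["TSY2"], x)
    if variant == "synthesis_only":
        thr = steady_state_synthesis(params, e_m, e_t)
        return AminoAcidProfile(x, np.atleast_1d(thr), model_variant=variant,
                                genotype=params.genotype)
    e_a = expression_at(gradients["THA12"], x)
    e_o = expression_at(gradients["OMR1"], x)
    out = np.array([
        steady_state_extended(params, em, et, ea, eo)
        for em, et, ea, eo in zip(np.atleast_1d(e_m), np.atleast_1d(e_t),
                                  np.atleast_1d(e_a), np.atleast_1d(e_o))
    ])
    return AminoAcidProfile(x, out[:, 0], out[:, 1], out[:, 2],
                            model_variant=variant, genotype=params.genotype)


def classify_pattern(
    profile: AminoAcidProfile,
    ram_end: float = 0.4,
) -> dict[str, bool]:
    """Boolean pattern flags describing where amino-acid maxima fall.

    The axis is split at ``ram_end`` into a RAM region ([0, ram_end],
    containing the stem cell niche at position 0) and an EZ+DZ region.
    Flags:

    - ``wt_max_at_scn``: the Thr maximum sits at the stem cell niche.
    - ``mutant_scn_deficient``: Thr at the SCN is positive but below the
      RAM mean ("low but higher than zero").
    - ``mutant_ez_elevated``: the Thr maximum lies in EZ+DZ and exceeds
      the RAM mean.
    - ``gly_ile_max_at_scn``: both catabolites peak at the SCN (extended
      profiles only; False otherwise).
    """
    x = profile.positions
    if x.size < 3:
        raise ValueError("profile needs at least 3 positions to classify")
    order = np.argsort(x)
    x, thr = x[order], profile.thr[order]
    ram = x <= ram_end
    ez_dz = ~ram
    if not ram.any() or not ez_dz.any():
        raise ValueError("profile positions must cover both RAM and EZ+DZ")
    i_max = int(np.argmax(thr))
    ram_mean = float(thr[ram].mean())
    flags = {
        "wt_max_at_scn": i_max == 0,
        "mutant_scn_deficient": bool(0.0 < thr[0] < ram_mean),
        "mutant_ez_elevated": bool(ez_dz[i_max] and thr[i_max] > ram_mean),
        "gly_ile_max_at_scn": False,
    }
    if profile.model_variant == "extended" and profile.gly.size:
        gly, ile = profile.gly[order], profile.ile[order]
        flags["gly_ile_max_at_scn"] = bool(
            np.argmax(gly) == 0 and np.argmax(ile) == 0 and gly[0] > 0 and ile[0] > 0
        )
    return flags


def whole_root_thr(profile: AminoAcidProfile, tail_weight: float = 10.0) -> float:
    """Whole-root free Thr content of a root with this axial profile.

    Integrates Thr over the modelled axis and adds a mature-root tail term
    ``tail_weight * Thr(1)``: the grown root's differentiated portion is
    several modelled-axis lengths long and, being shootward of the
    elongation zone, carries the profile's value at position 1.
    """
    order = np.argsort(profile.positions)
    x, thr = profile.positions[order], profile.thr[order]
    return float(np.trapezoid(thr, x) + tail_weight * thr[-1])
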