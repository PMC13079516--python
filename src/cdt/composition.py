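"""Multi-system gain composition with a cerebellar comparator correction.

The total subjective-time gain is composed from three system-level gains —
cerebellum (CBL), basal ganglia (BG) and cortex (CTX) — whose relative
influence depends on the interval duration τ being timed: cerebellar
mechanisms dominate sub-second timing, basal-ganglia accumulation dominates
supra-second timing, and a cortical contribution peaks at intermediate
timescales.  The composition is multiplicative,

    κ = κ_BG^w_BG · κ_CTX^w_CTX · C(κ_CBL, κ_BG+CTX),

with an exactly equivalent log-linear form, where C is a pluggable
comparator function modeling the cerebellum's error-checking role: it
compares the cerebellar gain against the combined cortico–basal-ganglia
gain and pushes the total toward veridical timing (κ = 1) with strength
g ∈ [0, 1].

The weight functions w_CBL(τ), w_BG(τ), w_CTX(τ) are a logistic pair in
log10(τ) (CBL falling, BG rising, crossing at τ = tau_cross) plus a
log-Gaussian cortical bump, renormalized so they sum to exactly 1 at
every τ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GainTrajectory, TimeGrid

__all__ = [
    "ComponentGains",
    "WeightProfile",
    "ComparatorSpec",
    "register_comparator",
    "weights_at",
    "combined_background_gain",
    "comparator_correction",
    "total_gain_multiplicative",
    "total_gain_loglinear",
    "compose_trajectory",
    "crossover_duration",
]


@dataclass(frozen=True)
class ComponentGains:
    """Per-system gains, all dimensionless and positive."""

    kappa_cbl: float = 1.0
    kappa_bg: float = 1.0
    kappa_ctx: float = 1.0

    def __post_init__(self):
        for name in ("kappa_cbl", "kappa_bg", "kappa_ctx"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class WeightProfile:
    """Parameters of the τ-dependent system weights.

    tau_cross : duration (s) at which w_CBL(τ) = w_BG(τ); default 1 s,
        the conventional boundary between sub- and supra-second timing.
    slope : logistic steepness per decade of τ.
    ctx_center : center of the cortical bump in log10(τ) (0 = 1 s).
    ctx_width : bump width in log10(τ) decades.
    ctx_height : pre-normalization bump amplitude.
    """

    tau_cross: float = 1.0
    slope: float = 2.0
    ctx_center: float = 0.0
    ctx_width: float = 0.5
    ctx_height: float = 0.5

    def __post_init__(self):
        if self.tau_cross <= 0:
            raise ValueError("tau_cross must be > 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.ctx_width <= 0:
            raise ValueError("ctx_width must be > 0")
        if self.ctx_height < 0:
            raise ValueError("ctx_height must be >= 0")


def weights_at(tau, profile: WeightProfile = WeightProfile()):
    """System weights (w_cbl, w_bg, w_ctx) at interval duration tau (s).

    The weights are each in [0, 1] and sum to exactly 1 (raw values are
    divided by their sum).  w_cbl is strictly decreasing in τ, w_bg
    strictly increasing, and w_ctx unimodal; w_cbl = w_bg at
    τ = profile.tau_cross.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(~np.isfinite(tau)) or np.any(tau <= 0):
        raise ValueError("tau must be positive and finite")
    x = np.log10(tau) - np.log10(profile.tau_cross)
    # logistic pair: raw_cbl + raw_bg = 1 by symmetry, so the CBL/BG
    # crossover at x = 0 survives renormalization
    raw_bg = 1.0 / (1.0 + np.exp(-profile.slope * x))
    raw_cbl = 1.0 - raw_bg
    xc = np.log10(tau) - profile.ctx_center
    raw_ctx = profile.ctx_height * np.exp(-0.5 * (xc / profile.ctx_width) ** 2)
    total = raw_cbl + raw_bg + raw_ctx
    w = (raw_cbl / total, raw_bg / total, raw_ctx / total)
    if tau.ndim == 0:
        return tuple(float(v) for v in w)
    return w


def crossover_duration(
    profile: WeightProfile = WeightProfile(),
    lo: float = 0.01,
    hi: float = 100.0,
    xtol: float = 1e-6,
) -> float:
    """Duration τ (s) where w_cbl(τ) = w_bg(τ), by bisection on [lo, hi]."""
    from scipy.optimize import brentq

    def gap(tau):
        w_cbl, w_bg, _ = weights_at(tau, profile)
        return w_cbl - w_bg

    if gap(lo) * gap(hi) > 0:
        raise ValueError("weight crossover does not bracket in [lo, hi]")
    return float(brentq(gap, lo, hi, xtol=xtol))


def combined_background_gain(gains: ComponentGains, weights) -> float:
    """Combined cortico–basal-ganglia gain κ_BG+CTX.

    Defined as the weight-normalized geometric mean κ_BG^w_bg · κ_CTX^w_ctx —
    the unique choice consistent with both the multiplicative and the
    log-linear composition.
    """
    _, w_bg, w_ctx = weights
    return float(gains.kappa_bg ** w_bg * gains.kappa_ctx ** w_ctx)


# --- comparator registry ---------------------------------------------------

_COMPARATORS: dict = {}


def register_comparator(name: str):
    """Register a comparator form ``f(kappa_cbl, kappa_bg_ctx, g, weights)``.

    Contract: f(1, 1, g, w) == 1 for all g, and with κ_CBL = 1 the total
    composed |ln κ| must be non-increasing in g.
    """

    def deco(fn):
        _COMPARATORS[name] = fn
        return fn

    return deco


@register_comparator("default")
def _default_comparator(kappa_cbl, kappa_bg_ctx, g, weights):
    # κ_CBL enters with its timescale weight; the −g exponent cancels the
    # combined CTX–BG gain, driving total κ -> 1 as g -> 1 (full correction)
    w_cbl = weights[0]
    return kappa_cbl ** w_cbl * kappa_bg_ctx ** (-g)


@dataclass(frozen=True)
class ComparatorSpec:
    """Comparator strength g in [0, 1] and the registered form to use."""

    g: float = 0.0
    form: str = "default"

    def __post_init__(self):
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("comparator gain g must lie in [0, 1]")
        if self.form not in _COMPARATORS:
            raise KeyError(
                f"unknown comparator form {self.form!r}; "
                f"registered: {sorted(_COMPARATORS)}"
            )


def comparator_correction(
    kappa_cbl: float, kappa_bg_ctx: float, spec: ComparatorSpec, weights=(1.0, 0.0, 0.0)
) -> float:
    """Comparator value C(κ_CBL, κ_BG+CTX) for the given spec."""
    if kappa_cbl <= 0 or kappa_bg_ctx <= 0:
        raise ValueError("comparator inputs must be positive")
    return float(_COMPARATORS[spec.form](kappa_cbl, kappa_bg_ctx, spec.g, weights))


def total_gain_multiplicative(
    gains: ComponentGains, weights, spec: ComparatorSpec = ComparatorSpec()
) -> float:
    """Total gain κ = κ_BG^w_bg · κ_CTX^w_ctx · C(κ_CBL, κ_BG+CTX)."""
    _, w_bg, w_ctx = weights
    kappa_bg_ctx = combined_background_gain(gains, weights)
    c = comparator_correction(gains.kappa_cbl, kappa_bg_ctx, spec, weights)
    return float(gains.kappa_bg ** w_bg * gains.kappa_ctx ** w_ctx * c)


def total_gain_loglinear(
    gains: ComponentGains, weights, spec: ComparatorSpec = ComparatorSpec()
) -> float:
    """ln κ as the weighted sum of log gains plus ln C (log-space form)."""
    _, w_bg, w_ctx = weights
    kappa_bg_ctx = combined_background_gain(gains, weights)
    c = comparator_correction(gains.kappa_cbl, kappa_bg_ctx, spec, weights)
    return float(
        w_bg * np.log(gains.kappa_bg)
        + w_ctx * np.log(gains.kappa_ctx)
        + np.log(c)
    )


def compose_trajectory(
    cbl: GainTrajectory,
    bg: GainTrajectory,
    ctx: GainTrajectory,
    tau: float,
    profile: WeightProfile = WeightProfile(),
    spec: ComparatorSpec = ComparatorSpec(),
) -> GainTrajectory:
    """Pointwise composition of three component gain trajectories.

    All three trajectories must share one time grid; weights are evaluated
    once at the task's interval duration tau.
    """
    if not (
        np.array_equal(cbl.t, bg.t) and np.array_equal(bg.t, ctx.t)
    ):
        raise ValueError("component trajectories must share one time grid")
    w = weights_at(tau, profile)
    _, w_bg, w_ctx = w
    kappa_bg_ctx = bg.kappa ** w_bg * ctx.kappa ** w_ctx
    c = np.array(
        [
            _COMPARATORS[spec.form](kc, kb, spec.g, w)
            for kc, kb in zip(cbl.kappa, kappa_bg_ctx)
        ]
    )
    kappa = bg.kappa ** w_bg * ctx.kappa ** w_ctx * c
    return GainTrajectory(grid=TimeGrid(cbl.t), d_r=kappa - 1.0)
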