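"""Scalar subjective-time quantities and the damped restoring dynamics.

The model describes subjective time as objective time scaled by a gain
factor κ(t):  Δt⁽ˢ⁾ = κ(t)·Δt.  κ > 1 means subjective dilation (events
feel longer), κ < 1 compression.  The mismatch between subjective and
objective clock periods is summarized by the relative deviation
D_r(t) = κ(t) − 1 and the precision P(t) = 1/|D_r(t)|.

The brain's regulatory loop is modeled as a damped restoring force on D_r:

    D_r'' = −a·D_r − b·D_r'      (a > 0 restoring, b > 0 damping)

which for b² ≥ 4a relaxes D_r smoothly (non-oscillatory) back to 0, i.e.
κ back to 1.  This module provides the exact analytic solution of that
linear ODE for all three damping branches, a bit-reproducible fixed-step
RK4 integrator that additionally accepts an external "challenge" forcing
u(t) (the perturbation epoch that drives D_r away from 0), and the change
of variable κ = 1 + D_r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "DynamicsParams",
    "DeviationState",
    "ChallengeProtocol",
    "GainTrajectory",
    "subjective_interval",
    "subjective_period",
    "absolute_deviation",
    "relative_deviation",
    "precision",
    "precision_regularized",
    "damping_regime",
    "solve_deviation_closed_form",
    "integrate_deviation",
    "gain_dynamics",
]

#: Sentinel returned by :func:`precision` at D_r = 0 (perfect timing).
INF = np.inf


def _as_grid(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(t)):
        raise ValueError("time grid must be finite")
    if t[0] < 0:
        raise ValueError("time grid must start at t >= 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    return t


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sample times in seconds, first element >= 0."""

    t: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", _as_grid(self.t))

    @classmethod
    def regular(cls, t_end: float, dt: float, t_start: float = 0.0) -> "TimeGrid":
        """Uniform grid [t_start, t_end] with spacing dt (end point included)."""
        if dt <= 0 or t_end <= t_start:
            raise ValueError("need dt > 0 and t_end > t_start")
        n = int(round((t_end - t_start) / dt))
        return cls(t_start + dt * np.arange(n + 1))

    def __len__(self):
        return self.t.size


@dataclass(frozen=True)
class DynamicsParams:
    """Restoring coefficient a (1/s²) and damping coefficient b (1/s).

    Only the ratios matter under a rescaling of time: (a, b) at t and
    (a/c², b/c) at c·t generate the same trajectory shape.
    """

    a: float
    b: float

    def __post_init__(self):
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"restoring coefficient a must be > 0, got {self.a}")
        if not (np.isfinite(self.b) and self.b > 0):
            raise ValueError(f"damping coefficient b must be > 0, got {self.b}")

    @property
    def discriminant(self) -> float:
        return self.b * self.b - 4.0 * self.a


@dataclass(frozen=True)
class DeviationState:
    """Initial condition: relative deviation D_r and its time derivative."""

    d_r: float
    dd_r: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.d_r) and np.isfinite(self.dd_r)):
            raise ValueError("deviation state must be finite")
        if self.d_r <= -1.0:
            raise ValueError("D_r must exceed -1 (kappa must stay positive)")


@dataclass(frozen=True)
class ChallengeProtocol:
    """External perturbation epoch driving D_r away from equilibrium.

    The forcing enters the dynamics additively: D_r'' = −a·D_r − b·D_r' + u(t).

    shape="step": u = a·amplitude on [onset, onset+duration), so `amplitude`
    is the steady-state deviation the challenge pulls toward while active.
    shape="ramp": u rises linearly from 0 to a·amplitude over the epoch.
    shape="impulse": an instantaneous velocity kick dD_r += amplitude at
    onset (duration ignored).
    """

    onset: float
    duration: float
    amplitude: float
    shape: str = "step"

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("challenge onset must be >= 0")
        if self.duration < 0:
            raise ValueError("challenge duration must be >= 0")
        if self.shape not in ("step", "ramp", "impulse"):
            raise ValueError(f"unknown challenge shape {self.shape!r}")

    def forcing(self, t: float, a: float) -> float:
        """Forcing term u(t) for restoring coefficient a."""
        if self.shape == "impulse":
            return 0.0
        if self.onset <= t < self.onset + self.duration:
            if self.shape == "step":
                return a * self.amplitude
            frac = (t - self.onset) / self.duration if self.duration > 0 else 1.0
            return a * self.amplitude * frac
        return 0.0

    def breakpoints(self) -> tuple[float, ...]:
        if self.shape == "impulse":
            return (self.onset,)
        return (self.onset, self.onset + self.duration)


@dataclass
class GainTrajectory:
    """Sampled gain κ(t) with the derived deviation and precision.

    Invariants: kappa = 1 + d_r elementwise; precision = 1/|d_r| with an
    infinity sentinel wherever d_r = 0.
    """

    grid: TimeGrid
    d_r: np.ndarray
    dd_r: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.d_r = np.asarray(self.d_r, dtype=float)
        if self.d_r.shape != self.grid.t.shape:
            raise ValueError("d_r and time grid shapes differ")
        if np.any(self.d_r <= -1.0):
            warnings.warn(
                "trajectory crosses D_r = -1 (kappa <= 0): subjective-time "
                "rate is no longer physically meaningful",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def t(self) -> np.ndarray:
        return self.grid.t

    @property
    def kappa(self) -> np.ndarray:
        return 1.0 + self.d_r

    @property
    def precision(self) -> np.ndarray:
        return precision(self.d_r)

    def summary(self) -> dict:
        p = self.precision
        finite = p[np.isfinite(p)]
        return {
            "mean_kappa": float(np.mean(self.kappa)),
            "mean_abs_d_r": float(np.mean(np.abs(self.d_r))),
            "mean_finite_precision": float(np.mean(finite)) if finite.size else INF,
        }

    def to_frame(self):
        """Trajectory as a DataFrame with columns t, d_r, kappa, precision."""
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "d_r": self.d_r, "kappa": self.kappa,
             "precision": self.precision}
        )


# ---------------------------------------------------------------------------
# scalar quantities


def _check_positive(name, value):
    value = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(value)) or np.any(value <= 0):
        raise ValueError(f"{name} must be positive and finite")
    return value


def subjective_interval(kappa, dt):
    """Subjective duration of an objective interval dt under gain kappa.

    Returns kappa * dt; kappa > 1 dilates, kappa < 1 compresses.
    """
    kappa = _check_positive("kappa", kappa)
    dt = np.asarray(dt, dtype=float)
    if np.any(~np.isfinite(dt)) or np.any(dt < 0):
        raise ValueError("dt must be non-negative and finite")
    out = kappa * dt
    return float(out) if out.ndim == 0 else out


def subjective_period(kappa, tau_p):
    """Subjective clock period for objective reference period tau_p (s)."""
    kappa = _check_positive("kappa", kappa)
    tau_p = _check_positive("tau_p", tau_p)
    out = kappa * tau_p
    return float(out) if out.ndim == 0 else out


def absolute_deviation(tau_s, tau_p):
    """D_a = subjective minus objective clock period, in seconds."""
    tau_s = _check_positive("tau_s", tau_s)
    tau_p = _check_positive("tau_p", tau_p)
    out = tau_s - tau_p
    return float(out) if out.ndim == 0 else out


def relative_deviation(kappa):
    """D_r = kappa − 1, the normalized period mismatch."""
    kappa = _check_positive("kappa", kappa)
    out = kappa - 1.0
    return float(out) if out.ndim == 0 else out


def precision(d_r):
    """P = 1/|D_r|; returns the infinity sentinel where D_r = 0."""
    d_r = np.asarray(d_r, dtype=float)
    if np.any(~np.isfinite(d_r)):
        raise ValueError("d_r must be finite")
    with np.errstate(divide="ignore"):
        out = np.where(d_r == 0.0, INF, 1.0 / np.abs(d_r))
    return float(out) if out.ndim == 0 else out


def precision_regularized(d_r, eps: float = 1e-6):
    """Finite precision variant P_eps = 1/max(|D_r|, eps), for plotting/fitting."""
    d_r = np.asarray(d_r, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    out = 1.0 / np.maximum(np.abs(d_r), eps)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# restoring dynamics

#: relative tolerance deciding the critically damped branch
_CRIT_RTOL = 1e-12


def damping_regime(params: DynamicsParams) -> str:
    """Classify (a, b) by the sign of b² − 4a.

    Underdamped parameters are admissible but produce oscillatory
    restoration, which the model treats as unintended; a RuntimeWarning is
    emitted in that case.
    """
    disc = params.discriminant
    scale = max(params.b * params.b, 4.0 * params.a)
    if abs(disc) <= _CRIT_RTOL * scale:
        return "critical"
    if disc > 0:
        return "overdamped"
    warnings.warn(
        "underdamped parameters (b^2 < 4a): restoration will oscillate "
        "around D_r = 0",
        RuntimeWarning,
        stacklevel=2,
    )
    return "underdamped"


def _closed_form_funcs(params: DynamicsParams, state0: DeviationState):
    """Return callables (D_r(t), D_r'(t)) for the homogeneous solution."""
    a, b = params.a, params.b
    d0, v0 = state0.d_r, state0.dd_r
    disc = params.discriminant
    scale = max(b * b, 4.0 * a)

    if abs(disc) <= _CRIT_RTOL * scale:  # critically damped
        r = -0.5 * b
        c2 = v0 - r * d0

        def f(t):
            return (d0 + c2 * t) * np.exp(r * t)

        def df(t):
            return (c2 + r * (d0 + c2 * t)) * np.exp(r * t)

    elif disc > 0:  # overdamped: two real decaying exponentials
        s = np.sqrt(disc)
        r1, r2 = 0.5 * (-b + s), 0.5 * (-b - s)
        c1 = (v0 - r2 * d0) / (r1 - r2)
        c2 = d0 - c1

        def f(t):
            return c1 * np.exp(r1 * t) + c2 * np.exp(r2 * t)

        def df(t):
            return c1 * r1 * np.exp(r1 * t) + c2 * r2 * np.exp(r2 * t)

    else:  # underdamped: damped cosine
        alpha = -0.5 * b
        omega = 0.5 * np.sqrt(-disc)
        c2 = (v0 - alpha * d0) / omega

        def f(t):
            return np.exp(alpha * t) * (d0 * np.cos(omega * t) + c2 * np.sin(omega * t))

        def df(t):
            e = np.exp(alpha * t)
            cos, sin = np.cos(omega * t), np.sin(omega * t)
            return e * (
                alpha * (d0 * cos + c2 * sin) + omega * (-d0 * sin + c2 * cos)
            )

    return f, df


def solve_deviation_closed_form(
    params: DynamicsParams, state0: DeviationState, grid: TimeGrid
) -> GainTrajectory:
    """Exact analytic solution of D_r'' = −a·D_r − b·D_r' on the grid.

    Uses the branch matching the damping regime (two real exponentials,
    critically damped, or damped cosine).  The trajectory converges to
    D_r = 0, i.e. the regulatory loop restores objective timing.
    """
    f, df = _closed_form_funcs(params, state0)
    t = grid.t
    return GainTrajectory(grid=grid, d_r=f(t), dd_r=df(t))


def _max_step(params: DynamicsParams) -> float:
    # fixed step keeps runs bit-reproducible; bound tied to the fastest
    # timescale so RK4 truncation error stays ~1e-9 over t in [0, 10]
    rate = max(np.sqrt(params.a), params.b)
    return min(0.01, 0.03 / rate)


def integrate_deviation(
    params: DynamicsParams,
    state0: DeviationState,
    grid: TimeGrid,
    forcing: ChallengeProtocol | None = None,
    equilibrium=None,
) -> GainTrajectory:
    """Fixed-step RK4 solution of D_r'' = −a(D_r − D_eq(t)) − b·D_r' + u(t).

    With ``forcing=None`` and ``equilibrium=None`` this solves the pure
    restoring dynamics and agrees with :func:`solve_deviation_closed_form`
    to better than 1e−8 absolute error over t ∈ [0, 10].

    Parameters
    ----------
    forcing
        Optional challenge protocol providing the additive term u(t).
    equilibrium
        Optional callable D_eq(t) (or constant) the restoring force pulls
        toward instead of 0; used when a composed multi-system gain sets a
        non-zero instantaneous equilibrium.
    """
    a, b = params.a, params.b
    t_grid = grid.t

    if equilibrium is None:
        d_eq = lambda t: 0.0  # noqa: E731
    elif callable(equilibrium):
        d_eq = equilibrium
    else:
        const = float(equilibrium)
        d_eq = lambda t: const  # noqa: E731

    u = (lambda t: 0.0) if forcing is None else (lambda t: forcing.forcing(t, a))

    def rhs(t, y):
        d, v = y
        return np.array([v, -a * (d - d_eq(t)) - b * v + u(t)])

    # integration nodes: grid points plus forcing breakpoints, so RK4 never
    # steps across a discontinuity of u(t)
    nodes = list(t_grid)
    impulses = []
    if forcing is not None:
        for bp in forcing.breakpoints():
            if t_grid[0] < bp < t_grid[-1]:
                nodes.append(bp)
        if forcing.shape == "impulse":
            impulses.append(forcing.onset)
    nodes = np.unique(np.asarray(nodes, dtype=float))

    h_max = _max_step(params)
    y = np.array([state0.d_r, state0.dd_r], dtype=float)
    out = np.empty_like(t_grid)
    grid_idx = 0
    if nodes[0] == t_grid[0]:
        out[grid_idx] = y[0]
        grid_idx += 1

    eps = 1e-12
    for t0, t1 in zip(nodes[:-1], nodes[1:]):
        for t_imp in impulses:
            if abs(t_imp - t0) <= eps:
                y[1] += forcing.amplitude
        span = t1 - t0
        n_sub = max(1, int(np.ceil(span / h_max)))
        h = span / n_sub
        t = t0
        for _ in range(n_sub):
            k1 = rhs(t, y)
            k2 = rhs(t + 0.5 * h, y + 0.5 * h * k1)
            k3 = rhs(t + 0.5 * h, y + 0.5 * h * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        if grid_idx < t_grid.size and abs(t1 - t_grid[grid_idx]) <= eps:
            out[grid_idx] = y[0]
            grid_idx += 1

    if grid_idx != t_grid.size:
        raise RuntimeError(
            f"integration failed to visit all grid points "
            f"({grid_idx}/{t_grid.size} recorded)"
        )
    return GainTrajectory(grid=grid, d_r=out)


def gain_dynamics(
    params: DynamicsParams, kappa0: float, dkappa0: float, grid: TimeGrid
) -> GainTrajectory:
    """Solve κ'' = −a(κ − 1) − b·κ' analytically.

    Equivalent to the deviation dynamics under the exact change of variable
    κ = 1 + D_r, so the returned trajectory satisfies
    kappa == 1 + solve_deviation_closed_form(...).d_r pointwise.
    """
    if not (np.isfinite(kappa0) and kappa0 > 0):
        raise ValueError("kappa0 must be positive and finite")
    state0 = DeviationState(d_r=kappa0 - 1.0, dd_r=dkappa0)
    return solve_deviation_closed_form(params, state0, grid)


def restoration_time(params: DynamicsParams, ratio: float = 1e-3) -> float:
    """Time for the slowest decaying mode to shrink by `ratio`.

    Derived from the slowest eigenvalue of the characteristic polynomial
    r² + b·r + a; useful for sizing simulation horizons.
    """
    disc = params.discriminant
    if disc > 0:
        slowest = 0.5 * (params.b - np.sqrt(disc))
    else:
        slowest = 0.5 * params.b
    # margin covers the polynomial prefactor of the critical branch
    return float(-np.log(ratio) / slowest * 2.0)
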