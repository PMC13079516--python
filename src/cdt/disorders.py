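"""Disorder regimes as parameterized presets, scenario simulation and
parameter-level interventions.

Each preset encodes the qualitative direction of the per-system gains
(cerebellum / basal ganglia / cortex) reported for a clinical condition:
the sign of ln κ per system, a precision level, and — for conditions with
unstable timing (schizophrenia, autism spectrum disorder) — a seeded
mean-zero Ornstein–Uhlenbeck process on ln κ that produces temporal
jitter rather than systematic dilation or compression.  Magnitudes are a
user parameter δ (scale of |ln κ|, default 0.2): the clinical literature
constrains directions, not sizes.

A scenario composes the preset's per-system gain paths into a total
gain via the comparator composition, then lets the damped restoring
dynamics relax the total deviation toward that composed equilibrium,
optionally perturbed by a challenge epoch.  Interventions (e.g. raising
comparator gain, as a stand-in for cerebellar neuromodulation) are pure
parameter edits applied from an onset time, after which the scenario is
re-simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import composition as comp
from .core import (
    ChallengeProtocol,
    DeviationState,
    DynamicsParams,
    GainTrajectory,
    TimeGrid,
    integrate_deviation,
)
from .rngs import stream

__all__ = [
    "DisorderPreset",
    "InterventionSpec",
    "ScenarioResult",
    "PRESET_NAMES",
    "preset",
    "simulate_scenario",
    "apply_intervention",
    "classify_regime",
]

_SYSTEMS = ("cbl", "bg", "ctx")

# Direction of ln kappa per system: -1 compressed, 0 neutral, +1 dilated,
# "unstable" = mean-zero OU jitter.  expected_label / expected_precision are
# the regime each preset should classify back to.
_TABLE = {
    "schizophrenia": {
        "directions": {"cbl": "unstable", "bg": 0, "ctx": "unstable"},
        "precision_level": "low",
        "expected_label": "unstable",
        "instability_sd": 0.2,
    },
    "bipolar_mania": {
        "directions": {"cbl": -1, "bg": 0, "ctx": -1},
        "precision_level": "low",
        "expected_label": "compressed",
    },
    "bipolar_depression": {
        "directions": {"cbl": 0, "bg": +1, "ctx": +1},
        "precision_level": "low",
        "expected_label": "dilated",
    },
    "major_depression": {
        "directions": {"cbl": 0, "bg": +1, "ctx": +1},
        "precision_level": "low",
        "expected_label": "dilated",
    },
    "anxiety_ptsd": {
        "directions": {"cbl": +1, "bg": +1, "ctx": +1},
        "precision_level": "low",
        "expected_label": "dilated",
    },
    "asd": {
        "directions": {"cbl": "unstable", "bg": "unstable", "ctx": "unstable"},
        "precision_level": "unstable",
        "expected_label": "unstable",
        "instability_sd": 0.35,
    },
    "parkinsonism": {
        "directions": {"cbl": -1, "bg": +1, "ctx": +1},
        "precision_level": "low",
        "expected_label": "dilated",  # supra-second side; compressed below 1 s
    },
    "null": {
        "directions": {"cbl": 0, "bg": 0, "ctx": 0},
        "precision_level": "normal",
        "expected_label": "normal",
    },
}

PRESET_NAMES = tuple(n for n in _TABLE if n != "null")


@dataclass(frozen=True)
class DisorderPreset:
    name: str
    directions: dict
    precision_level: str
    delta: float = 0.2
    instability_sd: float = 0.2
    seed: int = 0
    #: OU correlation time of unstable ln kappa paths, seconds
    tau_ou: float = 1.0
    #: optional list of (start, end) threat epochs; None = tonic bias
    threat_epochs: tuple | None = None
    expected_label: str = ""

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("magnitude delta must be > 0")

    @property
    def gains(self) -> comp.ComponentGains:
        """Nominal constant gains; unstable entries are reported at their
        process mean (ln kappa = 0)."""
        vals = {}
        for s in _SYSTEMS:
            d = self.directions[s]
            vals[s] = 1.0 if d == "unstable" else float(np.exp(d * self.delta))
        return comp.ComponentGains(
            kappa_cbl=vals["cbl"], kappa_bg=vals["bg"], kappa_ctx=vals["ctx"]
        )

    def _epoch_mask(self, t: np.ndarray) -> np.ndarray:
        if self.threat_epochs is None:
            return np.ones_like(t, dtype=bool)
        mask = np.zeros_like(t, dtype=bool)
        for start, end in self.threat_epochs:
            mask |= (t >= start) & (t < end)
        return mask

    def gain_paths(self, grid: TimeGrid) -> dict:
        """Per-system ln-kappa sample paths on the grid (seeded)."""
        t = grid.t
        mask = self._epoch_mask(t)
        paths = {}
        for s in _SYSTEMS:
            d = self.directions[s]
            if d == "unstable":
                rng = stream(self.seed, "preset", self.name, s)
                paths[s] = _ou_path(t, self.instability_sd, self.tau_ou, rng)
            else:
                ln_k = float(d) * self.delta
                paths[s] = np.where(mask, ln_k, 0.0)
        return paths


def _ou_path(t: np.ndarray, sd: float, tau: float, rng) -> np.ndarray:
    """Stationary mean-zero OU process on ln kappa, sampled on t."""
    x = np.empty_like(t)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        rho = np.exp(-dt / tau)
        x[i] = x[i - 1] * rho + rng.normal(0.0, sd * np.sqrt(1.0 - rho * rho))
    return x


def preset(name: str, delta: float = 0.2, seed: int = 0, **kwargs) -> DisorderPreset:
    """Named disorder preset with magnitude delta (|ln kappa| scale)."""
    if name not in _TABLE:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(_TABLE)}")
    row = _TABLE[name]
    return DisorderPreset(
        name=name,
        directions=dict(row["directions"]),
        precision_level=row["precision_level"],
        delta=delta,
        instability_sd=row.get("instability_sd", 0.2),
        seed=seed,
        expected_label=row["expected_label"],
        **kwargs,
    )


@dataclass
class ScenarioResult:
    """Simulated scenario: total gain trajectory plus provenance.

    Carries everything needed to re-simulate (preset, dynamics, challenge,
    composition settings), so interventions can splice a modified run.
    """

    total: GainTrajectory
    components: dict
    preset: DisorderPreset
    dynamics: DynamicsParams
    tau: float
    profile: comp.WeightProfile
    spec: comp.ComparatorSpec
    challenge: ChallengeProtocol | None = None
    label: str = ""
    precision_level: str = ""
    summary: dict = field(default_factory=dict)

    def finalize(self, **classify_kwargs) -> "ScenarioResult":
        self.label, self.precision_level = classify_regime(self, **classify_kwargs)
        self.summary = {
            **self.total.summary(),
            "label": self.label,
            "precision_level": self.precision_level,
        }
        return self


def _equilibrium_deviation(
    paths: dict, tau: float, profile: comp.WeightProfile, spec: comp.ComparatorSpec
) -> np.ndarray:
    """Composed equilibrium D_eq(t) = kappa_eq(t) - 1 from ln-gain paths."""
    w = comp.weights_at(tau, profile)
    w_cbl, w_bg, w_ctx = w
    ln_bg_ctx = w_bg * paths["bg"] + w_ctx * paths["ctx"]
    # default comparator in log space: w_cbl*ln k_cbl - g*ln k_bg_ctx
    kappa_cbl = np.exp(paths["cbl"])
    kappa_bg_ctx = np.exp(ln_bg_ctx)
    c = np.array(
        [
            comp.comparator_correction(kc, kb, spec, w)
            for kc, kb in zip(kappa_cbl, kappa_bg_ctx)
        ]
    )
    return np.exp(ln_bg_ctx) * c - 1.0


def simulate_scenario(
    preset: DisorderPreset,
    dynamics: DynamicsParams = DynamicsParams(a=25.0, b=10.0),
    challenge: ChallengeProtocol | None = None,
    tau: float = 2.0,
    profile: comp.WeightProfile = comp.WeightProfile(),
    spec: comp.ComparatorSpec = comp.ComparatorSpec(),
    grid: TimeGrid | None = None,
    state0: DeviationState | None = None,
) -> ScenarioResult:
    """Simulate a disorder scenario on the grid (default 20 s at 20 ms).

    The preset's per-system gain paths are composed pointwise into an
    instantaneous equilibrium gain; the total deviation then follows the
    damped restoring dynamics toward that equilibrium, starting at the
    equilibrium itself unless `state0` is given, and perturbed by the
    challenge protocol if any.

    Defaults: a critically damped fast regulator (a=25, b=10; 0.2 s time
    constant, so the total gain tracks its composed equilibrium faster
    than pathological fluctuations evolve) on a 60 s grid at 20 ms — long
    enough to estimate fluctuation statistics over many correlation times
    of the unstable presets.
    """
    if grid is None:
        grid = TimeGrid.regular(60.0, 0.02)
    paths = preset.gain_paths(grid)
    d_eq = _equilibrium_deviation(paths, tau, profile, spec)
    eq_fn = lambda t: np.interp(t, grid.t, d_eq)  # noqa: E731
    if state0 is None:
        state0 = DeviationState(d_r=float(d_eq[0]), dd_r=0.0)
    total = integrate_deviation(dynamics, state0, grid, forcing=challenge,
                                equilibrium=eq_fn)
    components = {
        s: GainTrajectory(grid=grid, d_r=np.exp(paths[s]) - 1.0) for s in _SYSTEMS
    }
    result = ScenarioResult(
        total=total,
        components=components,
        preset=preset,
        dynamics=dynamics,
        tau=tau,
        profile=profile,
        spec=spec,
        challenge=challenge,
    )
    return result.finalize()


@dataclass(frozen=True)
class InterventionSpec:
    """A parameter edit applied from `onset` seconds into a scenario.

    target: one of comparator_gain, damping_b, restoring_a, component_kappa.
    delta: signed change (added to g, b or a; multiplies the component gain
    by exp(delta) for component_kappa).
    """

    target: str
    delta: float
    onset: float = 0.0
    system: str | None = None

    def __post_init__(self):
        if self.target not in (
            "comparator_gain",
            "damping_b",
            "restoring_a",
            "component_kappa",
        ):
            raise ValueError(f"unknown intervention target {self.target!r}")
        if self.target == "component_kappa" and self.system not in _SYSTEMS:
            raise ValueError("component_kappa intervention needs system in "
                             f"{_SYSTEMS}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


def apply_intervention(
    result: ScenarioResult, intervention: InterventionSpec
) -> ScenarioResult:
    """Re-simulate a scenario with parameters modified from `onset` on.

    The pre-onset segment is kept as-is; from onset the trajectory
    continues from its current state under the edited parameters.  All
    edits must respect the type invariants (a, b > 0; g in [0, 1]; κ > 0).
    """
    grid = result.total.grid
    t = grid.t
    onset = intervention.onset
    dynamics, spec = result.dynamics, result.spec

    if intervention.target == "comparator_gain":
        g_new = spec.g + intervention.delta
        if not 0.0 <= g_new <= 1.0:
            raise ValueError(f"intervention drives comparator gain to {g_new}, "
                             "outside [0, 1]")
        spec = replace(spec, g=g_new)
    elif intervention.target == "damping_b":
        dynamics = DynamicsParams(a=dynamics.a, b=dynamics.b + intervention.delta)
    elif intervention.target == "restoring_a":
        dynamics = DynamicsParams(a=dynamics.a + intervention.delta, b=dynamics.b)

    paths = result.preset.gain_paths(grid)
    if intervention.target == "component_kappa":
        paths = dict(paths)
        paths[intervention.system] = paths[intervention.system] + np.where(
            t >= onset, intervention.delta, 0.0
        )

    d_eq = _equilibrium_deviation(paths, result.tau, result.profile, spec)
    eq_fn = lambda tt: np.interp(tt, t, d_eq)  # noqa: E731

    i0 = int(np.searchsorted(t, onset))
    i0 = min(max(i0, 0), t.size - 1)
    pre = result.total.d_r[: i0 + 1]
    dd0 = float(np.gradient(result.total.d_r, t)[i0])
    tail_grid = TimeGrid(t[i0:])
    tail = integrate_deviation(
        dynamics,
        DeviationState(d_r=float(result.total.d_r[i0]), dd_r=dd0),
        tail_grid,
        forcing=None,
        equilibrium=eq_fn,
    )
    d_r = np.concatenate([pre[:-1], tail.d_r])
    total = GainTrajectory(grid=grid, d_r=d_r)
    components = {
        s: GainTrajectory(grid=grid, d_r=np.exp(paths[s]) - 1.0) for s in _SYSTEMS
    }
    out = ScenarioResult(
        total=total,
        components=components,
        preset=result.preset,
        dynamics=dynamics,
        tau=result.tau,
        profile=result.profile,
        spec=spec,
        challenge=result.challenge,
    )
    return out.finalize()


def classify_regime(
    result: ScenarioResult,
    theta: float = 0.05,
    flip_threshold: int = 3,
    precision_low: float = 20.0,
    instability_std: float = 0.12,
):
    """Classify a scenario as (label, precision_level).

    label: "unstable" when the deviation flips sign (with excursions past
    ±theta) at least `flip_threshold` times; else "dilated"/"compressed"
    by the sign of the time-averaged D_r against theta; else "normal".

    precision_level: "unstable" when std(ln kappa) exceeds
    `instability_std`; else "low" when the effective precision
    1/mean(|D_r|) falls below `precision_low` or the regime itself is
    unstable (a sign-flipping deviation degrades timing precision even
    when its average magnitude is modest); else "normal".  The effective
    precision (reciprocal of the mean absolute deviation) is used instead
    of the mean instantaneous 1/|D_r|, whose average diverges whenever
    the trajectory crosses zero.
    """
    d_r = result.total.d_r
    signs = np.sign(d_r[np.abs(d_r) > theta])
    flips = int(np.sum(signs[1:] != signs[:-1])) if signs.size > 1 else 0

    mean_d = float(np.mean(d_r))
    if flips >= flip_threshold:
        label = "unstable"
    elif mean_d > theta:
        label = "dilated"
    elif mean_d < -theta:
        label = "compressed"
    else:
        label = "normal"

    kappa = result.total.kappa
    ln_k_std = float(np.std(np.log(np.maximum(kappa, 1e-12))))
    mean_abs = float(np.mean(np.abs(d_r)))
    p_eff = np.inf if mean_abs == 0 else 1.0 / mean_abs
    if ln_k_std > instability_std:
        precision_level = "unstable"
    elif p_eff < precision_low or label == "unstable":
        precision_level = "low"
    else:
        precision_level = "normal"
    return label, precision_level
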