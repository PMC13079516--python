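"""Forward models turning a gain regime into synthetic task observations.

Four readouts of the internal clock gain κ are modeled:

* interval reproduction — a duration encoded under gain κ_enc and
  reproduced under κ_rep has mean (κ_enc/κ_rep)·Δt, so a pathological
  encoding gain κ < 1 yields short reproductions;
* temporal bisection — probes are judged "long" when the subjective
  duration κ·Δt exceeds the geometric mean of the anchors, so κ > 1
  yields more "long" judgments and an objective bisection point B/κ;
* rhythmic tapping — continuation tapping reproduces the target period
  scaled by κ_enc/κ_rep, with a coefficient of variation that rises as
  precision falls: CV = cv0 + c·|D_r|;
* EEG spectral peak — periodic neural signals scale their period by κ,
  so a spectral peak at base frequency f shifts to f/κ (e.g. the
  individual alpha frequency rises when κ < 1).

Duration noise is multiplicative lognormal (durations are positive and
roughly scalar-timing-like); spectra carry additive Gaussian noise on a
Gaussian peak over a 1/f background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskSpec",
    "SpectralReadout",
    "reproduce_interval",
    "bisection_block",
    "bisection_prob_long",
    "tapping_series",
    "eeg_peak_frequency",
    "synth_psd",
    "detect_peak",
    "generate_task_dataset",
]


def _lognormal_factor(cv: float, size, rng) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and coefficient of
    variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def reproduce_interval(dt, kappa_enc: float, kappa_rep: float = 1.0,
                       noise_cv: float = 0.0, rng=None, size=None):
    """Reproduced duration(s) for stimulus dt (s).

    The stimulus is encoded subjectively as κ_enc·dt; at reproduction the
    accumulated subjective time is compared against that trace under gain
    κ_rep, so the noiseless reproduction is (κ_enc/κ_rep)·dt.  Noise is
    multiplicative lognormal with coefficient of variation noise_cv
    (unit-mean, so the stated mean is exact).
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("dt must be positive")
    if kappa_enc <= 0 or kappa_rep <= 0:
        raise ValueError("gains must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    mean = (kappa_enc / kappa_rep) * dt
    if noise_cv == 0 and size is None:
        out = mean
        return float(out) if out.ndim == 0 else out
    if rng is None:
        raise ValueError("rng required when noise_cv > 0 or size is set")
    shape = size if size is not None else dt.shape
    return mean * _lognormal_factor(noise_cv, shape, rng)


def bisection_prob_long(probe, kappa: float, short_anchor: float,
                        long_anchor: float, sigma_ln: float):
    """P("long" | probe) under the lognormal comparison rule.

    The subjective probe duration κ·Δt is compared to the subjective
    criterion B = sqrt(short·long) (the geometric mean of the anchors,
    the standard parameter-free bisection criterion); judgment noise is
    Gaussian on the log scale with sd sigma_ln.
    """
    from scipy.stats import norm

    probe = np.asarray(probe, dtype=float)
    if not 0 < short_anchor < long_anchor:
        raise ValueError("need 0 < short_anchor < long_anchor")
    if np.any(probe <= 0):
        raise ValueError("probes must be positive")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    criterion = np.sqrt(short_anchor * long_anchor)
    z = np.log(kappa * probe) - np.log(criterion)
    if sigma_ln == 0:
        p = (z > 0).astype(float) + 0.5 * (z == 0)
    else:
        p = norm.cdf(z / sigma_ln)
    return float(p) if p.ndim == 0 else p


def bisection_block(short_anchor: float, long_anchor: float, probes,
                    kappa: float, sigma_ln: float = 0.25,
                    n_per_probe: int = 50, rng=None) -> dict:
    """Simulate a bisection block and fit its psychometric function.

    Returns a dict with the trial table, the empirical P(long) per probe,
    and the fitted objective bisection point (50% "long" duration), whose
    model value is sqrt(short·long)/κ.  The fit is a probit regression of
    choice on log probe duration.
    """
    probes = np.asarray(probes, dtype=float)
    if np.any(probes < short_anchor) or np.any(probes > long_anchor):
        raise ValueError("probes must lie within [short_anchor, long_anchor]")
    if rng is None:
        rng = np.random.default_rng(0)
    p_long = bisection_prob_long(probes, kappa, short_anchor, long_anchor, sigma_ln)
    rows = []
    for probe, p in zip(probes, p_long):
        choices = rng.random(n_per_probe) < p
        for c in choices:
            rows.append((probe, bool(c)))
    trials = pd.DataFrame(rows, columns=["stimulus", "choice_long"])

    grouped = trials.groupby("stimulus")["choice_long"].mean()
    bp = _fit_bisection_point(trials)
    return {
        "trials": trials,
        "p_long": grouped,
        "bisection_point": bp,
        "model_bisection_point": float(np.sqrt(short_anchor * long_anchor) / kappa),
    }


def _fit_bisection_point(trials: pd.DataFrame) -> float:
    """Probit fit of P(long) on ln(stimulus); returns the 50% duration."""
    import statsmodels.api as sm

    x = sm.add_constant(np.log(trials["stimulus"].to_numpy()))
    y = trials["choice_long"].astype(float).to_numpy()
    if y.min() == y.max():  # all-one-response block: 50% point undefined
        return float("nan")
    model = sm.GLM(y, x, family=sm.families.Binomial(sm.families.links.Probit()))
    res = model.fit()
    b0, b1 = res.params
    if b1 == 0:
        return float("nan")
    return float(np.exp(-b0 / b1))


def tapping_series(target_period: float, kappa_enc: float = 1.0,
                   kappa_rep: float = 1.0, cv0: float = 0.05, c: float = 0.5,
                   d_r: float = 0.0, n_taps: int = 100, rng=None) -> np.ndarray:
    """Continuation-phase inter-tap intervals (s).

    Mean interval = (κ_enc/κ_rep)·target_period; the coefficient of
    variation follows the precision-linked law CV = cv0 + c·|D_r|, so
    variability rises as timing precision 1/|D_r| falls.  cv0 is a
    motor/clock noise floor keeping variability physical at D_r = 0.
    """
    if target_period <= 0:
        raise ValueError("target_period must be positive")
    if kappa_enc <= 0 or kappa_rep <= 0:
        raise ValueError("gains must be positive")
    if cv0 < 0 or c < 0:
        raise ValueError("cv0 and c must be >= 0")
    if n_taps < 1:
        raise ValueError("need n_taps >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    mean = (kappa_enc / kappa_rep) * target_period
    cv = cv0 + c * abs(d_r)
    return mean * _lognormal_factor(cv, n_taps, rng)


def eeg_peak_frequency(f_base: float, kappa: float) -> float:
    """Observed spectral peak frequency: f_base / kappa.

    Clock periods scale by κ, so frequencies scale by 1/κ; compression
    (κ < 1) raises the peak (e.g. individual alpha frequency in mania).
    """
    if f_base <= 0 or kappa <= 0:
        raise ValueError("f_base and kappa must be positive")
    return f_base / kappa


@dataclass
class SpectralReadout:
    """A synthetic power spectrum with its detected dominant peak."""

    freq_hz: np.ndarray
    power: np.ndarray
    peak_hz: float = field(init=False)

    def __post_init__(self):
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freq_hz.shape != self.power.shape:
            raise ValueError("freq and power shapes differ")
        self.peak_hz = detect_peak(self.freq_hz, self.power)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freq_hz, "power": self.power})


def detect_peak(freq: np.ndarray, power: np.ndarray, smooth: int = 11) -> float:
    """Dominant peak frequency via smoothed argmax + quadratic interpolation.

    Deterministic given the data: the spectrum is smoothed with a centered
    moving average (window `smooth` bins), the argmax located, and a
    parabola through the three surrounding smoothed bins refines the peak
    to sub-bin resolution.
    """
    freq = np.asarray(freq, dtype=float)
    power = np.asarray(power, dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        sm_power = np.convolve(power, kernel, mode="same")
    else:
        sm_power = power
    i = int(np.argmax(sm_power))
    if 0 < i < freq.size - 1:
        y0, y1, y2 = sm_power[i - 1], sm_power[i], sm_power[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            df = freq[1] - freq[0]
            return float(freq[i] + shift * df)
    return float(freq[i])


def synth_psd(f_peak: float, width: float = 1.0, noise_sd: float = 0.0,
              grid=None, rng=None, background: float = 1.0) -> SpectralReadout:
    """Synthetic unimodal PSD: Gaussian bump at f_peak over a 1/f background.

    Power is clipped at zero after adding seeded Gaussian noise.  The
    stored peak is detected from the emitted spectrum.
    """
    if grid is None:
        grid = np.arange(1.0, 40.0 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    if width <= 0:
        raise ValueError("width must be positive")
    if not (grid[0] <= f_peak <= grid[-1]):
        raise ValueError(f"f_peak={f_peak} lies outside the frequency grid")
    signal = np.exp(-0.5 * ((grid - f_peak) / width) ** 2)
    power = signal + background * 0.1 / grid
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        power = power + rng.normal(0.0, noise_sd, size=grid.shape)
    power = np.maximum(power, 0.0)
    return SpectralReadout(freq_hz=grid, power=power)


@dataclass(frozen=True)
class TaskSpec:
    """Configuration of one synthetic task dataset."""

    task: str
    durations: tuple = (1.0,)
    n_trials: int = 100
    seed: int = 0
    noise: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in ("reproduction", "bisection", "tapping", "eeg"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive")


def _regime_kappa(regime) -> float:
    """Total gain implied by a regime (scenario result, component gains,
    or plain float)."""
    from . import composition as comp

    if regime is None:
        return 1.0
    if isinstance(regime, (int, float)):
        if regime <= 0:
            raise ValueError("kappa must be positive")
        return float(regime)
    if hasattr(regime, "total"):  # ScenarioResult
        return float(np.mean(regime.total.kappa))
    if isinstance(regime, comp.ComponentGains):
        w = comp.weights_at(1.0)
        return comp.total_gain_multiplicative(regime, w)
    raise TypeError(f"cannot derive a gain from {type(regime).__name__}")


def generate_task_dataset(spec: TaskSpec, regime=None, condition: str = "") -> pd.DataFrame:
    """Trial table for a task under a κ regime, with ground truth recorded.

    Columns: task, condition, stimulus, response, seed.  The generative
    gain is stored in ``df.attrs["kappa"]`` for recovery tests.
    """
    from .rngs import stream

    kappa = _regime_kappa(regime)
    rng = stream(spec.seed, "task", spec.task, condition)
    noise = dict(spec.noise)
    rows: list[tuple] = []

    if spec.task == "reproduction":
        cv = noise.get("noise_cv", 0.1)
        for dt in spec.durations:
            resp = reproduce_interval(dt, kappa_enc=kappa, kappa_rep=1.0,
                                      noise_cv=cv, rng=rng, size=spec.n_trials)
            rows += [(spec.task, condition, dt, float(r), spec.seed) for r in resp]
    elif spec.task == "bisection":
        short, long_ = min(spec.durations), max(spec.durations)
        if short == long_:
            raise ValueError("bisection needs two distinct anchor durations")
        probes = np.geomspace(short, long_, 7)
        block = bisection_block(short, long_, probes, kappa,
                                sigma_ln=noise.get("sigma_ln", 0.25),
                                n_per_probe=spec.n_trials, rng=rng)
        for _, row in block["trials"].iterrows():
            rows.append((spec.task, condition, float(row["stimulus"]),
                         float(row["choice_long"]), spec.seed))
    elif spec.task == "tapping":
        period = spec.durations[0]
        taps = tapping_series(period, kappa_enc=kappa,
                              cv0=noise.get("cv0", 0.05),
                              c=noise.get("c", 0.5),
                              d_r=kappa - 1.0,
                              n_taps=spec.n_trials, rng=rng)
        rows += [(spec.task, condition, period, float(x), spec.seed) for x in taps]
    else:  # eeg
        f_base = spec.durations[0]
        f_obs = eeg_peak_frequency(f_base, kappa)
        for _ in range(spec.n_trials):
            psd = synth_psd(f_obs, width=noise.get("width", 1.0),
                            noise_sd=noise.get("noise_sd", 0.05), rng=rng)
            rows.append((spec.task, condition, f_base, psd.peak_hz, spec.seed))

    df = pd.DataFrame(rows, columns=["task", "condition", "stimulus",
                                     "response", "seed"])
    df.attrs["kappa"] = kappa
    df.attrs["spec"] = spec
    return df
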