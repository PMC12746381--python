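"""Population cardiac-stimulation threshold model and exposure-limit math.

A log-normal population distribution of myocardial E-field thresholds
(median 12 V/m, 1st percentile 6 V/m) is combined with a distribution of
dB/dt-over-E conversion ratios to obtain dB/dt thresholds: each sampled
threshold is t = R * E with independent draws (multiplication of
thresholds by ratios; a convolution in log domain). A degenerate ratio
reduces to a closed-form log-normal with the scale shifted by ln R.

Also implements the strength-duration limit curves
rheobase / (1 - exp(-tau/chronaxie)) for E (rheobase 2 V/m) and dB/dt
(rheobase 20 T/s, chronaxie 3 ms) and the effective stimulus duration of
arbitrary sampled waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ThresholdDistribution",
    "RatioDistribution",
    "IECLimitParams",
    "WaveformSpec",
    "DBdtThresholdDistribution",
    "calibrate_lognormal",
    "prob_E_below",
    "dBdt_threshold_distribution",
    "prob_adverse_event",
    "effective_dBdt_limit",
    "iec_E_limit",
    "iec_dBdt_limit",
    "effective_stimulus_duration",
]


@dataclass(frozen=True)
class ThresholdDistribution:
    """Log-normal population distribution of E-field thresholds (V/m)."""

    median: float = 12.0
    anchor_percentile: float = 1.0
    anchor_value: float = 6.0
    sigma_log: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.anchor_percentile < 50):
            raise ValueError("anchor percentile must be in (0, 50)")
        if not (0 < self.anchor_value < self.median):
            raise ValueError("anchor value must be positive and below the median")
        z = stats.norm.ppf(1.0 - self.anchor_percentile / 100.0)
        object.__setattr__(self, "sigma_log", float(np.log(self.median / self.anchor_value) / z))

    def cdf(self, e: float | np.ndarray) -> float | np.ndarray:
        e = np.asarray(e, dtype=float)
        if np.any(e <= 0):
            raise ValueError("E must be positive")
        out = stats.norm.cdf(np.log(e / self.median) / self.sigma_log)
        return float(out) if out.ndim == 0 else out

    def quantile(self, p: float | np.ndarray) -> float | np.ndarray:
        out = self.median * np.exp(self.sigma_log * stats.norm.ppf(p))
        return float(out) if np.ndim(out) == 0 else out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.median * np.exp(self.sigma_log * rng.standard_normal(n))


@dataclass(frozen=True)
class RatioDistribution:
    """Empirical (or degenerate) distribution of dB/dt-over-E ratios."""

    samples: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        s = np.atleast_1d(np.asarray(self.samples, dtype=float))
        if s.size == 0:
            raise ValueError("empty ratio samples")
        if np.any(s <= 0):
            raise ValueError("ratio samples must be positive")
        object.__setattr__(self, "samples", s)

    @classmethod
    def degenerate(cls, ratio: float, source: str = "constant") -> "RatioDistribution":
        return cls(samples=np.array([float(ratio)]), source=source)

    @property
    def is_degenerate(self) -> bool:
        return self.samples.size == 1


@dataclass(frozen=True)
class IECLimitParams:
    """Strength-duration limit parameters."""

    rheobase_E: float = 2.0  # V/m
    chronaxie_ms: float = 3.0
    rheobase_dBdt: float = 20.0  # T/s

    def __post_init__(self) -> None:
        if min(self.rheobase_E, self.chronaxie_ms, self.rheobase_dBdt) <= 0:
            raise ValueError("limit parameters must be positive")

    @property
    def governing_ratio(self) -> float:
        return self.rheobase_dBdt / self.rheobase_E


@dataclass(frozen=True)
class WaveformSpec:
    """Sampled gradient-field waveform (one period)."""

    times: np.ndarray  # s, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size < 3 or t.shape != v.shape:
            raise ValueError("waveform needs >= 3 matched samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


class DBdtThresholdDistribution:
    """Distribution of dB/dt thresholds t = R * E.

    Carries both Monte-Carlo samples and the closed-form mixture CDF: each
    ratio sample contributes a log-normal shifted by ln R, so the CDF is
    the average of per-ratio log-normal CDFs. The mixture path has exact
    tails; the sampled path is for cross-checks and plotting.
    """

    def __init__(
        self,
        e_dist: ThresholdDistribution,
        r_dist: RatioDistribution,
        samples: np.ndarray | None,
    ):
        self.e_dist = e_dist
        self.r_dist = r_dist
        self.samples = samples

    def cdf(self, dBdt: float | np.ndarray) -> float | np.ndarray:
        """Closed-form mixture CDF: mean over ratios of P(E < dBdt / R)."""
        d = np.asarray(dBdt, dtype=float)
        if np.any(d <= 0):
            raise ValueError("dB/dt must be positive")
        e_equiv = d[..., None] / self.r_dist.samples
        out = stats.norm.cdf(
            np.log(e_equiv / self.e_dist.median) / self.e_dist.sigma_log
        ).mean(axis=-1)
        return float(out) if out.ndim == 0 else out

    def empirical_cdf(self, dBdt: float) -> float:
        if self.samples is None:
            raise ValueError("no Monte-Carlo samples were drawn")
        return float(np.mean(self.samples <= dBdt))


def calibrate_lognormal(
    median: float = 12.0, anchor_percentile: float = 1.0, anchor_value: float = 6.0
) -> ThresholdDistribution:
    """Log-normal threshold distribution through (median, anchor quantile)."""
    return ThresholdDistribution(
        median=median, anchor_percentile=anchor_percentile, anchor_value=anchor_value
    )


def prob_E_below(dist: ThresholdDistribution, e: float) -> float:
    """Probability that an individual's threshold is below ``e`` V/m."""
    if e <= 0:
        raise ValueError("E must be positive")
    return float(dist.cdf(e))


def dBdt_threshold_distribution(
    e_dist: ThresholdDistribution,
    r_dist: RatioDistribution,
    n_mc: int = 100_000,
    seed: int = 0,
) -> DBdtThresholdDistribution:
    """Distribution of dB/dt thresholds from independent R and E draws.

    ``n_mc`` >= 1e4 Monte-Carlo samples are drawn with the given seed
    (pass n_mc=0 to skip sampling and use only the closed-form mixture).
    """
    samples = None
    if n_mc:
        if n_mc < 10_000:
            raise ValueError("use n_mc >= 10000 (or 0 for closed form only)")
        rng = np.random.default_rng(seed)
        r = rng.choice(r_dist.samples, size=n_mc, replace=True)
        e = e_dist.sample(n_mc, rng)
        samples = r * e
    return DBdtThresholdDistribution(e_dist, r_dist, samples)


def prob_adverse_event(threshold_dist: DBdtThresholdDistribution, dBdt: float) -> float:
    """Probability that a dB/dt exposure exceeds an individual's threshold.

    Uses the closed-form mixture CDF (exact log-normal tails per ratio
    stratum), not the truncated empirical CDF.
    """
    if dBdt <= 0:
        raise ValueError("dB/dt must be positive")
    return float(threshold_dist.cdf(dBdt))


def effective_dBdt_limit(conversion_ratio: float, params: IECLimitParams | None = None) -> float:
    """dB/dt rheobase implied by a conversion ratio (ratio x E rheobase)."""
    if conversion_ratio <= 0:
        raise ValueError("conversion ratio must be positive")
    params = params if params is not None else IECLimitParams()
    return conversion_ratio * params.rheobase_E


def _strength_duration(rheobase: float, tau_ms: float, chronaxie_ms: float) -> float:
    if tau_ms <= 0:
        raise ValueError("effective stimulus duration must be positive")
    return rheobase / (1.0 - np.exp(-tau_ms / chronaxie_ms))


def iec_E_limit(tau_s_eff_ms: float, params: IECLimitParams | None = None) -> float:
    """E-field limit (V/m) at effective stimulus duration tau (ms)."""
    params = params if params is not None else IECLimitParams()
    return float(_strength_duration(params.rheobase_E, tau_s_eff_ms, params.chronaxie_ms))


def iec_dBdt_limit(tau_s_eff_ms: float, params: IECLimitParams | None = None) -> float:
    """dB/dt limit (T/s) at effective stimulus duration tau (ms)."""
    params = params if params is not None else IECLimitParams()
    return float(_strength_duration(params.rheobase_dBdt, tau_s_eff_ms, params.chronaxie_ms))


def effective_stimulus_duration(w: WaveformSpec) -> float:
    """Peak-to-peak field variation over the max |field derivative| (s).

    First-order finite differences on the sampled waveform; sample the
    ramps with at least ~20 points for accurate results. A bipolar
    trapezoid gives twice its rise time; a sinusoid of period T gives T/pi.
    """
    pp = float(np.max(w.values) - np.min(w.values))
    if pp == 0.0:
        raise ValueError("constant waveform has no effective stimulus duration")
    deriv = np.diff(w.values) / np.diff(w.times)
    max_slope = float(np.max(np.abs(deriv)))
    if max_slope == 0.0:
        raise ValueError("zero maximum derivative")
    return pp / max_slope
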