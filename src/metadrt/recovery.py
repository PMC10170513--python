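"""Residence-time estimators and replica statistics.

Two protocols are implemented on top of a metadynamics deposition record:

*Conformational flooding.*  The acceleration factor α is the running
average over the (bound-basin-confined) run of the exponentiated bias,

    α(t) = ⟨ exp(β·V(s, t)) ⟩_A ,

with β the inverse physical temperature and V(s, t) the hill bias at the
instantaneous CV point, recorded just before each deposition.  The
transition out of the bound basin shows up as an abrupt sign change of
dα/dt: once the system leaves the flooded basin the sampled bias collapses
and the running average turns over.  The transition time t* is therefore
the time of the global maximum of α, and the recovered residence time is
RT_calcd = α_max · t*.

*t_META-D.*  A purely empirical descriptor: the simulation time a
constant-height metadynamics run needs to drive the system to the unbound
state (first record whose unbound flag is set).

Replica campaigns are summarised by the geometric mean τ of the
per-replica estimates (mean of log₁₀ values, SEM with n−1), their
empirical cumulative distribution, and a Kolmogorov–Smirnov check of the
exponential (Poisson rare-event) law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .engine import MetaDTrajectory

#: minutes per picosecond denominator: 1 min = 60 s = 6e13 ps
PS_PER_MINUTE = 6.0e13


class InvalidInputError(ValueError):
    pass


@dataclass
class AlphaSeries:
    """Running acceleration factor aligned with the deposition record."""

    times: np.ndarray
    alpha: np.ndarray
    log_alpha: np.ndarray  # natural log, overflow-safe form
    bound_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RTEstimate:
    """One replica's flooding estimate: RT_calcd = α_max · t*."""

    alpha_max: float
    log10_alpha_max: float
    t_transition: float  # ps
    rt_calcd_ps: float
    converged: bool

    @property
    def rt_calcd_minutes(self) -> float:
        return self.rt_calcd_ps / PS_PER_MINUTE

    @property
    def log10_rt_minutes(self) -> float:
        return self.log10_alpha_max + np.log10(self.t_transition / PS_PER_MINUTE)


@dataclass
class TMetadResult:
    """First-unbound time of a constant-height metadynamics run."""

    t_metad_ps: float
    censored: bool

    @property
    def t_metad_ns(self) -> float:
        return self.t_metad_ps / 1000.0


@dataclass
class ReplicaSummary:
    """Geometric-mean summary of per-replica values (log₁₀ statistics)."""

    values: np.ndarray
    n: int
    log_mean: float  # mean of log10(values)
    sem: float  # SEM of log10(values), sample std over sqrt(n); nan for n=1
    tau: float  # 10**log_mean, the geometric mean

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "log_mean": self.log_mean,
            "sem": self.sem,
            "tau": self.tau,
            "values": list(map(float, self.values)),
        }


@dataclass
class ECDCurve:
    """Empirical cumulative distribution: sorted values vs i/n."""

    values: np.ndarray
    probabilities: np.ndarray


def acceleration_factor(traj: MetaDTrajectory, beta: float) -> AlphaSeries:
    """Running average of exp(β·V) over the deposition record.

    Accumulated in log space (running log-sum-exp) so that β·V of several
    hundred does not overflow: log α_k = logsumexp(β·V_0..k) − log(k+1).
    """
    if len(traj) == 0:
        raise InvalidInputError("empty trajectory")
    v = np.asarray(traj.bias_before, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise InvalidInputError("bias values must be finite and non-negative")
    bv = beta * v
    log_cumsum = np.logaddexp.accumulate(bv)
    log_alpha = log_cumsum - np.log(np.arange(1, len(bv) + 1))
    with np.errstate(over="ignore"):
        alpha = np.exp(log_alpha)
    return AlphaSeries(
        times=np.asarray(traj.times, float),
        alpha=alpha,
        log_alpha=log_alpha,
        bound_mask=~np.asarray(traj.unbound, bool),
    )


def transition_time(series: AlphaSeries) -> tuple[float, float, bool]:
    """Transition time from the α turnover.

    Returns ``(t_star, alpha_max, converged)`` where t* is the time of the
    global maximum of α (earliest, on ties) and ``converged`` is False when
    the maximum sits at the final record — α still rising, no transition
    observed.  Equivalent to locating the sign change of dα/dt for a
    unimodal series.
    """
    if len(series) < 2:
        raise InvalidInputError("alpha series needs at least two records")
    k = int(np.argmax(series.log_alpha))  # argmax returns the first maximum
    converged = k < len(series) - 1
    return float(series.times[k]), float(series.alpha[k]), converged


def rt_calcd(alpha_max: float, t_star: float, converged: bool = True) -> RTEstimate:
    """Recovered residence time RT_calcd = α_max · t* (ps)."""
    if alpha_max < 1.0 or t_star <= 0:
        raise InvalidInputError("need alpha_max >= 1 and t_star > 0")
    return RTEstimate(
        alpha_max=float(alpha_max),
        log10_alpha_max=float(np.log10(alpha_max)),
        t_transition=float(t_star),
        rt_calcd_ps=float(alpha_max * t_star),
        converged=converged,
    )


def flooding_estimate(traj: MetaDTrajectory, beta: float) -> RTEstimate:
    """End-to-end flooding estimate from one well-tempered record."""
    series = acceleration_factor(traj, beta)
    t_star, a_max, converged = transition_time(series)
    est = rt_calcd(max(a_max, 1.0), t_star, converged)
    # for extreme biases alpha overflows the float range; rebuild from logs
    if not np.isfinite(est.alpha_max):
        k = int(np.argmax(series.log_alpha))
        log10_a = series.log_alpha[k] / np.log(10.0)
        est = RTEstimate(
            alpha_max=float("inf"),
            log10_alpha_max=float(log10_a),
            t_transition=t_star,
            rt_calcd_ps=float("inf"),
            converged=converged,
        )
    return est


def t_metad(traj: MetaDTrajectory) -> TMetadResult:
    """Time of the first record flagged unbound (censored if never)."""
    if len(traj) == 0:
        raise InvalidInputError("empty trajectory")
    unbound = np.asarray(traj.unbound, bool)
    if not unbound.any():
        return TMetadResult(t_metad_ps=float(traj.times[-1]), censored=True)
    k = int(np.argmax(unbound))
    return TMetadResult(t_metad_ps=float(traj.times[k]), censored=False)


def aggregate_replicas(values: Sequence[float], n: Optional[int] = None) -> ReplicaSummary:
    """Geometric-mean τ and SEM of log₁₀ values over a replica campaign."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise InvalidInputError("no replica values")
    if np.any(values <= 0) or np.any(~np.isfinite(values)):
        raise InvalidInputError("replica values must be positive and finite")
    n = values.size if n is None else int(n)
    logs = np.log10(values)
    log_mean = float(logs.mean())
    sem = float(logs.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return ReplicaSummary(values=values, n=n, log_mean=log_mean, sem=sem, tau=10.0**log_mean)


def ecd(values: Sequence[float]) -> ECDCurve:
    """Empirical cumulative distribution with probabilities i/n, i=1..n."""
    values = np.sort(np.asarray(list(values), dtype=float))
    if values.size == 0:
        raise InvalidInputError("no values")
    probs = np.arange(1, values.size + 1) / values.size
    return ECDCurve(values=values, probabilities=probs)


def poisson_cdf(x, theta: float, mode: str = "standard"):
    """Exponential (Poisson rare-event) CDF P(x) = 1 − exp(−x/θ).

    ``standard`` applies the formula on the linear scale (θ is the
    characteristic time).  ``as_printed`` mirrors the published figure
    caption, where both the abscissa and θ are log₁₀ values (x = log₁₀
    RT_calcd, θ = log₁₀ τ).  The two modes are numerically different
    parameterisations of the same comparison; outputs always carry the
    mode explicitly.
    """
    if mode not in ("standard", "as_printed"):
        raise ValueError(f"unknown mode {mode!r}")
    if theta <= 0:
        raise ValueError("theta must be positive")
    x = np.asarray(x, dtype=float)
    return 1.0 - np.exp(-x / theta)


def exponentiality_check(values: Sequence[float]) -> tuple[float, float]:
    """One-sample KS test of the values against a fitted exponential.

    The rate is fitted by the sample mean; the p-value uses the standard
    asymptotic KS distribution, which is conservative (biased towards
    accepting exponentiality) when the parameter is estimated from the
    same data — adequate as the qualitative rare-event check used here.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size < 5:
        raise InvalidInputError("need at least 5 values for the exponentiality check")
    if np.any(values <= 0):
        raise InvalidInputError("values must be positive")
    result = stats.kstest(values, "expon", args=(0, values.mean()))
    return float(result.statistic), float(result.pvalue)


_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in _STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


def unpaired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float, str]:
    """Classic pooled-variance Student's t-test.

    Returns ``(t, dof, p, stars)``; stars follow the *** < 0.001,
    ** < 0.01, * < 0.05 convention.  With zero pooled variance, t is 0 for
    equal means and ±inf otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each sample needs at least two observations")
    dof = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / dof
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, dof, 1.0, "ns"
        t = float(np.inf) if a.mean() > b.mean() else float(-np.inf)
        return t, dof, 0.0, "***"
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), dof, float(p), significance_stars(p)
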