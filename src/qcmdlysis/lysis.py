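"""The single-parameter lysis detection procedure.

The detection statistic is the overtone spread of the dissipation traces,

    δD(t) = ΔD₃(t) − ΔD₁₁(t),

which tracks the effective thickness and softness of the bacterial film:
because the shear wave penetrates ~140 nm at the third overtone but only
~70 nm at the eleventh, a tall, soft film of live cells produces a large
spread, while the thin, stiff debris layer left behind by phage-induced
lysis produces almost none.  To cancel sensor-to-sensor sensitivity
differences, δD is normalized to its maximum before the phage (second)
injection.  Classification then looks at the second derivative of the
normalized curve over the period after the final flush: lysed films are
still relaxing downward or beginning survivor regrowth (convex, mostly
positive second derivative), whereas uninfected films grow and saturate
(concave, mostly negative).  The mean (or sum) of the derivative curve
decides the call; a fixed-timepoint readout (default 240 min) and the
fractional δD drop across the injection complement it, and replicate arms
are compared with a Welch two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .traces import PhaseSchedule, QcmdExperiment, get_overtone_series

__all__ = [
    "SpreadSeries",
    "LysisCall",
    "GroupComparison",
    "DegenerateBaselineError",
    "delta_d_spread",
    "normalize_spread",
    "second_derivative",
    "classify_lysis",
    "drop_fraction",
    "readout_at",
    "group_compare",
    "analyze_experiment",
]


class DegenerateBaselineError(ValueError):
    """The pre-injection δD baseline is non-positive (no film formed)."""


#: Default moving-average halfwidth (samples) for derivative smoothing.
#: At the default 0.5-min sampling this is a 10.5-sample ≈ 5-min window,
#: well below the ≥ 10-min time constants of the film dynamics.
DEFAULT_SMOOTHING_HALFWIDTH = 10


@dataclass
class SpreadSeries:
    """A δD (or derived) time series.

    ``value`` is in 1e-6 units when raw, dimensionless once normalized;
    ``t_ref`` records the normalization reference time (start of the
    second injection).
    """

    time: np.ndarray
    value: np.ndarray
    normalized: bool = False
    t_ref: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape or self.time.ndim != 1:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class LysisCall:
    """Outcome of the derivative-based classification of one experiment."""

    label: str  # 'lytic' or 'non_lytic'
    derivative_sum: float  # 1/min²
    derivative_mean: float  # 1/min²
    drop_fraction: float
    readout_240: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class GroupComparison:
    """Welch two-sample comparison of replicate readouts."""

    mean_a: float
    std_a: float
    n_a: int
    mean_b: float
    std_b: float
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str


def delta_d_spread(exp: QcmdExperiment) -> SpreadSeries:
    """Raw overtone spread ``δD(t) = ΔD₃(t) − ΔD₁₁(t)`` (1e-6 units)."""
    d3 = get_overtone_series(exp, 3, "dissipation")
    d11 = get_overtone_series(exp, 11, "dissipation")
    return SpreadSeries(time=exp.time, value=d3 - d11, normalized=False)


def normalize_spread(series: SpreadSeries, t_ref: float) -> SpreadSeries:
    """Normalize δD to its maximum before ``t_ref`` (second injection).

    Scale-invariant and idempotent; raises
    :class:`DegenerateBaselineError` when the pre-injection maximum is not
    positive, which signals that no bacterial film formed.
    """
    pre = series.time < t_ref
    if not pre.any():
        raise ValueError(f"no samples before t_ref = {t_ref} min")
    ref = float(np.max(series.value[pre]))
    if ref <= 0:
        raise DegenerateBaselineError(
            f"maximum δD before {t_ref} min is {ref:g} <= 0; no film baseline"
        )
    return SpreadSeries(
        time=series.time.copy(),
        value=series.value / ref,
        normalized=True,
        t_ref=t_ref,
    )


def second_derivative(
    series: SpreadSeries,
    window: tuple[float, float],
    smoothing_halfwidth: int = DEFAULT_SMOOTHING_HALFWIDTH,
) -> SpreadSeries:
    """Smoothed second time-derivative of the series over ``window``.

    The full series is smoothed with a centered moving average of
    ``2·halfwidth + 1`` samples *before* the window is cut, so samples just
    outside the window inform the smoothed values at its edges (smoothing
    after windowing would bias the boundary slopes, to which the mean of
    the derivative curve is directly sensitive).  The smoothed series is
    then restricted to the half-open window and differentiated with
    central second differences on the uniform grid; the window endpoints
    use one-sided second differences with a stencil stride matched to the
    smoothing scale (a stride-1 one-sided difference of a smoothed series
    is dominated by residual noise, while a wider stride keeps the same
    truncation order).  All second differences, interior and endpoint, are
    exact for quadratics.
    """
    t0, t1 = window
    steps_all = np.diff(series.time)
    h = steps_all[0]
    if not np.allclose(steps_all, h, rtol=1e-6):
        raise ValueError("second_derivative requires a uniform time grid")
    if smoothing_halfwidth < 0:
        raise ValueError("smoothing halfwidth must be >= 0")
    y_full = series.value
    if smoothing_halfwidth > 0:
        y_full = uniform_filter1d(
            y_full, size=2 * smoothing_halfwidth + 1, mode="nearest"
        )
    mask = (series.time >= t0) & (series.time < t1)
    t = series.time[mask]
    y = y_full[mask]
    if len(t) < 5:
        raise ValueError(
            f"window [{t0}, {t1}) retains only {len(t)} samples; need at least 5"
        )
    d2 = np.empty_like(y)
    d2[1:-1] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) / h**2
    q = max(1, smoothing_halfwidth)
    if len(y) < 2 * q + 1:
        q = 1
    d2[0] = (y[2 * q] - 2.0 * y[q] + y[0]) / (q * h) ** 2
    d2[-1] = (y[-1] - 2.0 * y[-1 - q] + y[-1 - 2 * q]) / (q * h) ** 2
    return SpreadSeries(time=t, value=d2, normalized=series.normalized, t_ref=series.t_ref)


def readout_at(series: SpreadSeries, t: float) -> float:
    """Series value at time ``t`` by linear interpolation between samples."""
    if t < series.time[0] or t > series.time[-1]:
        raise ValueError(
            f"readout time {t} min outside the series span "
            f"[{series.time[0]}, {series.time[-1]}]"
        )
    return float(np.interp(t, series.time, series.value))


def drop_fraction(
    norm_series: SpreadSeries,
    schedule: PhaseSchedule,
    settling_buffer: float = 10.0,
) -> float:
    """Fractional δD drop across the phage injection and flush.

    ``1 − min δD / δD(injection start)``, with the minimum searched over
    samples strictly after the start of the second injection, up to
    ``settling_buffer`` minutes past the end of the final flush (to
    capture the post-flush settling of the signal).  Negative values
    signal growth during the injection.
    """
    inj = schedule.phase("second_injection")
    t_hi = (
        schedule.phase("flush_2").end if schedule.has_phase("flush_2") else inj.end
    ) + settling_buffer
    t_hi = min(t_hi, norm_series.time[-1])
    ref = readout_at(norm_series, inj.start)
    if ref <= 0:
        raise DegenerateBaselineError(
            f"δD at injection start is {ref:g} <= 0; cannot form a drop fraction"
        )
    mask = (norm_series.time > inj.start) & (norm_series.time <= t_hi)
    if not mask.any():
        raise ValueError("no samples between injection start and settling window")
    low = float(np.min(norm_series.value[mask]))
    return 1.0 - low / ref


def classify_lysis(
    norm_series: SpreadSeries,
    schedule: PhaseSchedule,
    rule: str = "mean_sign",
    smoothing_halfwidth: int = DEFAULT_SMOOTHING_HALFWIDTH,
    readout_time: float = 240.0,
    settling_buffer: float = 10.0,
) -> LysisCall:
    """Derivative-sign classification of a normalized δD curve.

    The second derivative is computed over the post-final-flush window; the
    experiment is called ``lytic`` iff the chosen statistic (mean or sum of
    the derivative curve) is strictly positive — an exactly zero statistic
    (e.g. a constant curve) is called ``non_lytic``.
    """
    if rule not in ("mean_sign", "sum_sign"):
        raise ValueError(f"unknown decision rule {rule!r}")
    if not norm_series.normalized:
        raise ValueError("classification requires a normalized δD series")
    post_start = (
        schedule.phase("flush_2").end
        if schedule.has_phase("flush_2")
        else schedule.phase("second_injection").end
    )
    window = (post_start, norm_series.time[-1] + 1e-9)
    d2 = second_derivative(norm_series, window, smoothing_halfwidth)
    d_sum = float(np.sum(d2.value))
    d_mean = float(np.mean(d2.value))
    statistic = d_mean if rule == "mean_sign" else d_sum
    label = "lytic" if statistic > 0 else "non_lytic"
    frac = drop_fraction(norm_series, schedule, settling_buffer)
    t_read = min(readout_time, float(norm_series.time[-1]))
    readout = readout_at(norm_series, t_read)
    return LysisCall(
        label=label,
        derivative_sum=d_sum,
        derivative_mean=d_mean,
        drop_fraction=frac,
        readout_240=readout,
        diagnostics={
            "rule": rule,
            "decision_statistic": statistic,
            "post_window": (float(d2.time[0]), float(d2.time[-1])),
            "readout_time": t_read,
            "smoothing_halfwidth": smoothing_halfwidth,
        },
    )


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def group_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparison:
    """Welch two-sample two-tailed t-test between replicate readouts.

    Stars follow the usual mapping (* p<0.05, ** p<0.01, *** p<0.001,
    ``ns`` otherwise).  Unequal variances are assumed throughout because
    sensor-to-sensor variance differs between arms.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb > 0:
        dof = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
    else:
        dof = float(len(a) + len(b) - 2)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    stars = "ns"
    for level, sym in _STAR_LEVELS:
        if p < level:
            stars = sym
            break
    t_stat = float(res.statistic) if np.isfinite(res.statistic) else 0.0
    return GroupComparison(
        mean_a=float(a.mean()),
        std_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        std_b=float(b.std(ddof=1)),
        n_b=len(b),
        t_statistic=t_stat,
        degrees_of_freedom=float(dof),
        p_value=p,
        stars=stars,
    )


def analyze_experiment(
    exp: QcmdExperiment,
    rule: str = "mean_sign",
    smoothing_halfwidth: int = DEFAULT_SMOOTHING_HALFWIDTH,
    readout_time: float = 240.0,
    settling_buffer: float = 10.0,
) -> LysisCall:
    """End-to-end single-experiment analysis: δD → normalize → classify."""
    spread = delta_d_spread(exp)
    t_ref = exp.schedule.phase("second_injection").start
    norm = normalize_spread(spread, t_ref)
    return classify_lysis(
        norm,
        exp.schedule,
        rule=rule,
        smoothing_halfwidth=smoothing_halfwidth,
        readout_time=readout_time,
        settling_buffer=settling_buffer,
    )
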