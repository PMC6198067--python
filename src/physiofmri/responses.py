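"""Event-related autonomic responses: epoching, contrasts, habituation.

Pupil and skin-conductance traces are epoched around stimulus onsets
(window 0-10 s, baseline the mean over the 1 s before onset).  Pupil
curves are expressed as a ratio to baseline — making them unit-free, with
a flat signal giving 1.0 everywhere — while skin conductance is
baseline-subtracted in native microsiemens.  Summary measures per trial
are the area under the deflection curve (trapezoidal, plus the
sum-over-samples variant for comparability with percent-times-samples
reporting) and the curve maximum with its latency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CONGRUENT, INCONGRUENT, EventDesign

logger = logging.getLogger("physiofmri")

#: epoch window after stimulus onset (s)
WINDOW_S = 10.0
#: baseline window before onset (s)
BASELINE_S = 1.0


@dataclass
class TrialResponse:
    """One trial's baseline-referenced response curve and its summaries.

    For pupil the curve is PD(t)/baseline (dimensionless ratio, reference
    level 1); for skin conductance it is SC(t) - baseline in uS
    (reference 0).  ``auc`` integrates (curve - reference) trapezoidally:
    %*s for pupil (deflection in percent), uS*s for SC.  ``auc_samples``
    is the plain sum over samples of the same deflection.
    """

    trial_index: int
    condition: str
    curve: np.ndarray
    baseline: float
    fs: float
    channel: str  # "pupil" | "sc"
    auc: float = field(init=False)
    auc_samples: float = field(init=False)
    peak: float = field(init=False)
    peak_latency: float = field(init=False)

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if not np.isfinite(self.baseline):
            raise ValueError("non-finite baseline")
        reference = 1.0 if self.channel == "pupil" else 0.0
        deflection = self.curve - reference
        if self.channel == "pupil":
            deflection = 100.0 * deflection  # percent of baseline
        self.auc = float(np.trapezoid(deflection, dx=1.0 / self.fs))
        self.auc_samples = float(deflection.sum())
        i = int(np.argmax(self.curve))
        self.peak = float(self.curve[i])
        self.peak_latency = float(i / self.fs)


@dataclass
class ConditionSummary:
    """Across-trial mean response curve and summary measures for one condition."""

    condition: str
    mean_curve: np.ndarray
    sd_curve: np.ndarray
    mean_auc: float
    mean_peak: float
    n_trials: int


@dataclass
class EffectStats:
    """Statistics of a paired comparison, trend or correlation."""

    t_statistic: float = np.nan
    df: int = 0
    p_value: float = np.nan
    r_squared: float = np.nan
    effect_percent: float = np.nan
    slope_sign: int = 0
    degenerate: bool = False
    loo_r_squared: list[float] | None = None


def extract_trial_responses(
    signal: np.ndarray,
    fs: float,
    events: EventDesign,
    channel: str,
    window_s: float = WINDOW_S,
    baseline_s: float = BASELINE_S,
) -> tuple[list[TrialResponse], list[tuple[int, str]]]:
    """Epoch a scan-synchronized signal around each stimulus onset.

    Trials lacking a full baseline (1 s before onset) or response window
    (10 s after) are excluded with a logged reason; included plus excluded
    counts always equal the design total.

    Returns
    -------
    (responses, excluded)
        ``responses`` is one :class:`TrialResponse` per usable trial;
        ``excluded`` lists (trial_index, reason) pairs.
    """
    if channel not in ("pupil", "sc"):
        raise ValueError("channel must be 'pupil' or 'sc'")
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    n_win = int(round(window_s * fs))
    n_base = int(round(baseline_s * fs))

    responses: list[TrialResponse] = []
    excluded: list[tuple[int, str]] = []
    for i, (onset, cond) in enumerate(zip(events.onsets, events.conditions)):
        i0 = int(round(onset * fs))
        if i0 - n_base < 0:
            excluded.append((i, "insufficient pre-onset baseline"))
            logger.warning("trial %d excluded: insufficient pre-onset baseline", i)
            continue
        if i0 + n_win > n:
            excluded.append((i, "insufficient post-onset window"))
            logger.warning("trial %d excluded: insufficient post-onset window", i)
            continue
        baseline = float(signal[i0 - n_base:i0].mean())
        seg = signal[i0:i0 + n_win]
        if channel == "pupil":
            if baseline <= 0:
                excluded.append((i, "non-positive pupil baseline"))
                continue
            curve = seg / baseline
        else:
            curve = seg - baseline
        responses.append(TrialResponse(trial_index=i, condition=str(cond),
                                       curve=curve, baseline=baseline,
                                       fs=fs, channel=channel))
    if not responses:
        raise ValueError("no extractable trials")
    return responses, excluded


def summarize_condition(responses: list[TrialResponse], condition: str
                        ) -> ConditionSummary:
    sel = [r for r in responses if r.condition == condition]
    if not sel:
        raise ValueError(f"no trials in condition {condition!r}")
    curves = np.stack([r.curve for r in sel])
    return ConditionSummary(
        condition=condition,
        mean_curve=curves.mean(axis=0),
        sd_curve=curves.std(axis=0, ddof=1) if len(sel) > 1 else np.zeros(curves.shape[1]),
        mean_auc=float(np.mean([r.auc for r in sel])),
        mean_peak=float(np.mean([r.peak for r in sel])),
        n_trials=len(sel),
    )


def condition_means(responses: list[TrialResponse], measure: str = "auc"
                    ) -> dict[str, float]:
    """Per-condition mean of a trial measure (one subject/session)."""
    out = {}
    for cond in (CONGRUENT, INCONGRUENT):
        vals = [getattr(r, measure) for r in responses if r.condition == cond]
        if vals:
            out[cond] = float(np.mean(vals))
    return out


def paired_t(cc: np.ndarray, ic: np.ndarray) -> EffectStats:
    """Two-sided paired t-test on per-subject values, df = n - 1.

    Zero-variance differences are reported as a degenerate case: t = 0 /
    p = 1 when the mean difference is also zero, infinite t and p = 0
    otherwise.
    """
    cc = np.asarray(cc, dtype=float)
    ic = np.asarray(ic, dtype=float)
    if cc.shape != ic.shape:
        raise ValueError("paired samples must have equal length")
    n = len(cc)
    if n < 3:
        raise ValueError("paired test needs at least 3 subjects")
    d = cc - ic
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if np.all(d == 0):
            return EffectStats(t_statistic=0.0, df=df, p_value=1.0, degenerate=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return EffectStats(t_statistic=t, df=df, p_value=0.0, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return EffectStats(t_statistic=float(t), df=df, p_value=float(p))


def compare_conditions(
    responses_by_subject: list[list[TrialResponse]],
    measure: str = "auc",
) -> EffectStats:
    """Paired comparison of condition means across subjects.

    For each subject the per-condition mean of ``measure`` is computed and
    the congruent-vs-incongruent difference tested with a paired t-test
    (CC - IC, so larger incongruent responses give a negative t).
    """
    cc, ic = [], []
    for resp in responses_by_subject:
        means = condition_means(resp, measure)
        if CONGRUENT not in means or INCONGRUENT not in means:
            raise ValueError("both conditions required for every subject")
        cc.append(means[CONGRUENT])
        ic.append(means[INCONGRUENT])
    return paired_t(np.asarray(cc), np.asarray(ic))


def stroop_effect_percent(cc_value: float, ic_value: float) -> float:
    """Percent increase of a measure from congruent to incongruent trials."""
    if cc_value <= 0:
        raise ValueError("congruent reference value must be positive")
    return 100.0 * (ic_value - cc_value) / cc_value


def habituation_trend(responses: list[TrialResponse], measure: str = "auc"
                      ) -> EffectStats:
    """Decline of responses over trials, standardized to the first trial.

    Ratios measure_i / measure_1 are correlated (Pearson) against the
    trial number; returns r-squared, two-sided p and the slope sign.
    Constant ratios are a documented degenerate case (r-squared 0).
    """
    vals = np.asarray([getattr(r, measure) for r in responses], dtype=float)
    if len(vals) < 4:
        raise ValueError("habituation trend needs at least 4 trials")
    if vals[0] == 0:
        raise ValueError(
            "first-trial value is zero; cannot standardize to the first trial "
            "(consider mean-standardization)")
    ratios = vals / vals[0]
    trial_no = np.arange(1, len(vals) + 1, dtype=float)
    if np.std(ratios) == 0:
        return EffectStats(r_squared=0.0, p_value=np.nan, degenerate=True)
    r, p = stats.pearsonr(trial_no, ratios)
    return EffectStats(r_squared=float(r ** 2), p_value=float(p),
                       slope_sign=int(np.sign(r)), df=len(vals) - 2)


def effect_correlation(x: np.ndarray, y: np.ndarray) -> EffectStats:
    """Pearson correlation of two per-subject effect measures.

    Reports r-squared and two-sided p plus a leave-one-out r-squared list
    as a simple outlier-sensitivity check.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        return EffectStats(r_squared=np.nan, degenerate=True)
    r, p = stats.pearsonr(x, y)
    loo = []
    for i in range(len(x)):
        xi = np.delete(x, i)
        yi = np.delete(y, i)
        if np.std(xi) == 0 or np.std(yi) == 0 or len(xi) < 3:
            loo.append(np.nan)
        else:
            loo.append(float(stats.pearsonr(xi, yi)[0] ** 2))
    return EffectStats(r_squared=float(r ** 2), p_value=float(p),
                       df=len(x) - 2, loo_r_squared=loo)
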