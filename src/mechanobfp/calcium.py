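"""Single-platelet calcium analysis and its linkage to bond mechanics.

A platelet's calcium trace over a ~200 s interrogation session is
normalized to its initial baseline and typed:

* null — basal trace, maximum normalized increase dI_max < 0.05;
* alpha — latency then a spike (fast rise, fast decay, dI_max mostly > 0.5);
* beta — gradual rise to an intermediate level with slow decay.

Mechanics is linked to signaling through the lifetimes that completed
before calcium onset: the longest (t_max), cumulative (sum t_i) and mean
pre-onset lifetime, their correlation with dI_max, and an ROC sweep of
t_max thresholds separating alpha from beta responders (optimal threshold
minimizes false positives + false negatives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AnalyzedCalcium",
    "PreCaStats",
    "normalize_and_peak",
    "classify_calcium",
    "pre_ca_stats",
    "correlate",
    "roc_threshold",
    "segregate_by_unfolding",
]

NULL_DIMAX = 0.05
ALPHA_BETA_AMPLITUDE = 0.5
ALPHA_RISE_TIME_MAX_S = 10.0
ALPHA_HALF_LIFE_MAX_S = 30.0
ONSET_SD_FACTOR = 5.0
ONSET_MIN_FRAMES = 3


@dataclass
class AnalyzedCalcium:
    time: np.ndarray
    intensity: np.ndarray        # normalized, baseline 1
    delta_i_max: float
    onset_time: float | None
    rise_time: float | None      # onset -> peak, s
    decay_half_life: float | None


@dataclass(frozen=True)
class PreCaStats:
    """Statistics of bond lifetimes completed before calcium onset."""

    t_max: float
    sum_t: float
    mean_t: float
    n_lifetimes: int

    def __post_init__(self):
        if self.n_lifetimes > 0:
            if self.t_max > self.sum_t + 1e-12:
                raise ValueError("t_max cannot exceed the cumulative lifetime")


def normalize_and_peak(time, intensity, baseline_fraction: float = 0.05,
                       min_baseline_frames: int = 3) -> AnalyzedCalcium:
    """Normalize a raw trace to its initial-window mean and locate the peak
    and onset.

    Onset = first run of ``ONSET_MIN_FRAMES`` consecutive frames exceeding
    baseline + 5 x baseline noise SD.
    """
    t = np.asarray(time, dtype=float)
    raw = np.asarray(intensity, dtype=float)
    if raw.size < 10:
        raise ValueError("need at least 10 samples")
    nb = max(int(raw.size * baseline_fraction), min_baseline_frames)
    base = raw[:nb].mean()
    if base <= 0:
        raise ValueError("non-positive baseline intensity")
    norm = raw / base
    noise = max(norm[:nb].std(ddof=1), 1e-6)
    d_i_max = float(norm.max() - 1.0)

    above = norm > 1.0 + ONSET_SD_FACTOR * noise
    onset = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= ONSET_MIN_FRAMES:
            onset = float(t[i - ONSET_MIN_FRAMES + 1])
            break

    rise_time = None
    half_life = None
    if onset is not None:
        i_on = int(np.searchsorted(t, onset))
        i_peak = i_on + int(np.argmax(norm[i_on:]))
        rise_time = float(t[i_peak] - onset)
        half = 1.0 + d_i_max / 2.0
        post = norm[i_peak:]
        below = np.flatnonzero(post < half)
        if below.size:
            half_life = float(t[i_peak + below[0]] - t[i_peak])
    return AnalyzedCalcium(time=t, intensity=norm, delta_i_max=d_i_max,
                           onset_time=onset, rise_time=rise_time,
                           decay_half_life=half_life)


def classify_calcium(analyzed: AnalyzedCalcium,
                     null_threshold: float = NULL_DIMAX,
                     amplitude_boundary: float = ALPHA_BETA_AMPLITUDE,
                     rise_time_max: float = ALPHA_RISE_TIME_MAX_S,
                     half_life_max: float = ALPHA_HALF_LIFE_MAX_S) -> str:
    """Type a normalized calcium trace as 'null', 'alpha' or 'beta'.

    Null if dI_max < 0.05.  Alpha requires a spike shape (rise time and
    decay half-life below the configured bounds) and dI_max above the
    alpha/beta amplitude boundary; everything else is beta.
    """
    if analyzed.delta_i_max < null_threshold:
        return "null"
    spike = (analyzed.rise_time is not None and analyzed.rise_time < rise_time_max
             and analyzed.decay_half_life is not None
             and analyzed.decay_half_life < half_life_max)
    if spike and analyzed.delta_i_max > amplitude_boundary:
        return "alpha"
    return "beta"


def pre_ca_stats(lifetimes, end_times, onset_time: float | None) -> PreCaStats:
    """Lifetime statistics over bonds completed before the calcium onset.

    Sessions without onset use the whole-session window.  Raises if the
    onset precedes every contact (empty statistics are flagged as an error
    rather than silently returned).
    """
    tb = np.asarray(lifetimes, dtype=float)
    te = np.asarray(end_times, dtype=float)
    if tb.shape != te.shape:
        raise ValueError("lifetimes and end_times must align")
    if onset_time is not None:
        sel = te <= onset_time
        tb = tb[sel]
    if tb.size == 0:
        raise ValueError("no lifetime completed before onset (empty statistics)")
    return PreCaStats(t_max=float(tb.max()), sum_t=float(tb.sum()),
                      mean_t=float(tb.mean()), n_lifetimes=int(tb.size))


def correlate(delta_i_max, stat):
    """Pearson correlation and linear fit of dI_max against a lifetime
    statistic (null-type platelets are expected to be excluded upstream).

    Returns dict with r, p, slope, intercept.
    """
    y = np.asarray(delta_i_max, dtype=float)
    x = np.asarray(stat, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {"r": float(r), "p": float(p), "slope": float(slope),
            "intercept": float(intercept)}


def roc_threshold(t_max_values, is_alpha):
    """ROC sweep of t_max thresholds separating alpha from beta platelets.

    Classification rule: predict alpha when t_max > t0.  The optimal t0
    minimizes (false positives + false negatives); ties resolve toward the
    smaller (more sensitive) threshold.

    Returns dict with t0, sensitivity, specificity, and the ROC curve
    (fpr, tpr, thresholds arrays) plus auc.
    """
    t = np.asarray(t_max_values, dtype=float)
    y = np.asarray(is_alpha, dtype=bool)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("values and labels must align")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate ROC: both classes must be present")

    # candidate thresholds: below the minimum, each observed value
    cands = np.concatenate(([t.min() - 1e-9], np.unique(t)))
    tpr = np.empty(cands.size)
    fpr = np.empty(cands.size)
    errs = np.empty(cands.size)
    for i, t0 in enumerate(cands):
        pred = t > t0
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = n_pos - tp
        tpr[i] = tp / n_pos
        fpr[i] = fp / n_neg
        errs[i] = fp + fn
    best = int(np.flatnonzero(errs == errs.min())[0])  # smallest t0 on ties
    order = np.lexsort((tpr, fpr))  # proper ROC staircase through ties
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return {
        "t0": float(cands[best]),
        "sensitivity": float(tpr[best]),
        "specificity": float(1.0 - fpr[best]),
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": cands,
        "auc": auc,
    }


def segregate_by_unfolding(records):
    """Group per-platelet records by their (LRRD±, MSD±) unfolding history.

    ``records`` is an iterable of dicts with keys ``lrrd`` (bool), ``msd``
    (bool), ``delta_i_max``, ``t_max``.  Returns a dict keyed by
    ('LRRD+', 'MSD+')-style tuples with group means, counts and the
    occurrence fraction of each combination (multinomial s.e. included).
    """
    from .coop import multinomial_sem

    groups: dict[tuple[str, str], dict] = {}
    recs = list(records)
    if not recs:
        return {}
    for rec in recs:
        key = ("LRRD+" if rec["lrrd"] else "LRRD-",
               "MSD+" if rec["msd"] else "MSD-")
        g = groups.setdefault(key, {"delta_i_max": [], "t_max": []})
        g["delta_i_max"].append(rec["delta_i_max"])
        g["t_max"].append(rec["t_max"])
    n = len(recs)
    counts = [len(g["delta_i_max"]) for g in groups.values()]
    sems = multinomial_sem(counts)
    out = {}
    for (key, g), c, se in zip(groups.items(), counts, sems):
        out[key] = {
            "n": c,
            "fraction": c / n,
            "fraction_se": float(se),
            "mean_delta_i_max": float(np.mean(g["delta_i_max"])),
            "mean_t_max": float(np.mean(g["t_max"])),
        }
    return out
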