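"""Detection and measurement of cycle outcomes and unfolding signatures.

Works on force-time traces (simulated or recorded): classifies each cycle as
no-bond / rupture / lifetime, measures clamp-phase bond lifetimes, and
detects the two unfolding signatures —

* ramped unfolding: a transient force stagnation or drop (kink) during the
  tensile ramp, found where the Savitzky-Golay-smoothed force slope falls
  below a fraction of the nominal loading rate;
* clamped unfolding: an abrupt force drop during the constant-force hold
  that does not collapse to zero (a collapse to zero is dissociation).  The
  released length is the force drop divided by the probe spring constant.

Unfolding lengths in the ramp are measured on the force-extension curve
(extension = target displacement minus probe deflection) either as the
extension jump at the event (converted to released contour length through
the WLC extension fraction at the event force) or as the difference of WLC
contour lengths fitted before and after the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .simulate import ForceTrace
from .wlc import DEFAULT_KBT_PN_NM, DEFAULT_PERSISTENCE_NM, fit_contour_length

__all__ = [
    "UnfoldingEvent",
    "CycleResult",
    "SegmentationError",
    "NotALifetimeError",
    "classify_cycle",
    "measure_lifetime",
    "detect_ramped_unfolding",
    "detect_clamped_unfolding",
    "force_extension_curve",
    "ramped_unfolding_length",
    "analyze_cycle",
]

# detection defaults (exposed as keyword arguments everywhere)
MIN_BOND_FORCE_PN = 5.0
DISSOCIATION_FORCE_PN = 2.0
DISSOCIATION_MIN_S = 0.005
SAVGOL_WINDOW = 21
SAVGOL_ORDER = 3
KINK_SLOPE_FRACTION = 0.3
KINK_MIN_DURATION_S = 0.004
CLAMP_TOLERANCE_PN = 2.0


class SegmentationError(ValueError):
    """Raised when a trace cannot be segmented into cycle phases."""


class NotALifetimeError(ValueError):
    """Raised when a lifetime is requested from a non-lifetime trace."""


@dataclass
class UnfoldingEvent:
    phase: str                      # "ramped" | "clamped"
    length: float                   # nm
    force: float                    # pN at the event (onset)
    t_u: float | None = None        # s since clamp attainment (clamped only)
    time: float | None = None       # s, trace clock
    domain: str = "unassigned"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("unfolding length must be positive")
        if self.phase == "clamped" and (self.t_u is None or self.t_u < 0):
            raise ValueError("clamped events carry a non-negative t_u")


@dataclass
class CycleResult:
    outcome: str                    # "no_bond" | "rupture" | "lifetime"
    bond_lifetime: float | None = None
    rupture_force: float | None = None
    events: list[UnfoldingEvent] = field(default_factory=list)

    def __post_init__(self):
        if self.outcome == "no_bond" and self.events:
            raise ValueError("a no-bond cycle cannot carry unfolding events")
        if self.outcome == "lifetime" and (self.bond_lifetime is None
                                           or self.bond_lifetime < 0):
            raise ValueError("lifetime outcome requires bond_lifetime >= 0")


# ---------------------------------------------------------------------------
# segmentation helpers
# ---------------------------------------------------------------------------

def _smooth(trace: ForceTrace, window: int = SAVGOL_WINDOW,
            order: int = SAVGOL_ORDER) -> np.ndarray:
    n = trace.force.size
    w = min(window if window % 2 else window + 1, n if n % 2 else n - 1)
    if w <= order:
        return trace.force.astype(float)
    return savgol_filter(trace.force, w, order)


def _sustained_run(mask: np.ndarray, min_len: int) -> int | None:
    """Start index of the first run of True at least ``min_len`` long."""
    if min_len <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    idx = np.flatnonzero(mask)
    if idx.size < min_len:
        return None
    # runs: consecutive indices
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], splits + 1))
    ends = np.concatenate((splits, [idx.size - 1]))
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_len:
            return int(idx[s])
    return None


def tensile_onset_index(trace: ForceTrace, smoothed: np.ndarray | None = None) -> int:
    """Index where tensile loading begins (force rises through zero after
    the compressive phase).  Raises :class:`SegmentationError` if the trace
    has no identifiable retraction."""
    f = smoothed if smoothed is not None else _smooth(trace)
    if "retract" in trace.segments:
        i0 = trace.segments["retract"]
    else:
        i0 = int(np.argmin(f))
    after = f[i0:]
    pos = np.flatnonzero(after > 0.0)
    if pos.size == 0:
        raise SegmentationError("no tensile phase found after retraction onset")
    return i0 + int(pos[0])


def _clamp_indices(trace: ForceTrace, clamp_force: float,
                   smoothed: np.ndarray | None = None):
    """(attain, dissociation) sample indices of the clamp plateau.

    Attainment = first sustained approach to the clamp level; dissociation =
    first sustained collapse below the dissociation force afterwards (trace
    end if the hold is censored).
    """
    f = smoothed if smoothed is not None else _smooth(trace)
    dt = 1.0 / trace.sample_rate
    min_run = max(int(DISSOCIATION_MIN_S / dt), 1)
    onset = tensile_onset_index(trace, f)
    attain = _sustained_run(f[onset:] >= clamp_force - CLAMP_TOLERANCE_PN, min_run)
    if attain is None:
        raise NotALifetimeError(
            f"force never reaches the clamp level {clamp_force} pN")
    attain += onset
    diss = _sustained_run(f[attain:] < DISSOCIATION_FORCE_PN, min_run)
    diss = trace.force.size - 1 if diss is None else attain + diss
    return attain, diss


# ---------------------------------------------------------------------------
# outcome classification and lifetime
# ---------------------------------------------------------------------------

def classify_cycle(trace: ForceTrace, min_force: float = MIN_BOND_FORCE_PN) -> str:
    """Classify a cycle as 'no_bond', 'rupture' or 'lifetime'.

    No-bond: peak tensile force below ``min_force``.  Lifetime: the clamp
    level was reached and held.  Rupture: a tensile signal appeared but the
    bond broke during loading (always the case in ramp mode).
    """
    f = _smooth(trace)
    try:
        onset = tensile_onset_index(trace, f)
    except SegmentationError:
        return "no_bond"
    peak = float(f[onset:].max(initial=0.0))
    if peak < min_force:
        return "no_bond"
    if trace.clamp_force is None:
        return "rupture"
    try:
        _clamp_indices(trace, trace.clamp_force, f)
    except NotALifetimeError:
        return "rupture"
    return "lifetime"


def measure_lifetime(trace: ForceTrace, clamp_force: float | None = None) -> float:
    """Bond lifetime t_b: clamp attainment to sustained force collapse (s)."""
    clamp = clamp_force if clamp_force is not None else trace.clamp_force
    if clamp is None:
        raise NotALifetimeError("no clamp level available for this trace")
    attain, diss = _clamp_indices(trace, clamp)
    return float((diss - attain) / trace.sample_rate)


def rupture_force(trace: ForceTrace) -> float:
    """Peak tensile force of a rupture cycle, pN.

    Uses a short smoothing window: the force peak just before rupture is
    brief and a wide filter clips it.
    """
    f = _smooth(trace, 9)
    onset = tensile_onset_index(trace, f)
    return float(f[onset:].max())


# ---------------------------------------------------------------------------
# unfolding detectors
# ---------------------------------------------------------------------------

def detect_clamped_unfolding(trace: ForceTrace, drop_threshold: float = 3.0,
                             clamp_force: float | None = None) -> list[UnfoldingEvent]:
    """Detect abrupt force drops during the clamp hold (MSD unfolding).

    A drop that collapses below the dissociation force is dissociation, not
    unfolding.  The released length is (pre-drop minus post-drop force) /
    spring constant; t_u is the drop onset relative to clamp attainment.
    """
    clamp = clamp_force if clamp_force is not None else trace.clamp_force
    if clamp is None:
        raise NotALifetimeError("clamped detection requires a clamp level")
    fs = _smooth(trace)
    attain, diss = _clamp_indices(trace, clamp, fs)
    # an unfolding drop right at clamp attainment delays the sustained-run
    # attainment estimate (and heavy smoothing can hide the brief approach
    # to the clamp level entirely); locate the first approach on a lightly
    # smoothed channel
    onset0 = tensile_onset_index(trace, fs)
    f_light = _smooth(trace, 7)
    reached = np.flatnonzero(f_light[onset0:attain + 1] >= clamp - CLAMP_TOLERANCE_PN)
    if reached.size:
        attain = onset0 + int(reached[0])
    dt = 1.0 / trace.sample_rate
    seg = fs[attain:diss]
    raw = trace.force[attain:diss]
    if seg.size < 10:
        return []

    gap = max(int(0.012 / dt), 2)
    step = seg[gap:] - seg[:-gap]
    cand = np.flatnonzero(step < -drop_threshold)
    # boundary case: a drop at clamp attainment leaves no pre-drop plateau
    # inside the window; flag it against the feedback setpoint
    head = seg[gap: 3 * gap]
    if head.size and (clamp - float(np.median(head))) > drop_threshold:
        if cand.size == 0 or cand[0] > 2 * gap:
            cand = np.concatenate(([0], cand))
    events: list[UnfoldingEvent] = []
    i_prev_end = -10**9
    w_med = max(int(0.012 / dt), 3)
    while cand.size:
        i = int(cand[0])
        # group contiguous candidates belonging to the same drop
        grp_end = i
        j = 0
        while j < cand.size and cand[j] <= grp_end + gap:
            grp_end = int(cand[j])
            j += 1
        cand = cand[j:]
        if i < i_prev_end:
            continue
        # bottom of the drop: minimum of the smoothed force within the
        # feedback response window (a longer lookahead would latch onto a
        # subsequent dissociation collapse)
        look = seg[i: min(i + int(0.018 / dt) + gap, seg.size)]
        i_bot = i + int(np.argmin(look))
        if i >= w_med // 2:
            pre = float(np.median(raw[max(i - w_med - 2, 0): max(i - 2, 1)]))
        else:
            # drop at clamp attainment: no pre-drop plateau exists, the
            # feedback setpoint is the pre level
            pre = float(clamp)
        post_lo = max(min(i_bot - w_med // 2, seg.size - 2), 0)
        post_hi = min(i_bot + w_med // 2 + 1, seg.size)
        post = float(np.median(raw[post_lo:post_hi]))
        i_prev_end = i_bot + w_med
        if post < DISSOCIATION_FORCE_PN:
            continue  # dissociation, handled by lifetime measurement
        # an unfolding drop recovers to the clamp level under feedback; a
        # dissociation collapse (possibly smeared by smoothing) does not.
        # If the bond dissociates before feedback recovers, accept the drop
        # as unfolding only when the post level holds clear of the
        # dissociation threshold for >= 12 ms.
        rec_hi = min(i_bot + int(0.12 / dt), seg.size)
        if not np.any(seg[i_bot:rec_hi] >= clamp - CLAMP_TOLERANCE_PN):
            n_hold = int(0.012 / dt)
            hold = raw[i_bot: min(i_bot + n_hold + 1, seg.size)]
            if hold.size <= n_hold or np.percentile(hold, 20) < DISSOCIATION_FORCE_PN + 0.5:
                continue
        drop = pre - post
        if drop < drop_threshold:
            continue
        length = drop / trace.spring_constant
        t_onset = (i + gap // 2) * dt
        events.append(UnfoldingEvent(phase="clamped", length=float(length),
                                     force=pre, t_u=float(t_onset),
                                     time=float((attain + i) * dt)))
    return events


def _marko_siggia_fraction_table(p: float, kbt: float, n: int = 2000):
    """(force, z) interpolation table for the WLC extension fraction."""
    z = np.linspace(1e-6, 0.99, n)
    f = (kbt / p) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return f, z


def detect_ramped_unfolding(trace: ForceTrace,
                            smoothing_window: int = 7,
                            step_threshold: float = 18.0,
                            min_force: float = 5.0,
                            min_length: float = 10.0,
                            block: int = 12,
                            post_guard_extra: int = 8,
                            persistence: float = DEFAULT_PERSISTENCE_NM,
                            kbt: float = DEFAULT_KBT_PN_NM) -> list[UnfoldingEvent]:
    """Detect ramped unfolding kinks via a contour-length transform.

    At the loading rates used here an unfolding kink is a brief force
    stagnation/drop that is hard to call on the force channel alone, so the
    detector works on the force-extension curve: each sample above
    ``min_force`` is mapped to an instantaneous WLC contour length
    Lc(t) = extension / z(force), where z is the Marko-Siggia extension
    fraction.  Along an unperturbed ramp Lc(t) is constant; an unfolding
    event is a step increase.  Steps are called where the difference of
    ``block``-sample means before/after exceeds ``step_threshold`` (nm of
    contour, scaled up when edge effects shorten the windows).  Candidates
    closer than ~10 ms merge into one event measured across the whole group
    (two domains unfolding within too short an interval are unresolvable
    and are reported as one event with the summed length).

    Event lengths are reported as released extension at the event force
    (z x contour step), the scale on which unfolding-length histograms are
    built; events shorter than ``min_length`` (nm) are below the detection
    limit and discarded.
    """
    # phase boundaries on a moderately smoothed channel; the transform
    # itself uses a short window so block means average independent noise
    fs_region = _smooth(trace, 11)
    fs = _smooth(trace, smoothing_window)
    dt = 1.0 / trace.sample_rate
    onset = tensile_onset_index(trace, fs_region)
    if trace.clamp_force is not None:
        # ramp ends at the first approach to the clamp level
        reached = np.flatnonzero(
            fs_region[onset:] >= trace.clamp_force - CLAMP_TOLERANCE_PN)
        end = onset + int(reached[0]) if reached.size else onset + int(
            np.argmax(fs_region[onset:]))
    else:
        end = onset + int(np.argmax(fs_region[onset:]))
    if end - onset < block:
        return []

    # refine the extension origin: locate the zero-force crossing on a
    # heavily smoothed force channel (single-sample jitter in the origin
    # biases the whole transform)
    n = trace.force.size
    w_ref = min(41, n if n % 2 else n - 1)
    f_heavy = savgol_filter(trace.force, w_ref, SAVGOL_ORDER)
    back = max(onset - 15, 0)
    crossing = np.flatnonzero(f_heavy[back:end] > 0.0)
    if crossing.size:
        onset = back + int(crossing[0])

    # smoothed extension channel (target is noiseless; probe carries the
    # force noise)
    w = min(smoothing_window if smoothing_window % 2 else smoothing_window + 1,
            n if n % 2 else n - 1)
    probe_s = savgol_filter(trace.probe_nm, w, SAVGOL_ORDER)
    ext = (trace.target_nm[onset:end] - trace.target_nm[onset]) - (
        probe_s[onset:end] - probe_s[onset])
    f_seg = fs[onset:end]

    f_tab, z_tab = _marko_siggia_fraction_table(persistence, kbt)

    sel = np.flatnonzero(f_seg > min_force)
    if sel.size < block:
        return []
    z_seg = np.interp(f_seg[sel], f_tab, z_tab)
    # asymmetric guards: the pre side only needs to clear the smoothing
    # smear; the post side must also skip the feedback/reload transient,
    # during which the lagging force estimate inflates the transform
    guard = max(w // 2, 2)
    g_post = guard + post_guard_extra
    m = sel.size
    merge_gap = max(int(0.010 / dt), 3) + guard
    nominal_var = 2.0 / block

    cs = np.concatenate(([0.0], np.cumsum(ext[sel] / z_seg)))

    def block_mean(a, b):
        return (cs[b] - cs[a]) / (b - a)

    d = np.full(m, -np.inf)
    thr = np.full(m, np.inf)
    for i in range(m):
        a0, a1 = max(i - guard - block, 0), i - guard
        b0, b1 = i + g_post, min(i + g_post + block, m)
        n1, n2 = a1 - a0, b1 - b0
        if n1 < 4 or n2 < 4:
            continue
        d[i] = block_mean(b0, b1) - block_mean(a0, a1)
        thr[i] = step_threshold * np.sqrt((1.0 / n1 + 1.0 / n2) / nominal_var)

    cand = np.flatnonzero(d > thr)
    events: list[UnfoldingEvent] = []
    if cand.size == 0:
        return events
    splits = np.flatnonzero(np.diff(cand) > merge_gap)
    starts = np.concatenate(([0], splits + 1))
    ends_ = np.concatenate((splits, [cand.size - 1]))
    for s, e in zip(starts, ends_):
        grp = cand[s: e + 1]
        # the d plateau is centered on the step (or spans both steps of an
        # unresolvable pair); anchor the measurement windows at its peak
        i_star = int(grp[np.argmax(d[grp])])
        a0, a1 = max(i_star - guard - block, 0), max(i_star - guard, 1)
        b0, b1 = min(i_star + g_post, m - 1), min(i_star + g_post + block, m)
        if a1 - a0 < 2 or b1 - b0 < 2:
            continue
        dlc = float(block_mean(b0, b1) - block_mean(a0, a1))
        i_trace = onset + int(sel[i_star])
        # unfolding force: extrapolate the pre-branch ramp to the step
        pre_idx = np.arange(a0, a1)
        pre_f = f_seg[sel[a0:a1]]
        if pre_idx.size >= 3:
            slope_b, icpt = np.polyfit(pre_idx, pre_f, 1)
            f_evt = float(icpt + slope_b * (i_star - 1))
        else:
            f_evt = float(np.median(pre_f))
        if f_evt < min_force + 1.0:
            continue
        z_evt = float(np.interp(f_evt, f_tab, z_tab))
        length = z_evt * dlc
        if length < min_length:
            continue
        events.append(UnfoldingEvent(phase="ramped", length=length,
                                     force=f_evt, time=float(i_trace * dt)))
    return events


# ---------------------------------------------------------------------------
# force-extension analysis
# ---------------------------------------------------------------------------

def force_extension_curve(trace: ForceTrace):
    """Molecular extension vs force for the tensile phase.

    Extension = target displacement minus probe deflection, both zeroed at
    the tensile-force onset.  Returns (extension nm, force pN) arrays.
    """
    if trace.probe_nm is None or trace.target_nm is None:
        raise ValueError("probe and target position channels are required")
    fs = _smooth(trace)
    onset = tensile_onset_index(trace, fs)
    if trace.clamp_force is not None:
        try:
            end, _ = _clamp_indices(trace, trace.clamp_force, fs)
        except NotALifetimeError:
            end = onset + int(np.argmax(fs[onset:]))
    else:
        end = onset + int(np.argmax(fs[onset:]))
    ext = (trace.target_nm[onset:end] - trace.target_nm[onset]) - (
        trace.probe_nm[onset:end] - trace.probe_nm[onset])
    return ext, trace.force[onset:end].astype(float)


def _extension_fraction(force: float, p: float, kbt: float) -> float:
    from scipy.optimize import brentq

    if force <= 0:
        return 1.0
    c = force * p / kbt
    return brentq(lambda z: 0.25 / (1 - z) ** 2 - 0.25 + z - c, 0, 1 - 1e-12)


def ramped_unfolding_length(extension, force, event_index: int,
                            method: str = "jump",
                            units: str = "extension",
                            sample_rate: float = 1000.0,
                            persistence: float = DEFAULT_PERSISTENCE_NM,
                            kbt: float = DEFAULT_KBT_PN_NM,
                            min_fit_force: float = 1.0) -> float:
    """Unfolding length (nm) of a ramped event on a force-extension curve.

    method='jump' measures the extension increase across the event at the
    event force; method='delta_Lc' fits WLC contour lengths to the curve
    before and after the event and differences them.  ``units`` selects the
    scale on which the two are reported (and on which they agree): released
    extension at the event force ('extension', the scale of the measured
    unfolding-length histograms) or released contour length ('contour').
    The two scales are related by the WLC extension fraction z(F) at the
    event force: extension jump = z(F) x contour increment.
    """
    x = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    i = int(event_index)
    if not (0 < i < x.size - 1):
        raise ValueError("event index out of range")
    if units not in ("extension", "contour"):
        raise ValueError("units must be 'extension' or 'contour'")

    w = max(int(0.006 * sample_rate), 2)
    pre_sl = slice(max(i - w - 1, 0), i - 1 if i - 1 > 0 else 1)
    f_evt = float(np.median(f[pre_sl])) if f[pre_sl].size else float(f[i - 1])
    z = _extension_fraction(max(f_evt, 0.5), persistence, kbt)

    if method == "jump":
        # post window starts once the force has reloaded to the event level
        j = i + 1
        while j < x.size - 1 and f[j] < f_evt:
            j += 1
        post_sl = slice(j, min(j + w, x.size))
        jump = float(np.median(x[post_sl]) - np.median(x[pre_sl]))
        return jump if units == "extension" else jump / z
    if method == "delta_Lc":
        pre = slice(0, i)
        post = slice(i + 1, x.size)
        out = []
        for sl in (pre, post):
            sel = f[sl] > min_fit_force
            xs, fsel = x[sl][sel], f[sl][sel]
            if xs.size < 4:
                raise ValueError("too few points to fit a WLC branch")
            res = fit_contour_length(xs, fsel, fix_persistence=persistence, kbt=kbt)
            out.append(res.contour_length)
        dlc = float(out[1] - out[0])
        return dlc if units == "contour" else dlc * z
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# one-call cycle analysis
# ---------------------------------------------------------------------------

def analyze_cycle(trace: ForceTrace, min_force: float = MIN_BOND_FORCE_PN,
                  drop_threshold: float = 3.0) -> CycleResult:
    """Classify a cycle and extract its lifetime and unfolding events."""
    outcome = classify_cycle(trace, min_force=min_force)
    if outcome == "no_bond":
        return CycleResult(outcome="no_bond")
    events: list[UnfoldingEvent] = []
    try:
        events.extend(detect_ramped_unfolding(trace))
    except SegmentationError:
        pass
    if outcome == "rupture":
        return CycleResult(outcome="rupture", rupture_force=rupture_force(trace),
                           events=events)
    t_b = measure_lifetime(trace)
    events.extend(detect_clamped_unfolding(trace, drop_threshold=drop_threshold))
    return CycleResult(outcome="lifetime", bond_lifetime=t_b, events=events)
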