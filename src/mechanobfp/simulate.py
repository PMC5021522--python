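"""Synthetic biomembrane-force-probe (BFP) cycle and session generator.

Replaces the instrument: produces force-time traces of repeated
approach/impinge/contact/retract cycles against a receptor-bearing target,
with the statistical structure the downstream analysis assumes, plus
ground-truth labels for validating the detectors.

Mechanical model
----------------
The probe is a linear spring (stiffness ``spring_constant``, pN/nm); force
equals spring constant times probe deflection at every sample.  The
molecular tether is a worm-like chain whose contour length grows by a fixed
increment when a domain unfolds, so ramped unfolding renders as a
WLC-consistent force kink/extension jump, and clamped unfolding as an abrupt
force drop of spring_constant x released extension followed by feedback
recovery.  Bond lifetimes in the clamp are dual-exponential, with separate
parameter sets depending on whether the LRR domain unfolded during the ramp
(the mechanism that couples the two domains); MSD times-to-unfold are
exponential with rate k_u.  Ramped unfolding is modelled as threshold-force
crossing with Gaussian thresholds.

Defaults reflect the study conditions: 0.3 pN/nm spring, 3.3 um/s
retraction (nominal ramp rate ~1000 pN/s), 2 s contact, clamp forces of
10/25/40/60 pN, <20% adhesion, 1 kHz sampling with 1 pN Gaussian force
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import params as ref
from .wlc import WLCParams, wlc_force

__all__ = [
    "SimParams",
    "CalciumCoupling",
    "ForceTrace",
    "UnfoldTruth",
    "GroundTruth",
    "CalciumTrace",
    "simulate_cycle",
    "simulate_outcomes",
    "simulate_session",
]


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters for one experimental condition."""

    spring_constant: float = 0.3          # pN/nm
    retraction_speed: float = 3.3         # um/s
    mode: str = "clamp"                   # "clamp" or "ramp"
    clamp_force: float = 25.0             # pN
    contact_duration: float = 2.0         # s
    impingement_force: float = 25.0       # pN
    adhesion_probability: float = 0.15    # fraction of cycles with a bond
    ligand: str = "A1WT"
    # kinetics; None -> resolved from the reference tables per ligand/force
    msd_unfold_rate: float | None = None          # k_u, 1/s
    lifetime_lrrd_minus: dict | None = None       # {w1, k1, k2}
    lifetime_lrrd_plus: dict | None = None
    # ramped unfolding propensities and Gaussian threshold-force models
    lrrd_probability: float = 0.13
    lrrd_force_mean: float = 15.0         # pN
    lrrd_force_sd: float = 3.0
    msd_ramp_probability: float = 0.10
    msd_ramp_force_mean: float = 12.0
    msd_ramp_force_sd: float = 3.0
    ramp_rupture_probability: float = 0.10  # rupture before clamp, given bond
    # tether / unfolding mechanics
    tether_contour_nm: float = 60.0
    persistence_nm: float = 0.5
    kbt: float = ref.KBT_PN_NM
    unfold_dlc_msd: float = ref.MSD_CONTOUR_LENGTH_NM
    unfold_dlc_lrrd: float = ref.LRRD_CONTOUR_LENGTH_NM
    # acquisition
    noise_sd: float = 1.0                 # pN
    sample_rate: float = 1000.0           # Hz
    feedback_delay_s: float = 0.02        # clamp feedback response delay
    feedback_recovery_s: float = 0.05     # clamp feedback restore time
    rupture_force_mean: float = 60.0      # ramp-mode rupture, pN
    rupture_force_sd: float = 15.0
    max_lifetime_s: float = 20.0          # truncation of rendered clamp hold

    def __post_init__(self):
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if not (0.0 <= self.adhesion_probability <= 1.0):
            raise ValueError("adhesion_probability must lie in [0, 1]")
        if self.mode not in ("clamp", "ramp"):
            raise ValueError("mode must be 'clamp' or 'ramp'")
        if self.sample_rate <= 0 or self.noise_sd < 0:
            raise ValueError("invalid acquisition parameters")
        for d in (self.lifetime_lrrd_minus, self.lifetime_lrrd_plus):
            if d is not None and (d["k1"] <= 0 or d["k2"] <= 0 or not 0 <= d["w1"] <= 1):
                raise ValueError("invalid lifetime parameters")
        if self.msd_unfold_rate is not None and self.msd_unfold_rate < 0:
            raise ValueError("msd_unfold_rate must be non-negative")

    @property
    def ramp_rate(self) -> float:
        """Nominal loading rate spring_constant x retraction speed, pN/s."""
        return self.spring_constant * self.retraction_speed * 1000.0

    @property
    def ku(self) -> float:
        if self.msd_unfold_rate is not None:
            return self.msd_unfold_rate
        return ref.msd_unfold_rate(self.clamp_force)

    def lifetime_params(self, lrrd_unfolded: bool) -> dict:
        if lrrd_unfolded and self.lifetime_lrrd_plus is not None:
            return self.lifetime_lrrd_plus
        if not lrrd_unfolded and self.lifetime_lrrd_minus is not None:
            return self.lifetime_lrrd_minus
        try:
            return ref.lifetime_params(self.ligand, self.clamp_force, lrrd_unfolded)
        except KeyError:
            # fall back to the LRRD- entry (mutant pooling or missing cell)
            return ref.lifetime_params(self.ligand, self.clamp_force, False)


@dataclass(frozen=True)
class CalciumCoupling:
    """Rule coupling the mechanical history to the calcium response.

    An alpha-type response is triggered at the first clamped MSD unfolding
    event in a cycle whose running longest lifetime exceeds
    ``lifetime_threshold``; sessions with lifetime events but no such
    trigger give a beta-type response; sessions without lifetime events
    stay null.
    """

    enabled: bool = True
    lifetime_threshold: float = 2.0   # s
    require_msd_unfold: bool = True
    onset_latency: float = 2.0        # s after the triggering lifetime ends
    alpha_rise_tau: float = 3.0       # alpha-function time-to-peak, s
    beta_rise_tau: float = 30.0
    alpha_amp_base: float = 0.55
    alpha_amp_slope: float = 0.08     # dI_max gain per second of t_max
    beta_probability: float = 0.6     # chance short-lived bonds trigger beta
    beta_amp_base: float = 0.15
    beta_amp_slope: float = 0.03
    amp_noise_sd: float = 0.06
    trace_noise_sd: float = 0.01
    frame_rate: float = 2.0           # Hz


@dataclass
class UnfoldTruth:
    phase: str        # "ramped" | "clamped"
    domain: str       # "MSD" | "LRRD"
    length: float     # nm, extension released at the event force
    time: float       # s; clamped: time since clamp attainment; ramped: since tensile onset
    force: float      # pN at the event
    #: whether the event renders a signature distinguishable from noise or
    #: dissociation: clamped events unfolding within one feedback response
    #: of dissociation collapse with it; ramped kinks below ~6.5 pN release
    #: too little extension to clear the tracking noise
    observable: bool = True


@dataclass
class GroundTruth:
    bond_formed: bool
    outcome: str                    # "no_bond" | "rupture" | "lifetime"
    lifetime: float | None = None   # t_b, s (clamp-phase)
    rupture_force: float | None = None
    events: list[UnfoldTruth] = field(default_factory=list)
    lrrd_unfolded: bool = False
    msd_clamped_unfolded: bool = False
    calcium_type: str | None = None


@dataclass
class ForceTrace:
    """One BFP cycle's sampled channels plus acquisition metadata."""

    time: np.ndarray          # s, uniform grid
    force: np.ndarray         # pN
    probe_nm: np.ndarray      # probe deflection, nm (= force / k, noisy)
    target_nm: np.ndarray     # piezo target displacement, nm
    mode: str
    spring_constant: float
    sample_rate: float
    clamp_force: float | None = None
    segments: dict = field(default_factory=dict)  # stage name -> start index

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class CalciumTrace:
    time: np.ndarray
    intensity: np.ndarray     # normalized, baseline 1
    ca_type: str              # ground-truth label
    onset_time: float | None
    delta_i_max: float


# ---------------------------------------------------------------------------
# statistical skeleton (shared by trace rendering and the fast path)
# ---------------------------------------------------------------------------

def _extension_fraction(force: float, persistence: float, kbt: float) -> float:
    """z = x/Lc at the given force for a Marko-Siggia chain (root find)."""
    from scipy.optimize import brentq

    if force <= 0:
        return 0.0
    c = force * persistence / kbt

    def g(z):
        return 0.25 / (1.0 - z) ** 2 - 0.25 + z - c

    return brentq(g, 0.0, 1.0 - 1e-12)


def _draw_cycle_truth(params: SimParams, rng: np.random.Generator) -> GroundTruth:
    """Draw the latent outcome of one cycle (no trace rendering)."""
    if rng.random() >= params.adhesion_probability:
        return GroundTruth(bond_formed=False, outcome="no_bond")

    events: list[UnfoldTruth] = []
    # ramped unfolding thresholds (pN); event occurs if the ramp reaches them
    peak = params.clamp_force if params.mode == "clamp" else None
    rupture_f = None
    lrrd = False

    if params.mode == "ramp":
        rupture_f = float(np.clip(
            rng.normal(params.rupture_force_mean, params.rupture_force_sd),
            10.0, 150.0))
        peak = rupture_f
    else:
        if rng.random() < params.ramp_rupture_probability:
            # bond fails during loading, clamp never reached
            rupture_f = float(rng.uniform(5.0, params.clamp_force))
            peak = rupture_f

    # threshold forces truncated to the observable kink range (~5-20 pN)
    candidates = []
    if rng.random() < params.lrrd_probability:
        f = float(rng.normal(params.lrrd_force_mean, params.lrrd_force_sd))
        candidates.append(("LRRD", float(np.clip(f, 5.0, 20.0)),
                           params.unfold_dlc_lrrd))
    if rng.random() < params.msd_ramp_probability:
        f = float(rng.normal(params.msd_ramp_force_mean, params.msd_ramp_force_sd))
        candidates.append(("MSD", float(np.clip(f, 5.0, 20.0)),
                           params.unfold_dlc_msd))
    for domain, f_th, dlc in sorted(candidates, key=lambda c: c[1]):
        if peak is not None and f_th >= peak:
            continue
        z = _extension_fraction(f_th, params.persistence_nm, params.kbt)
        events.append(UnfoldTruth(phase="ramped", domain=domain,
                                  length=z * dlc, time=np.nan, force=f_th,
                                  observable=f_th >= 6.5))
        if domain == "LRRD":
            lrrd = True

    if rupture_f is not None:
        return GroundTruth(bond_formed=True, outcome="rupture",
                           rupture_force=rupture_f, events=events,
                           lrrd_unfolded=lrrd)

    # clamp phase: dual-exponential lifetime, exponential time-to-unfold
    lt = params.lifetime_params(lrrd_unfolded=lrrd)
    k = lt["k1"] if rng.random() < lt["w1"] else lt["k2"]
    t_b = float(rng.exponential(1.0 / k))
    ku = params.ku
    msd_clamped = False
    if ku > 0:
        t_u = float(rng.exponential(1.0 / ku)) if np.isfinite(ku) else 0.0
        already = any(e.domain == "MSD" for e in events)
        if t_u < t_b and not already:
            z = _extension_fraction(params.clamp_force, params.persistence_nm,
                                    params.kbt)
            observable = (t_b - t_u) > (params.feedback_delay_s + 0.015)
            events.append(UnfoldTruth(phase="clamped", domain="MSD",
                                      length=z * params.unfold_dlc_msd,
                                      time=t_u, force=params.clamp_force,
                                      observable=observable))
            msd_clamped = True
    return GroundTruth(bond_formed=True, outcome="lifetime", lifetime=t_b,
                       events=events, lrrd_unfolded=lrrd,
                       msd_clamped_unfolded=msd_clamped)


def simulate_outcomes(n_cycles: int, params: SimParams,
                      rng: np.random.Generator | int | None = None) -> list[GroundTruth]:
    """Fast path: draw the latent outcomes of many cycles without rendering
    traces.  Statistically identical to the cycles :func:`simulate_cycle`
    renders (both consume the same per-cycle draw routine)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return [_draw_cycle_truth(params, rng) for _ in range(n_cycles)]


# ---------------------------------------------------------------------------
# trace rendering
# ---------------------------------------------------------------------------

def _wlc_load_curve(params: SimParams, lc: float, n: int = 400):
    """Target displacement vs force for tether (WLC) + probe spring in series."""
    wp = WLCParams(lc, params.persistence_nm, params.kbt)
    z = np.linspace(0.0, 0.985, n)
    f = wlc_force(z * lc, wp)
    xt = z * lc + f / params.spring_constant
    return xt, f


def _render_tensile(params: SimParams, truth: GroundTruth):
    """Force vs target-displacement samples of the tensile loading phase.

    Returns (forces, target displacement per sample, ramped event sample
    times relative to tensile onset).  Sampling is on the uniform time grid
    implied by the retraction speed.
    """
    v = params.retraction_speed * 1000.0  # nm/s
    dt = 1.0 / params.sample_rate
    k = params.spring_constant
    lc = params.tether_contour_nm
    peak = truth.rupture_force if truth.outcome == "rupture" else params.clamp_force
    if params.mode == "ramp" and truth.outcome == "rupture":
        peak = truth.rupture_force

    ramped = sorted([e for e in truth.events if e.phase == "ramped"],
                    key=lambda e: e.force)
    forces: list[float] = []
    xt_now = 0.0
    event_times = []
    for ev in ramped + [None]:
        f_stop = peak if ev is None else ev.force
        xt_grid, f_grid = _wlc_load_curve(params, lc)
        xt_stop = float(np.interp(f_stop, f_grid, xt_grid))
        n_seg = max(int(math.ceil((xt_stop - xt_now) / (v * dt))), 1)
        xs = xt_now + (np.arange(1, n_seg + 1)) * v * dt
        fs = np.interp(xs, xt_grid, f_grid)
        # crop at the stop force
        keep = fs <= f_stop + 1e-9
        fs, xs = fs[keep], xs[keep]
        forces.extend(fs.tolist())
        xt_now = xs[-1] if xs.size else xt_now
        if ev is not None:
            lc += (params.unfold_dlc_lrrd if ev.domain == "LRRD"
                   else params.unfold_dlc_msd)
            ev.time = len(forces) * dt  # since tensile onset
            event_times.append(ev.time)
    forces = np.asarray(forces)
    xt = np.arange(1, forces.size + 1) * v * dt
    return forces, xt


def simulate_cycle(params: SimParams, rng: np.random.Generator | int | None = None,
                   truth: GroundTruth | None = None):
    """Simulate one BFP cycle; returns (ForceTrace, GroundTruth).

    The trace contains approach, impingement, contact and retraction stages;
    bonded cycles add a tensile WLC ramp, and in clamp mode a constant-force
    plateau of dual-exponential duration with optional MSD unfolding drop.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if truth is None:
        truth = _draw_cycle_truth(params, rng)

    dt = 1.0 / params.sample_rate
    k = params.spring_constant
    v = params.retraction_speed * 1000.0

    segs: dict[str, int] = {}
    force_parts: list[np.ndarray] = []
    target_parts: list[np.ndarray] = []
    x_target = 0.0

    def _append(name, f_arr, xt_arr=None):
        nonlocal x_target
        if name is not None:
            segs[name] = sum(p.size for p in force_parts)
        f_arr = np.asarray(f_arr, dtype=float)
        if xt_arr is None:
            xt_arr = np.full(f_arr.size, x_target)
        force_parts.append(f_arr)
        target_parts.append(np.asarray(xt_arr, dtype=float))
        if len(xt_arr):
            x_target = float(np.asarray(xt_arr)[-1])

    # approach: free probe
    n_app = int(0.05 / dt)
    _append("approach", np.zeros(n_app))
    # impinge: compress to -F_imp at the nominal rate
    n_imp = max(int(params.impingement_force / (k * v) / dt), 1)
    f_imp = -np.linspace(0, params.impingement_force, n_imp)
    _append("impinge", f_imp, x_target - np.arange(1, n_imp + 1) * v * dt)
    # contact hold
    n_con = int(params.contact_duration / dt)
    _append("contact", np.full(n_con, -params.impingement_force))
    # retraction: release compression
    segs["retract"] = sum(p.size for p in force_parts)
    n_rel = max(int(params.impingement_force / (k * v) / dt), 1)
    f_rel = np.linspace(-params.impingement_force, 0.0, n_rel)
    _append(None, f_rel, x_target + np.arange(1, n_rel + 1) * v * dt)

    if not truth.bond_formed:
        n_tail = int(0.3 / dt)
        _append(None, np.zeros(n_tail),
                x_target + np.arange(1, n_tail + 1) * v * dt)
    else:
        segs["tensile"] = sum(p.size for p in force_parts)
        f_ramp, xt_ramp = _render_tensile(params, truth)
        # ramped event times were recorded relative to tensile onset;
        # promote them to the trace clock
        t_tensile = segs["tensile"] * dt
        for ev in truth.events:
            if ev.phase == "ramped" and np.isfinite(ev.time):
                ev.time = ev.time + t_tensile
        _append(None, f_ramp, x_target + xt_ramp)

        if truth.outcome == "rupture":
            n_tail = int(0.1 / dt)
            _append(None, np.zeros(n_tail),
                    x_target + np.arange(1, n_tail + 1) * v * dt)
        else:
            # clamp plateau with feedback (target frozen by the controller)
            segs["clamp"] = sum(p.size for p in force_parts)
            t_hold = min(truth.lifetime, params.max_lifetime_s)
            n_hold = max(int(t_hold / dt), 2)
            f_clamp = np.full(n_hold, params.clamp_force)
            clamped = [e for e in truth.events if e.phase == "clamped"]
            for ev in clamped:
                i0 = int(ev.time / dt)
                if i0 >= n_hold - 1:
                    continue
                drop = k * ev.length
                n_delay = max(int(params.feedback_delay_s / dt), 2)
                n_rec = max(int(params.feedback_recovery_s / dt), 2)
                rec = np.concatenate([
                    np.full(n_delay, params.clamp_force - drop),
                    np.linspace(params.clamp_force - drop,
                                params.clamp_force, n_rec),
                ])
                i1 = min(i0 + rec.size, n_hold)
                f_clamp[i0:i1] = rec[: i1 - i0]
            _append(None, f_clamp)
            # dissociation: collapse to zero and idle briefly
            segs["dissociation"] = sum(p.size for p in force_parts)
            n_tail = int(0.1 / dt)
            _append(None, np.zeros(n_tail))

    force = np.concatenate(force_parts)
    target = np.concatenate(target_parts)
    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd, force.size)
    time = np.arange(force.size) * dt
    probe = force / k
    trace = ForceTrace(time=time, force=force, probe_nm=probe, target_nm=target,
                       mode=params.mode, spring_constant=k,
                       sample_rate=params.sample_rate,
                       clamp_force=params.clamp_force if params.mode == "clamp" else None,
                       segments=segs)
    return trace, truth


# ---------------------------------------------------------------------------
# sessions and calcium
# ---------------------------------------------------------------------------

def _alpha_shape(t, tau):
    """Normalized alpha-function transient (t/tau) e^(1 - t/tau), t >= 0."""
    s = np.clip(t / tau, 0, None)
    return s * np.exp(1.0 - s)


def _render_calcium(session_duration: float, ca_type: str, onset: float | None,
                    amp: float, coupling: CalciumCoupling,
                    rng: np.random.Generator) -> CalciumTrace:
    n = max(int(session_duration * coupling.frame_rate), 20)
    t = np.arange(n) / coupling.frame_rate
    intensity = 1.0 + rng.normal(0.0, coupling.trace_noise_sd, n)
    if ca_type != "null" and onset is not None:
        tau = coupling.alpha_rise_tau if ca_type == "alpha" else coupling.beta_rise_tau
        intensity = intensity + amp * _alpha_shape(t - onset, tau)
    d_i_max = float(intensity.max() / np.mean(intensity[: max(int(n * 0.05), 3)]) - 1.0)
    return CalciumTrace(time=t, intensity=intensity, ca_type=ca_type,
                        onset_time=onset, delta_i_max=d_i_max)


def simulate_session(n_cycles: int, params: SimParams,
                     coupling: CalciumCoupling | None = None,
                     seed: int | np.random.Generator | None = 0,
                     render_traces: bool = True):
    """Simulate a session of repeated cycles on one platelet plus its
    calcium trace.

    Returns ``(cycles, calcium)`` where ``cycles`` is a list of
    ``(ForceTrace | None, GroundTruth)`` tuples (traces omitted when
    ``render_traces`` is false) and ``calcium`` is a :class:`CalciumTrace`.
    Ground-truth records gain a ``start_time`` attribute (session clock).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    coupling = coupling if coupling is not None else CalciumCoupling()
    master = (seed if isinstance(seed, np.random.Generator)
              else np.random.default_rng(seed))
    streams = master.spawn(n_cycles + 1)
    ca_rng = streams[-1]

    cycles = []
    t_session = 0.0
    lifetime_events = []   # (end_time, t_b, truth)
    trigger_time = None
    t_max_running = 0.0
    for i in range(n_cycles):
        rng = streams[i]
        if render_traces:
            trace, truth = simulate_cycle(params, rng)
            duration = trace.time[-1] + 1.0 / params.sample_rate
        else:
            truth = _draw_cycle_truth(params, rng)
            trace = None
            duration = (0.1 + params.impingement_force / params.ramp_rate
                        + params.contact_duration
                        + params.impingement_force / params.ramp_rate
                        + params.clamp_force / params.ramp_rate
                        + (min(truth.lifetime, params.max_lifetime_s)
                           if truth.outcome == "lifetime" else 0.0) + 0.2)
        truth.start_time = t_session
        if truth.outcome == "lifetime":
            end = t_session + duration
            lifetime_events.append((end, truth.lifetime, truth))
            t_max_running = max(t_max_running, truth.lifetime)
            if (trigger_time is None and coupling.enabled
                    and (truth.msd_clamped_unfolded or not coupling.require_msd_unfold)
                    and t_max_running > coupling.lifetime_threshold):
                trigger_time = end
        cycles.append((trace, truth))
        t_session += duration

    session_duration = max(t_session, 1.0)
    # a trigger too close to the end of the observation window never shows
    # its rise within the recording; such sessions are not alpha responders
    alpha_visible = (trigger_time is not None and
                     trigger_time + coupling.onset_latency
                     <= session_duration - 5.0)
    if not coupling.enabled:
        ca_type, onset, amp = "null", None, 0.0
    elif alpha_visible:
        ca_type = "alpha"
        onset = trigger_time + coupling.onset_latency
        amp = (coupling.alpha_amp_base
               + coupling.alpha_amp_slope * min(t_max_running, 10.0)
               + ca_rng.normal(0.0, coupling.amp_noise_sd))
        amp = float(np.clip(amp, 0.52, 2.0))
    elif lifetime_events and ca_rng.random() < coupling.beta_probability:
        ca_type = "beta"
        onset = min(lifetime_events[0][0] + coupling.onset_latency,
                    session_duration * 0.9)
        amp = (coupling.beta_amp_base
               + coupling.beta_amp_slope * min(t_max_running, 10.0)
               + ca_rng.normal(0.0, coupling.amp_noise_sd))
        amp = float(np.clip(amp, 0.07, 0.45))
    else:
        ca_type, onset, amp = "null", None, 0.0
    calcium = _render_calcium(session_duration, ca_type, onset, amp,
                              coupling, ca_rng)
    for _, truth in cycles:
        truth.calcium_type = ca_type
    return cycles, calcium
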