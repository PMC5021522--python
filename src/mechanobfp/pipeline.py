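"""End-to-end pipeline: simulate -> detect -> classify -> kinetics ->
cooperativity -> calcium, with a YAML config and a JSON summary report.

The pipeline is a pure function of (config, seed): rerunning the same
config produces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calcium as ca
from . import coop, kinetics, lengths
from .events import analyze_cycle
from .simulate import CalciumCoupling, SimParams, simulate_session

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "detect", "classify", "kinetics", "coop", "calcium")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    forces: list = field(default_factory=lambda: [25.0])
    ligand: str = "A1WT"
    n_sessions: int = 6
    n_cycles: int = 50
    render_traces: bool = True
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    sim_overrides: dict = field(default_factory=dict)
    coupling_overrides: dict = field(default_factory=dict)
    min_force: float = 5.0
    drop_threshold: float = 3.0

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")
        valid_sim = {f.name for f in dataclasses.fields(SimParams)}
        bad = set(self.sim_overrides) - valid_sim
        if bad:
            raise ValueError(f"unknown sim_overrides keys: {sorted(bad)}")
        valid_cpl = {f.name for f in dataclasses.fields(CalciumCoupling)}
        bad = set(self.coupling_overrides) - valid_cpl
        if bad:
            raise ValueError(f"unknown coupling_overrides keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _session_records(config: RunConfig, force: float, seed_stream):
    params = SimParams(mode="clamp", clamp_force=force, ligand=config.ligand,
                       **config.sim_overrides)
    coupling = CalciumCoupling(**config.coupling_overrides)
    sessions = []
    for _ in range(config.n_sessions):
        cycles, calcium = simulate_session(
            config.n_cycles, params, coupling,
            seed=seed_stream.spawn(1)[0],
            render_traces=config.render_traces)
        sessions.append((cycles, calcium, params))
    return sessions


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write per-stage artifacts plus a
    summary report to ``config.out_dir``.  Returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed, "forces": list(map(float, config.forces))}

    all_sessions = {}
    if config.stages.get("simulate", True):
        for force in config.forces:
            all_sessions[float(force)] = _session_records(config, force, master)

    per_force: dict[str, dict] = {}
    for force, sessions in all_sessions.items():
        entry: dict = {}
        detected = []      # (session idx, cycle idx, CycleResult or truth-based)
        for si, (cycles, calcium, params) in enumerate(sessions):
            for ci, (trace, truth) in enumerate(cycles):
                if config.stages.get("detect", True) and trace is not None:
                    res = analyze_cycle(trace, min_force=config.min_force,
                                        drop_threshold=config.drop_threshold)
                else:
                    res = _truth_as_result(truth)
                detected.append((si, ci, res, truth))

        if config.stages.get("classify", True):
            results = [r for _, _, r, _ in detected]
            summary = lengths.condition_summary(results,
                                                condition=f"{force:g} pN")
            entry["unfolding"] = json.loads(
                summary.reset_index().to_json(orient="records"))

        if config.stages.get("kinetics", True):
            t_us = [ev.t_u for _, _, r, _ in detected for ev in r.events
                    if ev.phase == "clamped" and ev.t_u is not None and ev.t_u > 0]
            n_lifetime = sum(r.outcome == "lifetime" for _, _, r, _ in detected)
            n_unfold = sum(any(e.phase == "clamped" for e in r.events)
                           for _, _, r, _ in detected)
            entry["kinetics"] = {
                "n_lifetime_cycles": int(n_lifetime),
                "n_clamped_unfoldings": int(n_unfold),
                "observed_unfold_frequency": (n_unfold / n_lifetime
                                              if n_lifetime else None),
            }
            if len(t_us) >= 5:
                fit = kinetics.fit_exponential(t_us)
                entry["kinetics"]["ku_fit"] = fit.rate
            try:
                from .params import lifetime_params, msd_unfold_rate

                lt = lifetime_params(config.ligand, force, False)
                entry["kinetics"]["predicted_unfold_probability"] = (
                    kinetics.predict_unfold_probability(msd_unfold_rate(force), lt))
            except KeyError:
                entry["kinetics"]["predicted_unfold_probability"] = None

        if config.stages.get("coop", True):
            lrrd, msd = [], []
            for _, _, r, truth in detected:
                if r.outcome == "no_bond":
                    continue
                doms = {lengths.assign_domain(e.phase, e.length)
                        for e in r.events}
                lrrd.append("LRRD" in doms or "BOTH" in doms)
                msd.append("MSD" in doms or "BOTH" in doms)
            if lrrd and any(lrrd) and any(msd) and not all(lrrd) and not all(msd):
                table = coop.build_table(lrrd, msd)
                chi2, df, p = coop.chi_square_independence(table)
                m = table.marginals
                entry["coop"] = {
                    "table": table.as_array().astype(int).tolist(),
                    "chi2": chi2, "df": df, "p": p,
                    "dPoverP": coop.delta_p_over_p(
                        m["P(both)"], m["P(MSD+)"], m["P(LRRD+)"]),
                }
            else:
                entry["coop"] = {"note": "cooperativity undefined (a marginal is zero)"}

        if config.stages.get("calcium", True):
            platelets = []
            for si, (cycles, calcium, params) in enumerate(sessions):
                an = ca.normalize_and_peak(calcium.time, calcium.intensity)
                ctype = ca.classify_calcium(an)
                tbs, ends = [], []
                for trace, truth in cycles:
                    if truth.outcome == "lifetime":
                        tbs.append(truth.lifetime)
                        ends.append(getattr(truth, "start_time", 0.0)
                                    + (truth.lifetime or 0.0))
                rec = {"session": si, "type": ctype,
                       "delta_i_max": an.delta_i_max,
                       "onset": an.onset_time}
                if tbs:
                    try:
                        st = ca.pre_ca_stats(tbs, ends, an.onset_time)
                        rec.update(t_max=st.t_max, sum_t=st.sum_t,
                                   mean_t=st.mean_t, n_lifetimes=st.n_lifetimes)
                    except ValueError:
                        pass
                platelets.append(rec)
            fractions = {k: sum(p["type"] == k for p in platelets) / len(platelets)
                         for k in ("null", "alpha", "beta")}
            entry["calcium"] = {"platelets": platelets, "type_fractions": fractions}

        per_force[f"{force:g}"] = entry

    report["per_force"] = per_force
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _truth_as_result(truth):
    """Fallback when traces are not rendered: read outcomes from ground truth."""
    from .events import CycleResult, UnfoldingEvent

    events = []
    for e in truth.events:
        events.append(UnfoldingEvent(
            phase=e.phase, length=e.length, force=e.force,
            t_u=e.time if e.phase == "clamped" else None))
    if truth.outcome == "no_bond":
        return CycleResult(outcome="no_bond")
    if truth.outcome == "rupture":
        return CycleResult(outcome="rupture", rupture_force=truth.rupture_force,
                           events=events)
    return CycleResult(outcome="lifetime", bond_lifetime=truth.lifetime,
                       events=events)
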