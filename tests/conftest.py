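import numpy as np
import pytest

from mechanobfp.simulate import SimParams, simulate_cycle


@pytest.fixture(scope="session")
def labeled_cycles():
    """A reusable ensemble of rendered cycles with ground truth.

    Every cycle is bonded so the ensemble is rich in unfolding events; the
    remaining parameters are the default 25 pN clamp condition.
    """
    params = SimParams(adhesion_probability=1.0, ramp_rupture_probability=0.0)
    rng = np.random.default_rng(1)
    return params, [simulate_cycle(params, rng) for _ in range(600)]


def match_events(truth_events, detected, phase, tol_s=0.05):
    """Greedy time matching of detected events to ground truth.

    Returns (matched truth/detected index pairs, unmatched truth list,
    unmatched detected indices).  A merged detection (one call covering two
    nearly simultaneous truths) may match several truths.
    """
    def t_of(ev):
        return ev.time if phase == "ramped" else ev.t_u

    pairs, missed = [], []
    used = set()
    for t in truth_events:
        best = None
        for j, d in enumerate(detected):
            dt = abs(t_of(d) - t.time)
            if dt < tol_s and (best is None or dt < best[0]):
                best = (dt, j)
        if best is None:
            missed.append(t)
        else:
            pairs.append((t, detected[best[1]]))
            used.add(best[1])
    unmatched_det = [j for j in range(len(detected)) if j not in used]
    return pairs, missed, unmatched_det
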