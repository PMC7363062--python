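"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive expected behaviour by the most literal
route available (rule transcription, distribution convolution) and stay
independent of the library code paths they are used to check.
"""

import numpy as np
from scipy import stats as spstats

from gaitmill.controller import FEEDBACK_COPED, FEEDBACK_TRY


def oracle_trace(upper, hrs, speed0, increment, max_trials):
    """Literal transcription of the speed-switching rules."""
    speed, prev, out, pending = speed0, None, [], False
    for hr in list(hrs)[:max_trials]:
        feedback = None
        if pending:
            feedback = FEEDBACK_COPED if hr <= upper else FEEDBACK_TRY
        pending = False
        if hr > upper:
            out.append((speed, "terminate", feedback))
            break
        if prev is not None and hr < prev:
            out.append((speed, "increase", feedback))
            speed += increment
            pending = True
        else:
            out.append((speed, "maintain", feedback))
        prev = hr
    return out


def enumeration_p(diffs):
    """Exact two-sided signed-rank p via convolution over doubled mid-ranks.

    Builds the null distribution of the positive rank sum by dynamic
    programming instead of materializing the 2^n assignments.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks2 = (2 * spstats.rankdata(np.abs(d))).round().astype(int)  # halves -> ints
    dist = {0: 1}
    for r in ranks2:
        new = {}
        for s, c in dist.items():
            new[s] = new.get(s, 0) + c
            new[s + r] = new.get(s + r, 0) + c
        dist = new
    total = int(sum(ranks2))
    w_pos2 = int(ranks2[d > 0].sum())
    w2 = min(w_pos2, total - w_pos2)
    count = sum(c for s, c in dist.items() if min(s, total - s) <= w2)
    return count / 2 ** len(ranks2)
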