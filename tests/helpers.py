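"""Independent oracles used by the test suite.

These deliberately avoid the production code paths they check: the cohort
oracle is a naive per-woman / per-event / per-category triple loop, and the
interval oracles are vectorized bisections on the defining score / exact
coverage equations.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, norm

from pregrisk.cohort import assess_eligibility, resolve_window


def naive_classify(registry, events, bundle, study):
    """Triple-loop reference classification: {patient_id: (eligible, at_risk)}."""
    out = {}
    for patient in registry:
        eligible, _ = assess_eligibility(patient, study)
        hits = 0
        if eligible:
            for ev in events:
                if ev.patient_id != patient.patient_id:
                    continue
                for cat, codes in bundle.lists.items():
                    if ev.code in codes:
                        lo, hi = resolve_window(cat, study)
                        if lo <= ev.event_date <= hi:
                            hits += 1
        out[patient.patient_id] = (eligible, eligible and hits == 0)
    return out


def clopper_pearson_bisect(x, n, level=0.95, iters=80):
    """Exact interval by bisection on the coverage equations
    P(X >= x | p_low) = alpha/2 and P(X <= x | p_high) = alpha/2."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    alpha = 1.0 - level

    a, b = np.zeros_like(x), np.ones_like(x)
    for _ in range(iters):
        mid = 0.5 * (a + b)
        too_big = binom.sf(x - 1, n, mid) > alpha / 2  # sf increasing in p
        b = np.where(too_big, mid, b)
        a = np.where(too_big, a, mid)
    low = np.where(x == 0, 0.0, 0.5 * (a + b))

    a, b = np.zeros_like(x), np.ones_like(x)
    for _ in range(iters):
        mid = 0.5 * (a + b)
        too_big = binom.cdf(x, n, mid) > alpha / 2  # cdf decreasing in p
        a = np.where(too_big, mid, a)
        b = np.where(too_big, b, mid)
    high = np.where(x == n, 1.0, 0.5 * (a + b))
    return low, high


def wilson_bisect(x, n, level=0.95, iters=80):
    """Score interval by bisection on the score-test inversion
    (p_hat - p)^2 = z^2 p (1 - p) / n, written as a quadratic h(p)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    z2 = norm.ppf(1 - (1 - level) / 2) ** 2
    phat = x / n

    def h(p):
        return (1 + z2 / n) * p**2 - (2 * phat + z2 / n) * p + phat**2

    # lower root on [0, phat]: h(0) >= 0, h(phat) <= 0
    a, b = np.zeros_like(phat), phat.copy()
    for _ in range(iters):
        mid = 0.5 * (a + b)
        pos = h(mid) > 0
        a = np.where(pos, mid, a)
        b = np.where(pos, b, mid)
    low = np.where(x == 0, 0.0, 0.5 * (a + b))

    # upper root on [phat, 1]: h(phat) <= 0, h(1) >= 0
    a, b = phat.copy(), np.ones_like(phat)
    for _ in range(iters):
        mid = 0.5 * (a + b)
        pos = h(mid) > 0
        b = np.where(pos, mid, b)
        a = np.where(pos, a, mid)
    high = np.where(x == n, 1.0, 0.5 * (a + b))
    return low, high


def expected_ppv(p_at_risk: float, q_unrecorded: float) -> float:
    """Closed-form expected PPV of the algorithm against planted truth when
    a contracepting woman leaves no coded trace with probability q:
    P(at risk) / (P(at risk) + q * P(contracepting))."""
    p_contracepting = 1.0 - p_at_risk
    return p_at_risk / (p_at_risk + q_unrecorded * p_contracepting)
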