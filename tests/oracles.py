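"""Independent brute-force reference implementations used only by tests.

Each oracle re-evaluates the underlying definition directly (explicit loops,
exact rational arithmetic for the hypergeometric enumeration) and is kept
separate from the package code paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

TOL = 1e-9


def _ge(x: float, y: float) -> bool:
    return x >= y - TOL * abs(y)


def _le(x: float, y: float) -> bool:
    return x <= y + TOL * abs(y)


def oracle_assess(rels: list[float]) -> tuple[list[str], bool, int | None, int | None]:
    """Literal re-evaluation of the volumetric response definitions.

    ``rels`` are follow-up volumes relative to baseline (baseline = 1.0).
    Returns (categories, te_detected, naive_event_index, te_aware_event_index).
    """
    n = len(rels)

    categories = []
    for i in range(n):
        nadir_or_baseline = min([1.0] + list(rels[:i]))
        v = rels[i]
        if _ge(v, 1.40 * nadir_or_baseline):
            categories.append("PD")
        elif _le(v, 0.35):
            categories.append("PR")
        elif _le(v, 0.60):
            categories.append("MR")
        else:
            categories.append("SD")

    # transient enlargement: >= 20% increase over baseline followed by a
    # regression >= 20% relative to the running episode maximum
    detected = False
    rise = None
    for i in range(n):
        if _ge(rels[i], 1.20):
            rise = i
            break
    if rise is not None:
        episode_max = rels[rise]
        for k in range(rise + 1, n):
            if _le(rels[k], 0.80 * episode_max):
                detected = True
                break
            if rels[k] > episode_max:
                episode_max = rels[k]

    naive = None
    for i in range(n):
        if categories[i] == "PD":
            naive = i
            break

    aware = None
    i = 0
    while i < n:
        if categories[i] != "PD":
            i += 1
            continue
        episode_max = rels[i]
        resolved = None
        for k in range(i + 1, n):
            if _le(rels[k], 0.80 * episode_max):
                resolved = k
                break
            if rels[k] > episode_max:
                episode_max = rels[k]
        if resolved is None:
            aware = i
            break
        i = resolved + 1

    return categories, detected, naive, aware


def oracle_km(durations: list[float], events: list[bool]) -> tuple[list[float], list[float]]:
    """Hand product-limit estimator; censorings at an event time stay at risk."""
    event_times = sorted({t for t, e in zip(durations, events) if e})
    surv = []
    s = 1.0
    for t in event_times:
        at_risk = sum(1 for d in durations if d >= t)
        d_t = sum(1 for d, e in zip(durations, events) if e and d == t)
        s *= 1.0 - d_t / at_risk
        surv.append(s)
    return event_times, surv


def oracle_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by complete enumeration in exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))
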