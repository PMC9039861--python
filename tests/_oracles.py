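"""Brute-force reference implementations, kept deliberately naive.

These re-derive the extraction results sample by sample with plain Python
loops and hand-written order statistics, independent of the vectorised
library code they are used to check.
"""

import math


def quantile_linear(values, q):
    """Interpolated order statistic (the 'linear'/type-7 convention)."""
    sv = sorted(values)
    pos = (len(sv) - 1) * q
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return sv[lo] * (1 - frac) + sv[hi] * frac


def tukey_retained(values, k=1.5):
    """Element-by-element fence test; fences computed once on the input."""
    q1 = quantile_linear(values, 0.25)
    q3 = quantile_linear(values, 0.75)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return [v for v in values if lo <= v <= hi]


def median_by_sort(values):
    sv = sorted(values)
    n = len(sv)
    mid = n // 2
    if n % 2:
        return sv[mid]
    return (sv[mid - 1] + sv[mid]) / 2.0


def brute_force_median_plee(time, flow, paw, pl, datastart, set_peep,
                            paw_margin=1.0, flow_margin=10.0, k=1.5):
    """Full pipeline, one sample at a time.

    Returns the median retained P_L, or the name of the failing stage
    ('empty-window' / 'no-end-expiration') so callers can compare error
    behaviour as well as values.
    """
    kept = []
    any_in_window = False
    for t, f, p, x in zip(time, flow, paw, pl):
        if t < datastart:
            continue
        any_in_window = True
        if abs(p - set_peep) <= paw_margin and abs(f) <= flow_margin:
            kept.append(x)
    if not any_in_window:
        return "empty-window"
    if not kept:
        return "no-end-expiration"
    return median_by_sort(tukey_retained(kept, k))
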