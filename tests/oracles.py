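"""Independent brute-force oracles used to pin down the metric implementations.

Everything here is deliberately naive (explicit loops, sequential
product-limit factors) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def product_limit(times, events, t, strict: bool = False) -> float:
    """Sequential Kaplan-Meier product over event times <= t (or < t)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    event_times = np.unique(times[events == 1])
    s = 1.0
    for u in event_times:
        if (u > t) if not strict else (u >= t):
            break
        at_risk = int(np.sum(times >= u))
        d = int(np.sum((times == u) & (events == 1)))
        s *= 1.0 - d / at_risk
    return s


def censoring_product_limit(times, events, t, strict: bool = False) -> float:
    return product_limit(times, 1 - np.asarray(events), t, strict=strict)


def ipcw_auc_brute(marker, times, events, t) -> float:
    """Double loop over all weighted case-control pairs."""
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    g_t = censoring_product_limit(times, events, t)
    case_idx = np.where((times <= t) & (events == 1))[0]
    ctrl_idx = np.where(times > t)[0]
    num = 0.0
    wsum = 0.0
    vsum = 0.0
    v = 1.0 / g_t
    for j in ctrl_idx:
        vsum += v
    for i in case_idx:
        w = 1.0 / censoring_product_limit(times, events, times[i], strict=True)
        wsum += w
        for j in ctrl_idx:
            if marker[i] > marker[j]:
                num += w * v
            elif marker[i] == marker[j]:
                num += 0.5 * w * v
    return num / (wsum * vsum)


def ipcw_brier_brute(predicted_survival, times, events, t) -> float:
    """Explicit per-subject weighted sum."""
    s = np.asarray(predicted_survival, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    g_t = censoring_product_limit(times, events, t)
    total = 0.0
    for i in range(len(times)):
        if times[i] <= t and events[i] == 1:
            g = censoring_product_limit(times, events, times[i], strict=True)
            total += (0.0 - s[i]) ** 2 / g
        elif times[i] > t:
            total += (1.0 - s[i]) ** 2 / g_t
    return total / len(times)


def exponential_rate_mle_by_group(times, events, group) -> float:
    """Log rate ratio between two groups: closed-form exponential MLE.

    For exponential data the MLE of the rate in a group is
    (number of events) / (total follow-up time); with a single binary
    covariate the PH log-hazard-ratio MLE is the log of the rate ratio.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    group = np.asarray(group)
    rates = []
    for g in (0, 1):
        m = group == g
        rates.append(events[m].sum() / times[m].sum())
    return float(np.log(rates[1] / rates[0]))
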