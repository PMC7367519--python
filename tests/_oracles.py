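"""Independent oracles used by the test suite (never by the package itself)."""

from __future__ import annotations

import numpy as np


def _masks(met, rule, on_body=None, asleep=None):
    met = np.asarray(met, dtype=float)
    n = met.size
    on = np.ones(n, bool) if on_body is None else np.asarray(on_body, bool)
    slp = np.zeros(n, bool) if asleep is None else np.asarray(asleep, bool)
    blocked = ~on
    if rule.waking_only:
        blocked = blocked | slp
    if rule.met_comparator == "at_least":
        qual = (met >= rule.met_threshold) & ~blocked
    else:
        qual = (met <= rule.met_threshold) & ~blocked
    return qual, blocked


def _window_valid(qual, blocked, s, e, rule):
    """Exhaustive validity check of window [s, e)."""
    if e - s < rule.min_bout_minutes:
        return False
    if not (qual[s] and qual[e - 1]):
        return False
    if blocked[s:e].any():
        return False
    run = 0
    total = 0
    for i in range(s, e):
        if qual[i]:
            run = 0
        else:
            run += 1
            total += 1
            if rule.interruption_mode == "run" and run > rule.max_interruption_run:
                return False
    if rule.interruption_mode == "total" and total > rule.max_interruption_run:
        return False
    return True


def exhaustive_bouted_minutes(met, rule, on_body=None, asleep=None) -> int:
    """O(n^2) enumeration of all valid windows; sums the maximal ones.

    Only usable for short sequences.  A window is emitted when it is valid and
    not contained in any longer valid window.
    """
    qual, blocked = _masks(met, rule, on_body, asleep)
    n = qual.size
    windows = []
    for s in range(n):
        if not qual[s]:
            continue
        for e in range(s + rule.min_bout_minutes, n + 1):
            if _window_valid(qual, blocked, s, e, rule):
                windows.append((s, e))
    maximal = [
        (s, e)
        for (s, e) in windows
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for (s2, e2) in windows)
    ]
    if rule.credit == "qualifying_only":
        return int(sum(qual[s:e].sum() for s, e in maximal))
    return sum(e - s for s, e in maximal)


def maximal_window_bouted_minutes(met, rule, on_body=None, asleep=None) -> int:
    """Fast maximal-window oracle (run-reading only), linear time.

    Derivation independent of the greedy scan: a minute is *bad* when it is
    blocked or belongs to a sub-threshold run longer than the allowance; for
    each qualifying start the reachable end is the next bad minute, so maximal
    windows are, per distinct "next bad minute", the earliest qualifying start
    with ends trimmed to the last qualifying minute before the bad one.
    """
    assert rule.interruption_mode == "run"
    qual, blocked = _masks(met, rule, on_body, asleep)
    n = qual.size
    # length of the sub-threshold run containing each minute
    run_len = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        if qual[i]:
            i += 1
            continue
        j = i
        while j < n and not qual[j] and not blocked[j]:
            j += 1
        run_len[i:j] = j - i
        i = max(j, i + 1)
    bad = blocked | (~qual & (run_len > rule.max_interruption_run))
    # next bad minute at or after each index
    next_bad = np.full(n + 1, n)
    for i in range(n - 1, -1, -1):
        next_bad[i] = i if bad[i] else next_bad[i + 1]
    total = 0
    qual_idx = np.flatnonzero(qual)
    prev_group = -1
    for s in qual_idx:
        g = next_bad[s]
        if g == prev_group:
            continue  # an earlier start reaches the same bad minute: contained
        prev_group = g
        # trim to last qualifying minute before the bad one
        in_window = qual_idx[(qual_idx >= s) & (qual_idx < g)]
        e = int(in_window[-1]) + 1
        if e - s >= rule.min_bout_minutes:
            if rule.credit == "qualifying_only":
                total += int(in_window.size)
            else:
                total += e - s
    return int(total)
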