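"""Naive reference implementations of the outcome rules.

Written as direct, loop-based restatements of the definitions, kept
deliberately independent of the vectorised implementations they check.
"""

AD = {"ssri_citalopram", "ssri_escitalopram", "ssri_sertraline", "other_antidepressant"}


def naive_windows(days, gap_days=90):
    """Split at every gap >= gap_days by linear scan."""
    days = sorted(set(days))
    if not days:
        return []
    windows = [[days[0]]]
    for prev, cur in zip(days, days[1:]):
        if cur - prev >= gap_days:
            windows.append([cur])
        else:
            windows[-1].append(cur)
    return [(w[0], w[-1], len(w)) for w in windows]


def naive_weeks(days, gap_days=90):
    return sum((last - first) for first, last, _ in naive_windows(days, gap_days)) / 7.0


def _index_days(rx, ssri):
    return sorted({d for d, c in rx if c == ssri})


def _other_ad_days(rx, ssri):
    return sorted({d for d, c in rx if c in AD and c != ssri})


def _ad_days(rx):
    return sorted({d for d, c in rx if c in AD})


def naive_switch(rx, ssri, window, tol, tol_window=30, min_control=3):
    idx = _index_days(rx, ssri)
    if not idx:
        return "excluded"
    others = [d for d in _other_ad_days(rx, ssri) if d >= idx[0]]
    if not others:
        return "control" if len(idx) >= min_control else "excluded"
    d = others[0]
    gap = d - max(x for x in idx if x <= d)
    before = sum(1 for x in idx if d - tol_window <= x < d)
    after = sum(1 for x in idx if d < x <= d + tol_window)
    if gap <= window and before <= tol and after <= tol:
        return "case"
    return "excluded"


def _naive_control(rx, ssri, min_control=3):
    idx = _index_days(rx, ssri)
    others = [d for d in _other_ad_days(rx, ssri) if idx and d >= idx[0]]
    if not others and len(idx) >= min_control:
        return "control"
    return "excluded"


def naive_disc1(rx, ssri, record_end, lookahead=180):
    idx = _index_days(rx, ssri)
    if not idx:
        return "excluded"
    if len(idx) == 1:
        if record_end - idx[0] < lookahead:
            return "excluded"
        if any(d > idx[0] for d in _ad_days(rx)):
            return "excluded"
        return "case"
    return _naive_control(rx, ssri)


def naive_disc2(rx, ssri, record_end, lookahead=180, max_short=56, gap_days=90):
    idx = _index_days(rx, ssri)
    if not idx:
        return "excluded"
    windows = naive_windows(idx, gap_days)
    if len(windows) == 1 and windows[0][1] - windows[0][0] < max_short:
        last = idx[-1]
        if record_end - last >= lookahead and not any(d > last for d in _ad_days(rx)):
            return "case"
        if record_end - last < lookahead:
            return "excluded"
    return _naive_control(rx, ssri)


def naive_side_effects(rx, events, ssri, post, record_start, record_end, prior=30):
    idx = _index_days(rx, ssri)
    if not idx:
        return "excluded"
    first = idx[0]
    if record_start > first - prior or record_end < first + post:
        return "excluded"
    prior_codes = {c for d, c, _ in events if first - prior <= d <= first}
    for d, code, is_uku in events:
        if is_uku and first < d <= first + post and code not in prior_codes:
            return "case"
    return "control"
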