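"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles with plain Python loops —
deliberately sharing no code with the package — so descriptor values can be
cross-checked against hand arithmetic and closed forms.
"""

import math


def poincare_points(values, valid=None):
    if valid is None:
        valid = [True] * len(values)
    pts = []
    for i in range(len(values) - 1):
        if valid[i] and valid[i + 1]:
            pts.append((values[i], values[i + 1]))
    return pts


def _on_li(x, y):
    return abs(y - x) <= 1e-9 * max(1.0, abs(x))


def brute_descriptors(values, valid=None):
    """SD1, SD2, GI, GI_S, PI of a series by direct enumeration."""
    pts = poincare_points(values, valid)
    cx = sum(p[0] for p in pts) / len(pts)
    cy = sum(p[1] for p in pts) / len(pts)
    d_perp = [(y - x) / math.sqrt(2) for x, y in pts]
    d_par = [((x - cx) + (y - cy)) / math.sqrt(2) for x, y in pts]
    on_li = [_on_li(x, y) for x, y in pts]

    off = [i for i in range(len(pts)) if not on_li[i]]
    up = [i for i in off if d_perp[i] > 0]
    down = [i for i in off if d_perp[i] < 0]

    sd1 = math.sqrt(sum(d_perp[i] ** 2 for i in off) / len(off)) if off else float("nan")
    sd2 = math.sqrt(sum(d**2 for d in d_par) / len(pts)) if len(pts) >= 2 else float("nan")

    den_perp = sum(d_perp[i] ** 2 for i in off)
    gi = 100.0 * sum(d_perp[i] ** 2 for i in up) / den_perp if den_perp > 0 else float("nan")

    den_par = sum(d**2 for d in d_par)
    num_par = sum(d_par[i] ** 2 for i in up) + 0.5 * sum(
        d_par[i] ** 2 for i in range(len(pts)) if on_li[i]
    )
    gi_s = 100.0 * num_par / den_par if den_par > 0 else float("nan")

    pi = 100.0 * len(down) / len(off) if off else float("nan")
    return {"sd1": sd1, "sd2": sd2, "gi": gi, "gi_s": gi_s, "pi": pi, "n": len(off)}


def brute_cochran_q(rows):
    """Cochran Q statistic from per-subject binary rows, by the textbook formula."""
    k = len(rows[0])
    col = [sum(r[j] for r in rows) for j in range(k)]
    row_tot = [sum(r) for r in rows]
    num = (k - 1) * (k * sum(c * c for c in col) - sum(col) ** 2)
    den = k * sum(row_tot) - sum(t * t for t in row_tot)
    return num / den


def brute_holm(p_values):
    """Step-down Holm adjustment by direct definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_values[idx]))
        adjusted[idx] = running
    return adjusted
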