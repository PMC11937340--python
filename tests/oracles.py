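"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here works on explicit Python sets or whole-array scans and stays
deliberately naive; the implementation under test must agree with it exactly.
"""

from __future__ import annotations

import math

import numpy as np


def pixel_sets(labels: np.ndarray) -> dict[int, set]:
    out: dict[int, set] = {}
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            v = int(labels[r, c])
            if v > 0:
                out.setdefault(v, set()).add((r, c))
    return out


def sdc_sets(a: set, b: set, variant: str) -> float:
    inter = len(a & b)
    if variant == "sum_denominator":
        return 2.0 * inter / (len(a) + len(b))
    return 2.0 * inter / len(a | b)


def spillover_sets(target: set, prox_regions: dict[int, set],
                   threshold: float, variant: str) -> set:
    """Set-algebra transcription of the spill-over exclusion rule."""
    excluded: set = set()
    for a in prox_regions.values():
        overlap = a & target
        if not overlap:
            continue
        if a <= target:
            continue
        if sdc_sets(a, target, variant) < threshold:
            excluded |= overlap
    return target - excluded


def flood_fill_particles(binary: np.ndarray, fill_holes: bool) -> list[int]:
    """8-connected particle sizes via explicit flood fill (holes filled)."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    seen = np.zeros_like(binary)
    sizes = []
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = set()
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and binary[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            sizes.append(len(_fill_holes_set(comp, h, w)) if fill_holes
                         else len(comp))
    return sizes


def _fill_holes_set(comp: set, h: int, w: int) -> set:
    """comp plus its holes: background 4-connected cells not reachable from
    the image border."""
    stack = [(r, c) for r in (0, h - 1) for c in range(w) if (r, c) not in comp]
    stack += [(r, c) for c in (0, w - 1) for r in range(1, h - 1)
              if (r, c) not in comp]
    outside = set(stack)
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if (0 <= rr < h and 0 <= cc < w and (rr, cc) not in comp
                    and (rr, cc) not in outside):
                outside.add((rr, cc))
                stack.append((rr, cc))
    every = {(r, c) for r in range(h) for c in range(w)}
    holes = every - comp - outside
    return comp | holes


def student_t_one_sided(x, y, direction: str) -> tuple[float, float, float]:
    """Textbook pooled-variance two-sample t-test, one-sided.

    Returns (t, df, p). p is the tail probability in the stated direction
    ('greater': mean(x) > mean(y); 'less': mean(x) < mean(y)).
    """
    from scipy.stats import t as tdist

    x = [float(v) for v in x]
    y = [float(v) for v in y]
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    t_stat = (mx - my) / se
    p = tdist.sf(t_stat, df) if direction == "greater" else tdist.cdf(t_stat, df)
    return t_stat, float(df), float(p)


def anova_f(groups) -> float:
    """Hand-computed one-way ANOVA F = MS_between / MS_within."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
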