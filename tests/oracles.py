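"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (flood fill, exhaustive scans, full
enumeration) kept free of the package's own code paths.
"""

from itertools import combinations
from math import comb

import numpy as np


def flood_components(grid, connectivity=8):
    """Connected components of a boolean grid as a list of pixel sets."""
    grid = np.asarray(grid, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(grid)
    comps = []
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            if grid[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    pr, pc = stack.pop()
                    comp.add((pr, pc))
                    for dr, dc in nbrs:
                        nr, nc = pr + dr, pc + dc
                        if (
                            0 <= nr < grid.shape[0]
                            and 0 <= nc < grid.shape[1]
                            and grid[nr, nc]
                            and not seen[nr, nc]
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def otsu_bruteforce(values):
    """Exhaustive scan of between-class variance over integer thresholds."""
    vals = np.asarray(values, dtype=float)
    best_t, best_var = None, -1.0
    for t in range(int(vals.min()), int(vals.max()) + 1):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def frame_classify(component, origin, size):
    """Per-pixel edge classification: 'counted', 'excluded', or 'outside'.

    Counted when nothing crosses the right/bottom edge and the bottom-right
    corner of the pixel set's bounding box falls in the field; excluded when
    the component intersects the field but crosses a forbidden edge.
    """
    r0, c0 = origin
    r1, c1 = r0 + size[0] - 1, c0 + size[1] - 1
    max_r = max(r for r, _ in component)
    max_c = max(c for _, c in component)
    if r0 <= max_r <= r1 and c0 <= max_c <= c1:
        return "counted"
    inside = any(r0 <= r <= r1 and c0 <= c <= c1 for r, c in component)
    if inside and (max_r > r1 or max_c > c1):
        return "excluded"
    return "outside"


def chi2_stat(table):
    """Textbook Pearson statistic sum((O-E)^2 / E)."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / total
            stat += (t[i, j] - e) ** 2 / e
    return stat


def fisher_p_enumeration(table):
    """Two-sided Fisher p by full hypergeometric enumeration (2x2)."""
    t = np.asarray(table, dtype=int)
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = t.sum()

    def prob(a):
        return comb(r1, a) * comb(r2, c1 - a) / comb(n, c1)

    p_obs = prob(t[0, 0])
    return sum(
        prob(a)
        for a in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(a) <= p_obs * (1 + 1e-9)
    )


def mannwhitney_exact_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(idx_a):
        xs = [pooled[i] for i in idx_a]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        u = sum(1 for x in xs for y in ys if x > y) + 0.5 * sum(
            1 for x in xs for y in ys if x == y
        )
        return u

    obs = u_stat(set(range(n1)))
    n2 = len(b)
    mid = n1 * n2 / 2
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = u_stat(set(idx))
        total += 1
        if abs(u - mid) >= abs(obs - mid) - 1e-9:
            count += 1
    return count / total
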