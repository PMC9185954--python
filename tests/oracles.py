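"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (flood fill, union-find over all
pairs, ANOVA by direct summation) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(mask: np.ndarray, eight_connected: bool = True) -> np.ndarray:
    """Label foreground components by explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    if eight_connected:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels


def component_areas(mask: np.ndarray, eight_connected: bool = True) -> list[int]:
    labels = flood_fill_components(mask, eight_connected)
    return [int((labels == k).sum()) for k in range(1, labels.max() + 1)]


def threshold_graph_partition(points: np.ndarray, cutoff: float, min_size: int) -> np.ndarray:
    """Union-find connected components of the <=cutoff pairwise-distance graph.

    Returns per-point labels: -1 for components smaller than min_size,
    otherwise component ids numbered 1.. in order of first member index.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= cutoff:
                parent[find(i)] = find(j)

    labels = np.full(n, -1, dtype=int)
    next_id = 1
    roots_assigned: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        size = sum(1 for j in range(n) if find(j) == root)
        if size >= min_size and root not in roots_assigned:
            roots_assigned[root] = next_id
            next_id += 1
    for i in range(n):
        root = find(i)
        if root in roots_assigned:
            labels[i] = roots_assigned[root]
    return labels


def anova_icc_oneway(values: np.ndarray) -> float:
    """ICC(1) by direct-summation one-way ANOVA mean squares."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.sum() / values.size
    ss_between = 0.0
    ss_within = 0.0
    for i in range(n):
        row_mean = values[i].sum() / k
        ss_between += k * (row_mean - grand) ** 2
        for j in range(k):
            ss_within += (values[i, j] - row_mean) ** 2
    msr = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msr - msw) / (msr + (k - 1) * msw)


def anova_icc_twoway(values: np.ndarray) -> tuple[float, float]:
    """(ICC(A,1), ICC(C,1)) by direct-summation two-way ANOVA mean squares."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.sum() / values.size
    ss_rows = sum(k * (values[i].sum() / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (values[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_total = sum(
        (values[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc_c = (msr - mse) / (msr + (k - 1) * mse)
    icc_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return icc_a, icc_c


def shoelace_area(vertices: np.ndarray) -> float:
    """Analytic polygon area from the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 1], v[:, 0]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
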