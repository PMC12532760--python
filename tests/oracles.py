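"""Brute-force oracles, independent of the package implementation.

Everything here is deliberately naive: breadth-first search with explicit
queues, per-face loops, and exhaustive polyomino enumeration.  These are
the reference answers the fast array implementations are tested against.
"""

from collections import deque

import numpy as np


def bfs_patch_count(window, class_code, connectivity):
    """Connected components of class cells by explicit BFS."""
    window = np.asarray(window)
    rows, cols = window.shape
    if connectivity == 4:
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1),
                  (-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = set()
    count = 0
    for r in range(rows):
        for c in range(cols):
            if window[r, c] != class_code or (r, c) in seen:
                continue
            count += 1
            q = deque([(r, c)])
            seen.add((r, c))
            while q:
                cr, cc = q.popleft()
                for dr, dc in shifts:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < rows and 0 <= nc < cols \
                            and window[nr, nc] == class_code \
                            and (nr, nc) not in seen:
                        seen.add((nr, nc))
                        q.append((nr, nc))
    return count


def face_edge_count(window, class_code, count_boundary):
    """Edge faces by explicit enumeration of every cell face."""
    window = np.asarray(window)
    rows, cols = window.shape
    faces = 0
    for r in range(rows):
        for c in range(cols):
            if window[r, c] != class_code:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols:
                    if window[nr, nc] != class_code:
                        faces += 1
                elif count_boundary:
                    faces += 1
    return faces


def core_cell_set(window, class_code, neighborhood):
    """Core cells by per-cell neighbour check; border cells never core."""
    window = np.asarray(window)
    rows, cols = window.shape
    if neighborhood == 4:
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1),
                  (-1, -1), (-1, 1), (1, -1), (1, 1)]
    core = set()
    for r in range(rows):
        for c in range(cols):
            if window[r, c] != class_code:
                continue
            ok = True
            for dr, dc in shifts:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < rows and 0 <= nc < cols) \
                        or window[nr, nc] != class_code:
                    ok = False
                    break
            if ok:
                core.add((r, c))
    return core


def ndca_oracle(window, class_code, connectivity, neighborhood):
    """BFS component count of the core-cell set."""
    core = core_cell_set(window, class_code, neighborhood)
    if not core:
        return 0
    window = np.asarray(window)
    tmp = np.zeros_like(window)
    for r, c in core:
        tmp[r, c] = 1
    return bfs_patch_count(tmp, 1, connectivity)


def min_perimeter_formula(n):
    """Closed-form minimum polyomino perimeter (validated for n <= 9 by
    :func:`enumerate_min_perimeter`)."""
    import math

    if n == 0:
        return 0
    m = math.isqrt(n)
    if m * m == n:
        return 4 * m
    if n <= m * (m + 1):
        return 4 * m + 2
    return 4 * m + 4


def lsi_oracle(window, class_code):
    faces = face_edge_count(window, class_code, count_boundary=True)
    n = int((np.asarray(window) == class_code).sum())
    if n == 0:
        return None
    return faces / min_perimeter_formula(n)


def enumerate_min_perimeter(n):
    """Minimum perimeter over ALL fixed polyominoes of n cells, by
    exhaustive growth enumeration (practical for n <= 9)."""
    if n == 0:
        return 0

    def normalize(cells):
        r0 = min(r for r, _ in cells)
        c0 = min(c for _, c in cells)
        return frozenset((r - r0, c - c0) for r, c in cells)

    shapes = {frozenset([(0, 0)])}
    for _ in range(n - 1):
        nxt = set()
        for shape in shapes:
            for r, c in shape:
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    cell = (r + dr, c + dc)
                    if cell not in shape:
                        nxt.add(normalize(shape | {cell}))
        shapes = nxt

    def perimeter(shape):
        p = 0
        for r, c in shape:
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                if (r + dr, c + dc) not in shape:
                    p += 1
        return p

    return min(perimeter(s) for s in shapes)


def random_windows(n_windows, size=12, n_classes_range=(3, 5), seed=0,
                   clustered=True):
    """Seeded random categorical test windows, mixing speckle and blocky
    structure so patches, corridors and cores all occur."""
    rng = np.random.default_rng(seed)
    for _ in range(n_windows):
        k = int(rng.integers(n_classes_range[0], n_classes_range[1] + 1))
        w = rng.integers(1, k + 1, size=(size, size))
        if clustered and rng.random() < 0.7:
            # paste a few rectangles to create solid patches and cores
            for _ in range(int(rng.integers(1, 4))):
                r0, c0 = rng.integers(0, size - 3, 2)
                h, wd = rng.integers(2, 6, 2)
                w[r0 : r0 + h, c0 : c0 + wd] = int(rng.integers(1, k + 1))
        yield w.astype(np.uint8)
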