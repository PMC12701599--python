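"""Independent brute-force border-following oracle for contour tests.

A deliberately naive, definition-first implementation: components are found
by breadth-first search over the 8-neighbourhood, the boundary walk orders
neighbours by compass angle computed with atan2 at every step, and cycle
detection stores every visited (pixel, came-from-direction) state in a set.
It shares no code with the production tracer.
"""

from __future__ import annotations

import math

import numpy as np


def components_8(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components as sets of (x, y), by BFS, in discovery order
    of their topmost-leftmost pixel."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                comp = set()
                queue = [(x, y)]
                seen[y, x] = True
                while queue:
                    cx, cy = queue.pop()
                    comp.add((cx, cy))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            nx, ny = cx + dx, cy + dy
                            if (0 <= nx < w and 0 <= ny < h
                                    and mask[ny, nx] and not seen[ny, nx]):
                                seen[ny, nx] = True
                                queue.append((nx, ny))
                comps.append(comp)
    return comps


def _clockwise_angle(dx: int, dy: int) -> float:
    """Angle of a neighbour offset measured clockwise from East, screen
    coordinates (y grows downward)."""
    a = math.atan2(dy, dx)  # screen-clockwise is positive with y down
    return a % (2 * math.pi)


def trace_boundary(comp: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Clockwise outer-boundary pixel sequence of one component."""
    start = min(comp, key=lambda p: (p[1], p[0]))  # topmost, then leftmost
    if len(comp) == 1:
        return [start]
    # walk: state is (pixel, backtrack offset); neighbours scanned clockwise
    # starting just past the backtrack direction
    cur = start
    back = (-1, 0)  # exterior West of the start pixel
    state0 = (cur, back)
    seq: list[tuple[int, int]] = []
    states: dict[tuple, int] = {}
    while True:
        key = (cur, back)
        if key in states:
            return seq[states[key]:]
        states[key] = len(seq)
        seq.append(cur)
        base = _clockwise_angle(*back)
        # sort all 8 neighbour offsets by clockwise angle past the backtrack
        offs = [(dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dx, dy) != (0, 0)]
        offs.sort(key=lambda o: ((_clockwise_angle(*o) - base) % (2 * math.pi)
                                 or 2 * math.pi))
        moved = False
        last_bg = back
        for dx, dy in offs:
            cand = (cur[0] + dx, cur[1] + dy)
            if cand in comp:
                back = (last_bg[0] + cur[0] - cand[0],
                        last_bg[1] + cur[1] - cand[1])
                cur = cand
                moved = True
                break
            last_bg = (dx, dy)
        if not moved:
            return seq


def oracle_contours(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """Outer boundary pixel cycles for every component, largest-area first."""
    comps = components_8(mask)
    comps.sort(key=len, reverse=True)
    return [trace_boundary(c) for c in comps]


def closed_perimeter(points: list[tuple[int, int]]) -> float:
    """Sum of Euclidean steps around the closed polygon."""
    if len(points) <= 1:
        return 0.0
    total = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:] + points[:1]):
        total += math.hypot(x1 - x0, y1 - y0)
    return total
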