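"""Independent brute-force oracles used by the unit and acceptance tests."""

from collections import deque

import numpy as np


def flood_fill_sizes(mask: np.ndarray, connectivity: int = 4,
                     periodic: bool = True) -> list[int]:
    """Connected-component sizes of a boolean grid by explicit BFS flood
    fill (no scipy), with optional periodic wrapping."""
    nx, ny = mask.shape
    if connectivity == 4:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    elif connectivity == 8:
        steps = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                 if (dx, dy) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    for sx in range(nx):
        for sy in range(ny):
            if not mask[sx, sy] or seen[sx, sy]:
                continue
            q = deque([(sx, sy)])
            seen[sx, sy] = True
            size = 0
            while q:
                x, y = q.popleft()
                size += 1
                for dx, dy in steps:
                    px, py = x + dx, y + dy
                    if periodic:
                        px, py = px % nx, py % ny
                    elif not (0 <= px < nx and 0 <= py < ny):
                        continue
                    if mask[px, py] and not seen[px, py]:
                        seen[px, py] = True
                        q.append((px, py))
            sizes.append(size)
    return sizes


def coverage_oracle(points_xy: np.ndarray, reach: np.ndarray,
                    box_xy: np.ndarray, nx: int, ny: int) -> np.ndarray:
    """Boolean (nx, ny) coverage mask: cell centre within ``reach`` of any
    point in the periodic x-y plane, by brute force over all cells."""
    cx, cy = box_xy[0] / nx, box_xy[1] / ny
    centers_x = (np.arange(nx) + 0.5) * cx
    centers_y = (np.arange(ny) + 0.5) * cy
    covered = np.zeros((nx, ny), dtype=bool)
    for (px, py), r in zip(points_xy, reach):
        dx = centers_x - px
        dx -= box_xy[0] * np.round(dx / box_xy[0])
        dy = centers_y - py
        dy -= box_xy[1] * np.round(dy / box_xy[1])
        covered |= dx[:, None] ** 2 + dy[None, :] ** 2 < r * r
    return covered
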