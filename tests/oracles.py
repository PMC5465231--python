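"""Independent brute-force oracles for morphology, voting and overlap.

These re-implement the per-voxel definitions directly (padded-array
neighbourhood tests, breadth-first searches), deliberately avoiding both
scipy.ndimage and the package's own code paths, so they can serve as
independent references in equivalence tests.
"""

from collections import deque

import numpy as np

FOUR_N = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def square_offsets(side: int) -> list[tuple[int, int]]:
    r = side // 2
    return [(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1)]


def erode2d(mask: np.ndarray, offsets) -> np.ndarray:
    """A voxel survives iff every offset neighbour is inside the mask
    (outside the array counts as background)."""
    nx, ny = mask.shape
    out = np.zeros_like(mask)
    for x in range(nx):
        for y in range(ny):
            if not mask[x, y]:
                continue
            ok = True
            for dx, dy in offsets:
                xx, yy = x + dx, y + dy
                if not (0 <= xx < nx and 0 <= yy < ny and mask[xx, yy]):
                    ok = False
                    break
            out[x, y] = ok
    return out


def dilate2d(mask: np.ndarray, offsets) -> np.ndarray:
    nx, ny = mask.shape
    out = np.zeros_like(mask)
    for x in range(nx):
        for y in range(ny):
            for dx, dy in offsets:
                xx, yy = x + dx, y + dy
                if 0 <= xx < nx and 0 <= yy < ny and mask[xx, yy]:
                    out[x, y] = True
                    break
    return out


def fill_holes2d(mask: np.ndarray) -> np.ndarray:
    """Background not reachable from the border (4-connectivity) is filled."""
    nx, ny = mask.shape
    reachable = np.zeros_like(mask)
    queue: deque = deque()
    for x in range(nx):
        for y in (0, ny - 1):
            if not mask[x, y] and not reachable[x, y]:
                reachable[x, y] = True
                queue.append((x, y))
    for y in range(ny):
        for x in (0, nx - 1):
            if not mask[x, y] and not reachable[x, y]:
                reachable[x, y] = True
                queue.append((x, y))
    while queue:
        x, y = queue.popleft()
        for dx, dy in FOUR_N:
            xx, yy = x + dx, y + dy
            if 0 <= xx < nx and 0 <= yy < ny and not mask[xx, yy] and not reachable[xx, yy]:
                reachable[xx, yy] = True
                queue.append((xx, yy))
    return mask | ~reachable


def largest_cc3d(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component via BFS."""
    nx, ny, nz = mask.shape
    seen = np.zeros_like(mask)
    best: list = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                comp = [(x, y, z)]
                seen[x, y, z] = True
                queue = deque(comp)
                while queue:
                    cx, cy, cz = queue.popleft()
                    for dx, dy, dz in offsets:
                        xx, yy, zz = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= xx < nx
                            and 0 <= yy < ny
                            and 0 <= zz < nz
                            and mask[xx, yy, zz]
                            and not seen[xx, yy, zz]
                        ):
                            seen[xx, yy, zz] = True
                            comp.append((xx, yy, zz))
                            queue.append((xx, yy, zz))
                if len(comp) > len(best):
                    best = comp
    out = np.zeros_like(mask)
    for x, y, z in best:
        out[x, y, z] = True
    return out


def strip_skin_oracle(body, ff, r2s, ff_max, r2s_min, closing_se, final_se, max_iter=50):
    """Per-voxel re-implementation of the full skin-strip sequence."""
    mask = body.copy()
    skin_like = (ff <= ff_max) & (r2s >= r2s_min)
    for _ in range(max_iter):
        removed_any = False
        new = mask.copy()
        for k in range(mask.shape[2]):
            boundary = mask[:, :, k] & ~erode2d(mask[:, :, k], FOUR_N)
            rm = boundary & skin_like[:, :, k]
            if rm.any():
                removed_any = True
                new[:, :, k] &= ~rm
        mask = new
        if not removed_any:
            break
    mask = largest_cc3d(mask)
    out = np.zeros_like(mask)
    off_close = square_offsets(closing_se)
    for k in range(mask.shape[2]):
        sl = erode2d(dilate2d(mask[:, :, k], off_close), off_close)
        out[:, :, k] = fill_holes2d(sl)
    mask = out
    out = np.zeros_like(mask)
    off_final = square_offsets(final_se)
    for k in range(mask.shape[2]):
        out[:, :, k] = erode2d(mask[:, :, k], off_final)
    return out


def fine_adjust_oracle(voi, ff, r2s, ff_min, r2s_max):
    mask = voi & (ff >= ff_min)
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        out[:, :, k] = erode2d(mask[:, :, k], FOUR_N)
    return out & (r2s <= r2s_max)


def refine_oracle(mask, water, fat, threshold, dil_se, ero_se):
    low = mask & ((water + fat) <= threshold)
    off_d = square_offsets(dil_se)
    off_e = square_offsets(ero_se)
    airbone = np.zeros_like(low)
    for k in range(low.shape[2]):
        sl = fill_holes2d(dilate2d(low[:, :, k], off_d))
        airbone[:, :, k] = erode2d(sl, off_e)
    return mask & ~airbone


def vote_oracle(coverage_stack, represented_stack, threshold):
    """Exhaustive per-voxel modified majority vote."""
    shape = coverage_stack.shape[1:]
    out = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(shape):
        m = 0
        v = 0
        for a in range(coverage_stack.shape[0]):
            if represented_stack[(a,) + idx]:
                m += 1
                if coverage_stack[(a,) + idx] >= threshold:
                    v += 1
        out[idx] = m >= 1 and v > m / 2
    return out


def overlap_oracle(mas, ref, domain):
    """Triple-loop TP/FP/FN counting."""
    tp = fp = fn = 0
    nx, ny, nz = mas.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not domain[x, y, z]:
                    continue
                a, b = mas[x, y, z], ref[x, y, z]
                if a and b:
                    tp += 1
                elif a and not b:
                    fp += 1
                elif b and not a:
                    fn += 1
    return tp, fp, fn
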