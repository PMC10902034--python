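"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorized/library code paths of the package:
scalar loops, explicit shifts, and hand-rolled boundary tracing.
"""

import math

import numpy as np

from bpq.grid import TIP_LEFT, TIP_RIGHT, TIP_STEM, TRUNK


def brute_partition(mask_grid, design, tip_fraction):
    """Scalar-loop nearest-skeleton-point assignment of every pixel."""
    segs = design.skeleton()
    tip_label = {"stem": TIP_STEM, "left": TIP_LEFT, "right": TIP_RIGHT}
    labels = np.zeros(mask_grid.shape, dtype=np.uint8)
    fg = np.asarray(mask_grid.pixels).astype(bool)
    x0, y0 = mask_grid.origin
    ps = mask_grid.pixel_size
    for r in range(fg.shape[0]):
        for c in range(fg.shape[1]):
            if not fg[r, c]:
                continue
            px, py = x0 + c * ps, y0 - r * ps
            dists = []
            for name, a, b in segs:
                ax, ay = a
                bx, by = b
                vx, vy = bx - ax, by - ay
                t = ((px - ax) * vx + (py - ay) * vy) / (vx * vx + vy * vy)
                t = min(1.0, max(0.0, t))
                d = math.hypot(px - (ax + t * vx), py - (ay + t * vy))
                length = design.segment_length(name)
                dists.append((d, (1.0 - t) * length, name, length))
            dists.sort(key=lambda item: item[0])
            d0, arc, name, length = dists[0]
            if dists[1][0] - d0 < 1e-9 * max(1.0, design.stem_length
                                             + design.branch_length):
                labels[r, c] = TRUNK
            elif arc <= tip_fraction * length:
                labels[r, c] = tip_label[name]
            else:
                labels[r, c] = TRUNK
    return labels


def naive_opening(fg, footprint):
    """Opening as explicit erosion-then-dilation via array shifts."""
    fg = np.asarray(fg).astype(bool)
    offs = np.argwhere(footprint) - np.array(footprint.shape) // 2
    pad = int(np.abs(offs).max()) + 1
    padded = np.pad(fg, pad)

    def shift(img, dr, dc):
        out = np.zeros_like(img)
        rs = slice(max(0, dr), img.shape[0] + min(0, dr))
        cs = slice(max(0, dc), img.shape[1] + min(0, dc))
        rs_src = slice(max(0, -dr), img.shape[0] + min(0, -dr))
        cs_src = slice(max(0, -dc), img.shape[1] + min(0, -dc))
        out[rs, cs] = img[rs_src, cs_src]
        return out

    eroded = np.ones_like(padded)
    for dr, dc in offs:
        eroded &= shift(padded, -dr, -dc)
    dilated = np.zeros_like(padded)
    for dr, dc in offs:
        dilated |= shift(eroded, dr, dc)
    return dilated[pad:-pad, pad:-pad]


def moore_chain(fg):
    """Ordered closed boundary pixel chain via Moore-neighbour tracing."""
    fg = np.asarray(fg).astype(bool)
    rows, cols = np.nonzero(fg)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    # clockwise neighbourhood starting west
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1),
            (0, 1), (1, 1), (1, 0), (1, -1)]

    def is_fg(p):
        r, c = p
        return 0 <= r < fg.shape[0] and 0 <= c < fg.shape[1] and fg[r, c]

    chain = [start]
    backtrack = 0  # index of the neighbour we entered from (west of start)
    current = start
    limit = 10 * len(rows) + 10
    for _ in range(limit):
        found = None
        for k in range(8):
            idx = (backtrack + k) % 8
            cand = (current[0] + nbrs[idx][0], current[1] + nbrs[idx][1])
            if is_fg(cand):
                found = (cand, idx)
                break
        if found is None:  # isolated pixel
            break
        nxt, idx = found
        if nxt == start and len(chain) > 2:
            break
        chain.append(nxt)
        # new backtrack: neighbour just before the one we moved to,
        # relative to the new current pixel
        backtrack = (idx + 5) % 8
        current = nxt
    return chain


def chain_lengths_by_label(fg, labels, pixel_size):
    """Boundary chain length (µm) apportioned to each pixel label.

    Uses the Vossepoel–Smeulders step weights (0.948 for axis-aligned,
    1.343 for diagonal moves) so raw staircase bias does not inflate the
    estimate.
    """
    chain = moore_chain(fg)
    out = {}
    n = len(chain)
    for i in range(n):
        p, q = chain[i], chain[(i + 1) % n]
        step = 0.948 if abs(p[0] - q[0]) + abs(p[1] - q[1]) == 1 else 1.343
        lab = int(labels[p])
        out[lab] = out.get(lab, 0.0) + step * pixel_size
    return out
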