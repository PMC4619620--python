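"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the most naive correct algorithm
(scan-order flood fill, full sign-assignment enumeration, sort-based
percentiles) and stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

MAD_TO_SD = 1.4826


def brute_force_detect(img: np.ndarray, k_sigma: float = 5.0,
                       connectivity: int = 8, um_per_px: float = 1.0,
                       min_diameter_um: float = 0.0) -> list[dict]:
    """Flood-fill object detection with the same threshold contract.

    Returns one dict per object, in scan order of the object's first pixel,
    with keys ``first_index``, ``area``, ``intensity``, ``centroid``.
    """
    img = np.asarray(img, dtype=float)
    bg = float(np.median(img))
    sd = MAD_TO_SD * float(np.median(np.abs(img - bg)))
    for _ in range(3):  # same sigma-clipped background contract
        sel = np.abs(img - bg) <= 3.0 * sd
        if not sel.any():
            break
        bg = float(np.median(img[sel]))
        sd = MAD_TO_SD * float(np.median(np.abs(img[sel] - bg)))
    thr = bg + k_sigma * sd
    mask = img > thr
    h, w = mask.shape
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    out = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            pixels = []
            while queue:
                r, c = queue.popleft()
                pixels.append((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                            and not seen[rr, cc]):
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            area = len(pixels)
            equiv_diameter_um = 2.0 * np.sqrt(area / np.pi) * um_per_px
            if equiv_diameter_um < min_diameter_um:
                continue
            intensity = max(sum(img[r, c] - bg for r, c in pixels), 0.0)
            rows = [p[0] for p in pixels]
            cols = [p[1] for p in pixels]
            out.append({
                "first_index": min(r * w + c for r, c in pixels),
                "area": area,
                "intensity": intensity,
                "centroid": (float(np.mean(rows)), float(np.mean(cols))),
            })
    out.sort(key=lambda d: d["first_index"])
    return out


def enumerate_signed_rank_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    # mid-ranks by explicit averaging of sorted positions
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        n_le += w <= w_obs + 1e-12
        n_ge += w >= w_obs - 1e-12
        total += 1
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


def sort_percentile(values, q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    pos = q / 100.0 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
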