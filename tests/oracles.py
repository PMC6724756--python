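"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by the most literal method
available — exhaustive flood search, per-pixel distance scans, nested-loop
tallies — sharing no code path with the implementation it checks.
"""

from collections import deque

import numpy as np


def flood_maxima(a: np.ndarray, tol: float) -> list:
    """Literal tolerance-maxima search: enumerate maximal plateaus, flood
    each over pixels > v - tol, reject on reaching higher ground; the global
    survivors stand against the image minimum; mutually reachable
    equal-valued plateaus merge into one focus at their joint centroid.
    Returns sorted (row, col, peak_value) triples.
    """
    a = np.asarray(a, dtype=float)
    h, w = a.shape
    vmin = a.min()

    visited = np.zeros(a.shape, dtype=bool)
    plateaus = []  # (value, [(r, c), ...]) for maximal plateaus only
    for r in range(h):
        for c in range(w):
            if visited[r, c]:
                continue
            v = a[r, c]
            comp, q, is_max = [], deque([(r, c)]), True
            visited[r, c] = True
            while q:
                y, x = q.popleft()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == 0 and dx == 0:
                            continue
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            if a[yy, xx] == v and not visited[yy, xx]:
                                visited[yy, xx] = True
                                q.append((yy, xx))
                            elif a[yy, xx] > v:
                                is_max = False
            if is_max and len(comp) < h * w:
                plateaus.append((v, comp))

    accepted, reach = [], {}
    for i, (v, comp) in enumerate(plateaus):
        seen = np.zeros(a.shape, dtype=bool)
        for y, x in comp:
            seen[y, x] = True
        q = deque(comp)
        ok = True
        while q and ok:
            y, x = q.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and not seen[yy, xx] and a[yy, xx] > v - tol:
                        if a[yy, xx] > v:
                            ok = False
                            break
                        seen[yy, xx] = True
                        q.append((yy, xx))
                if not ok:
                    break
        if ok and v - vmin < tol:
            ok = False  # global survivor below tolerance over the image minimum
        if ok:
            reached = {
                j
                for j, (v2, comp2) in enumerate(plateaus)
                if j != i and v2 == v and seen[comp2[0][0], comp2[0][1]]
            }
            accepted.append(i)
            reach[i] = reached

    groups, grouped = [], set()
    for i in accepted:
        if i in grouped:
            continue
        grp, q = {i}, deque([i])
        while q:
            j = q.popleft()
            for k in reach.get(j, ()):
                if k in accepted and k not in grp:
                    grp.add(k)
                    q.append(k)
        grouped |= grp
        groups.append(grp)

    out = []
    for grp in groups:
        pix = [p for i in grp for p in plateaus[i][1]]
        rr = int(np.floor(np.mean([p[0] for p in pix]) + 0.5))
        cc = int(np.floor(np.mean([p[1] for p in pix]) + 0.5))
        out.append((rr, cc, plateaus[next(iter(grp))][0]))
    return sorted(out)


def nearest_label_dilation(labels: np.ndarray, radius: float) -> np.ndarray:
    """Per-pixel exhaustive nearest-nucleus assignment within ``radius``.

    For every background pixel, scan every labelled pixel, keep the minimum
    Euclidean distance; ties go to the lower label id.
    """
    labels = np.asarray(labels)
    out = labels.astype(np.int64, copy=True)
    lab_pix = np.argwhere(labels > 0)
    lab_val = labels[labels > 0]
    if lab_pix.size == 0:
        return out
    for r, c in np.argwhere(labels == 0):
        d2 = (lab_pix[:, 0] - r) ** 2 + (lab_pix[:, 1] - c) ** 2
        best = d2.min()
        if best <= radius * radius:
            out[r, c] = lab_val[d2 == best].min()
    return out


def summary_by_loops(flag_rows: list, channels: list) -> dict:
    """Nested-loop recomputation of every region-summary field.

    flag_rows: one dict {channel: bool} per cell.  Returns percent_positive,
    conditional (None on empty denominator) and exact-subset class counts.
    """
    n = len(flag_rows)
    percent_positive = {}
    for ch in channels:
        k = 0
        for row in flag_rows:
            if row[ch]:
                k += 1
        percent_positive[ch] = 100.0 * k / n
    conditional = {}
    for a in channels:
        for b in channels:
            if a == b:
                continue
            denom = num = 0
            for row in flag_rows:
                if row[b]:
                    denom += 1
                    if row[a]:
                        num += 1
            conditional[(a, b)] = None if denom == 0 else 100.0 * num / denom
    from itertools import combinations

    class_counts = {}
    for k in range(len(channels) + 1):
        for subset in combinations(channels, k):
            cnt = 0
            for row in flag_rows:
                if all(row[ch] == (ch in subset) for ch in channels):
                    cnt += 1
            class_counts[subset] = cnt
    return {
        "percent_positive": percent_positive,
        "conditional": conditional,
        "class_counts": class_counts,
    }


def priority_flood_watershed(dist: np.ndarray, seeds: list, mask: np.ndarray) -> np.ndarray:
    """Two-(or more-)seed region growing on a distance map: pixels are claimed
    in order of descending distance value from the given seed points —
    an independent re-derivation of the watershed partition."""
    import heapq

    h, w = dist.shape
    out = np.zeros((h, w), dtype=np.int64)
    heap = []
    for i, (r, c) in enumerate(seeds, start=1):
        out[r, c] = i
        heapq.heappush(heap, (-dist[r, c], r, c, i))
    while heap:
        negd, r, c, lab = heapq.heappop(heap)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                rr, cc = r + dy, c + dx
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and out[rr, cc] == 0:
                    out[rr, cc] = lab
                    heapq.heappush(heap, (-dist[rr, cc], rr, cc, lab))
    return out
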