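"""Independent brute-force reference implementations used to validate the
fast production code on small grids.  Everything here is written for
clarity, not speed, and deliberately shares no code with the package."""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbours(connectivity: int):
    offs = []
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                if (i, j, k) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(i) + abs(j) + abs(k) != 1:
                    continue
                offs.append((i, j, k))
    return offs


def flood_components(mask: np.ndarray, connectivity: int):
    """BFS labelling in scan order; returns (labels, sizes)."""
    labels = np.zeros(mask.shape, dtype=int)
    sizes = []
    offs = neighbours(connectivity)
    code = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx] and labels[idx] == 0:
            code += 1
            q = deque([idx])
            labels[idx] = code
            n = 0
            while q:
                p = q.popleft()
                n += 1
                for o in offs:
                    qq = tuple(p[a] + o[a] for a in range(3))
                    if all(0 <= qq[a] < mask.shape[a] for a in range(3)):
                        if mask[qq] and labels[qq] == 0:
                            labels[qq] = code
                            q.append(qq)
            sizes.append(n)
    return labels, sizes


def chessboard(mask: np.ndarray) -> np.ndarray:
    pts = np.argwhere(mask)
    out = np.empty(mask.shape, dtype=int)
    for idx in np.ndindex(mask.shape):
        d = np.abs(pts - np.array(idx)).max(axis=1)
        out[idx] = d.min()
    return out


def euclidean(mask: np.ndarray, spacing) -> np.ndarray:
    pts = np.argwhere(mask).astype(float) * np.asarray(spacing)
    out = np.empty(mask.shape, dtype=float)
    for idx in np.ndindex(mask.shape):
        p = np.array(idx, dtype=float) * np.asarray(spacing)
        out[idx] = np.sqrt(((pts - p) ** 2).sum(axis=1)).min()
    return out


def dilate(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Set-union dilation by explicit offsets (element center = middle)."""
    ctr = [s // 2 for s in element.shape]
    out = np.zeros_like(mask)
    for off in np.argwhere(element):
        o = off - ctr
        for idx in np.argwhere(mask):
            q = idx - o  # reflected element, matching binary dilation
            if all(0 <= q[a] < mask.shape[a] for a in range(3)):
                out[tuple(q)] = True
    return out


def erode(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    ctr = [s // 2 for s in element.shape]
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        ok = True
        for off in np.argwhere(element):
            q = idx + (off - ctr)
            if not all(0 <= q[a] < mask.shape[a] for a in range(3)) or not mask[tuple(q)]:
                ok = False
                break
        out[tuple(idx)] = ok
    return out


def perimeter_fraction(component: np.ndarray, reference: np.ndarray) -> float:
    per = set()
    for idx in np.argwhere(component):
        for o in neighbours(6):
            q = tuple(idx[a] + o[a] for a in range(3))
            if all(0 <= q[a] < component.shape[a] for a in range(3)):
                if not component[q]:
                    per.add(q)
    if not per:
        return 0.0
    return sum(1 for q in per if reference[q]) / len(per)


def pearson(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fuse_voxelwise(target, atlas_list, patch_half, radius_map, spacing, beta):
    """Exhaustive per-voxel weighted-voting fusion; the independent oracle
    for the vectorised implementation.  Offsets are searched in the same
    deterministic (distance, lexicographic) order."""
    shape = target.shape
    out = np.zeros(shape, dtype=int)

    for idx in np.ndindex(shape):
        r = radius_map[idx]
        offs = []
        h = [int(np.floor(r / s)) for s in spacing]
        for i in range(-h[0], h[0] + 1):
            for j in range(-h[1], h[1] + 1):
                for k in range(-h[2], h[2] + 1):
                    d = np.sqrt((i * spacing[0]) ** 2 + (j * spacing[1]) ** 2
                                + (k * spacing[2]) ** 2)
                    if d <= r + 1e-9:
                        offs.append((d, (i, j, k)))
        offs.sort(key=lambda t: (t[0], t[1]))

        weights: dict[int, float] = {}
        total = 0.0
        centre_labels = []
        for inten, lab in atlas_list:
            best = -np.inf
            best_lab = 0
            for _, o in offs:
                c = tuple(idx[a] + o[a] for a in range(3))
                # overlap of the target patch at idx with the shifted atlas
                # patch; voxels whose shifted position leaves the grid are
                # excluded from the correlation (valid-overlap semantics)
                pa, pb = [], []
                for di in range(-patch_half[0], patch_half[0] + 1):
                    for dj in range(-patch_half[1], patch_half[1] + 1):
                        for dk in range(-patch_half[2], patch_half[2] + 1):
                            t_ix = (idx[0] + di, idx[1] + dj, idx[2] + dk)
                            a_ix = tuple(t_ix[a] + o[a] for a in range(3))
                            if not all(0 <= t_ix[a] < shape[a] for a in range(3)):
                                continue
                            if all(0 <= a_ix[a] < shape[a] for a in range(3)):
                                pa.append(target[t_ix])
                                pb.append(inten[a_ix])
                r_sim = pearson(pa, pb) if len(pa) >= 2 else 0.0
                lab_here = (
                    int(lab[c]) if all(0 <= c[a] < shape[a] for a in range(3)) else 0
                )
                if r_sim > best:
                    best = r_sim
                    best_lab = lab_here
            w = max(best, 0.0) ** beta
            weights[best_lab] = weights.get(best_lab, 0.0) + w
            total += w
            ci = idx
            centre_labels.append(int(lab[ci]))
        if total > 0:
            best_w = -1.0
            win = 0
            for code in sorted(weights):
                if weights[code] > best_w:
                    best_w = weights[code]
                    win = code
            out[idx] = win
        else:
            counts = {}
            for c in centre_labels:
                counts[c] = counts.get(c, 0) + 1
            best_c = -1
            win = 0
            for code in sorted(counts):
                if counts[code] > best_c:
                    best_c = counts[code]
                    win = code
            out[idx] = win
    return out
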