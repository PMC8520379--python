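"""Brute-force reference implementations used as independent oracles.

Everything here is written as plain double loops over explicit formulas,
deliberately sharing no code with the package implementation.
"""

import math

import numpy as np


def brute_force_ratio_match(src_desc, dst_desc, ratio):
    """All-pairs distance matching with ratio test and one-to-one rule.

    Returns a set of (src_index, dst_index) pairs.
    """
    src_desc = np.asarray(src_desc)
    dst_desc = np.asarray(dst_desc)
    claims = []
    for i in range(len(src_desc)):
        dists = []
        for j in range(len(dst_desc)):
            dists.append((math.dist(src_desc[i], dst_desc[j]), j))
        dists.sort()
        d1, j1 = dists[0]
        d2 = dists[1][0] if len(dists) > 1 else math.inf
        if d1 < ratio * d2:
            claims.append((d1, i, j1))
    claims.sort()
    taken = set()
    kept = set()
    for d1, i, j in claims:
        if j in taken:
            continue
        taken.add(j)
        kept.add((i, j))
    return kept


def prescreen_oracle(slopes, t):
    """Exhaustive slope-census pre-check; returns a keep mask.

    Every slope is a candidate centre; the centre with the largest count of
    slopes within t wins, ties resolved by smaller |centre| then positive
    before negative.
    """
    slopes = list(map(float, slopes))
    best = None
    for centre in slopes:
        count = sum(1 for s in slopes if abs(s - centre) <= t)
        key = (-count, abs(centre), -centre)
        if best is None or key < best[0]:
            best = (key, centre)
    centre = best[1]
    return [abs(s - centre) <= t for s in slopes]


def disparity_gradient_oracle(m_src, m_dst, n_src, n_dst):
    """|d(m) - d(n)| / |c(m) - c(n)| from raw coordinates."""
    dm = (m_dst[0] - m_src[0], m_dst[1] - m_src[1])
    dn = (n_dst[0] - n_src[0], n_dst[1] - n_src[1])
    cm = ((m_src[0] + m_dst[0]) / 2.0, (m_src[1] + m_dst[1]) / 2.0)
    cn = ((n_src[0] + n_dst[0]) / 2.0, (n_src[1] + n_dst[1]) / 2.0)
    sep = math.hypot(cm[0] - cn[0], cm[1] - cn[1])
    if sep == 0.0:
        return math.inf
    return math.hypot(dm[0] - dn[0], dm[1] - dn[1]) / sep


def disparity_filter_oracle(src_pts, dst_pts, K, max_gradient=2.0):
    """Exhaustive K-nearest-neighbour median disparity-gradient filter.

    Returns a keep mask over the (preselected) matches given as coordinate
    arrays.  Neighbour order: distance between source points, then
    neighbour x, then y; matches with identical coordinates are not each
    other's neighbours.
    """
    n = len(src_pts)
    k_eff = min(K, n - 1)
    keep = []
    for i in range(n):
        cands = []
        for j in range(n):
            if j == i:
                continue
            if tuple(src_pts[j]) == tuple(src_pts[i]) and tuple(dst_pts[j]) == tuple(
                dst_pts[i]
            ):
                continue
            d = math.dist(src_pts[i], src_pts[j])
            cands.append((d, src_pts[j][0], src_pts[j][1], j))
        cands.sort()
        if not cands:
            keep.append(True)
            continue
        grads = [
            disparity_gradient_oracle(src_pts[i], dst_pts[i], src_pts[j], dst_pts[j])
            for *_, j in cands[:k_eff]
        ]
        grads.sort()
        m = len(grads)
        med = grads[m // 2] if m % 2 else 0.5 * (grads[m // 2 - 1] + grads[m // 2])
        keep.append(med < max_gradient)
    return keep
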