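"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (BFS flood fill, exhaustive pair
enumeration, numerical integration) and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn


def neighbor_offsets(connectivity: int):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int = 26):
    """List of voxel-index frozensets, one per connected component (BFS)."""
    mask = np.asarray(mask) > 0
    offs = neighbor_offsets(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in offs:
                w = tuple(a + b for a, b in zip(v, d))
                if all(0 <= c < n for c, n in zip(w, mask.shape)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return comps


def brute_force_vote(hard_masks: list[np.ndarray], min_votes: int,
                     connectivity: int = 26) -> np.ndarray:
    """Reference lesion-wise voting: enumerate union components, count
    orientations overlapping each, keep those with enough votes."""
    union = np.zeros(hard_masks[0].shape, dtype=bool)
    for m in hard_masks:
        union |= m > 0
    out = np.zeros_like(union)
    for comp in flood_fill_components(union, connectivity):
        votes = sum(1 for m in hard_masks if any(m[v] for v in comp))
        if votes >= min_votes:
            for v in comp:
                out[v] = True
    return out


def brute_force_match(pred: np.ndarray, gt: np.ndarray,
                      min_overlap_fraction: float,
                      connectivity: int = 26):
    """Reference lesion matching: (TP_l, FP_l, FN_l) by exhaustive
    component enumeration on both sides."""
    pred = np.asarray(pred) > 0
    gt_comps = flood_fill_components(gt, connectivity)
    pred_comps = flood_fill_components(pred, connectivity)
    gt_set = {v for c in flood_fill_components(gt, connectivity) for v in c}
    tp = fn = 0
    for comp in gt_comps:
        covered = sum(1 for v in comp if pred[v])
        if covered / len(comp) >= min_overlap_fraction:
            tp += 1
        else:
            fn += 1
    fp = sum(1 for comp in pred_comps
             if not any(v in gt_set for v in comp))
    return tp, fp, fn


def t_cdf_by_quadrature(t: float, df: int) -> float:
    """Student-t CDF via numerical integration of the density."""
    c = gamma_fn((df + 1) / 2.0) / (np.sqrt(df * np.pi) * gamma_fn(df / 2.0))

    def pdf(x):
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    if t <= 0:
        val, _ = quad(pdf, -np.inf, t, epsabs=1e-13, epsrel=1e-13)
        return val
    val, _ = quad(pdf, t, np.inf, epsabs=1e-13, epsrel=1e-13)
    return 1.0 - val
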