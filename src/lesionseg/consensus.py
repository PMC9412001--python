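"""Multi-rater fusion: STAPLE, the consensus protocol, unbiased ground truth.

Three pieces of machinery for working with several expert masks of the
same volume:

* :func:`staple_fuse` — binary STAPLE: an EM algorithm that alternates
  between estimating the latent true segmentation (E-step, per-voxel
  posterior) and each rater's sensitivity p_j and specificity q_j
  (M-step).
* :func:`build_consensus` — the two-step reading protocol: candidate
  lesions found by at least ``majority_threshold`` raters are accepted
  automatically; the rest are *disputed* and need an accept/reject
  decision (from a senior-expert decision table, or derived from an
  existing consensus mask). Accepted lesions are delineated by STAPLE
  over the raters who found them, run on a dilated bounding box around
  the lesion.
* :func:`unbiased_ground_truth` — a leave-one-expert-out reference u_i:
  with the excluded rater's mask never read, lesions found by ≥ 2
  remaining raters are kept, single-finder lesions are kept only when the
  original consensus contains them (the constant-decisions assumption),
  and kept lesions are delineated by voxel-wise majority vote over the
  remaining raters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .triplanar import _structure
from .volume_io import BinaryMask3D, GeometryError

__all__ = ["ExpertMaskSet", "RaterPerformance", "ConsensusResult",
           "ProtocolError", "staple_fuse", "partition_lesions",
           "build_consensus", "unbiased_ground_truth", "majority_vote"]


class ProtocolError(RuntimeError):
    pass


@dataclasses.dataclass
class ExpertMaskSet:
    masks: list[BinaryMask3D]
    rater_ids: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rater_ids:
            self.rater_ids = [m.id or f"rater{i}"
                              for i, m in enumerate(self.masks)]
        shapes = {tuple(m.shape) for m in self.masks}
        if len(shapes) > 1:
            raise GeometryError(f"expert masks differ in shape: {shapes}")

    def __len__(self) -> int:
        return len(self.masks)

    def stack(self) -> np.ndarray:
        return np.stack([m.data.astype(bool) for m in self.masks])


@dataclasses.dataclass
class RaterPerformance:
    sensitivity: np.ndarray  # p_j per rater
    specificity: np.ndarray  # q_j per rater
    converged: bool = True
    n_iter: int = 0


@dataclasses.dataclass
class ConsensusResult:
    mask: BinaryMask3D
    provenance: list[dict]  # lesion id, finders, status


def staple_fuse(masks: ExpertMaskSet,
                region: np.ndarray | None = None,
                init: float = 0.9999,
                tol: float = 1e-6,
                max_iter: int = 100
                ) -> tuple[np.ndarray, RaterPerformance]:
    """Binary STAPLE restricted to ``region`` (default: whole volume).

    Returns the posterior probability map of the latent true segmentation
    (zero outside the region) and the final rater performances. The prior
    foreground probability is initialized to the empirical mean of the
    rater masks over the region and re-estimated in every M-step (full
    EM); with a fixed inflated prior, sparse false positives can otherwise
    be absorbed into the latent truth. Thresholding the posterior at 0.5
    gives the fused mask.
    """
    if len(masks) < 1:
        raise ValueError("need at least one rater")
    d_full = masks.stack()
    region = np.ones(d_full.shape[1:], dtype=bool) if region is None else region
    if not region.any():
        raise ValueError("empty region")
    d = d_full[:, region].astype(np.float64)  # (R, V)
    r, v = d.shape
    prior = float(d.mean())
    post_map = np.zeros(d_full.shape[1:], dtype=np.float64)
    if prior == 0.0:  # all raters empty: nothing to estimate
        perf = RaterPerformance(sensitivity=np.full(r, init),
                                specificity=np.full(r, init),
                                converged=True, n_iter=0)
        return post_map, perf
    p = np.full(r, init)
    q = np.full(r, init)
    w = np.full(v, prior)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior that the latent truth is foreground
        log_a = (d * np.log(p)[:, None]
                 + (1 - d) * np.log1p(-p)[:, None]).sum(axis=0) \
            + np.log(prior)
        log_b = ((1 - d) * np.log(q)[:, None]
                 + d * np.log1p(-q)[:, None]).sum(axis=0) \
            + np.log1p(-prior)
        m = np.maximum(log_a, log_b)
        w_new = np.exp(log_a - m) / (np.exp(log_a - m) + np.exp(log_b - m))
        delta = float(np.abs(w_new - w).max())
        w = w_new
        # M-step: re-estimate performances, clamped to the open interval
        sw = w.sum()
        swc = (1 - w).sum()
        eps = 1e-7
        p = np.clip((d * w).sum(axis=1) / max(sw, eps), eps, 1 - eps)
        q = np.clip(((1 - d) * (1 - w)).sum(axis=1) / max(swc, eps),
                    eps, 1 - eps)
        prior = float(np.clip(w.mean(), eps, 1 - eps))
        if delta < tol:
            converged = True
            break
    post_map[region] = w
    perf = RaterPerformance(sensitivity=p, specificity=q,
                            converged=converged, n_iter=it)
    return post_map, perf


def _candidate_lesions(stack: np.ndarray, connectivity: int
                       ) -> tuple[np.ndarray, int, list[list[int]]]:
    """Components of the union of rater masks and who found each."""
    union = stack.any(axis=0)
    labels, n = ndimage.label(union, structure=_structure(connectivity))
    finders: list[list[int]] = []
    for lid in range(1, n + 1):
        sel = labels == lid
        finders.append([j for j in range(stack.shape[0])
                        if (stack[j] & sel).any()])
    return labels, n, finders


def partition_lesions(masks: ExpertMaskSet, majority_threshold: int = 3,
                      connectivity: int = 26
                      ) -> tuple[list[dict], list[dict]]:
    """Split candidate lesions into majority and disputed lists.

    A candidate lesion is a connected component of the union of all rater
    masks; its finder count is the number of raters overlapping it in at
    least one voxel.
    """
    stack = masks.stack()
    labels, n, finders = _candidate_lesions(stack, connectivity)
    majority, disputed = [], []
    for lid in range(1, n + 1):
        entry = {"id": lid,
                 "finders": [masks.rater_ids[j] for j in finders[lid - 1]],
                 "n_finders": len(finders[lid - 1])}
        (majority if entry["n_finders"] >= majority_threshold
         else disputed).append(entry)
    return majority, disputed


def _lesion_region(component: np.ndarray, margin: int = 3) -> np.ndarray:
    return ndimage.binary_dilation(component, iterations=margin)


def build_consensus(masks: ExpertMaskSet,
                    decisions: dict[int, str] | BinaryMask3D | None = None,
                    majority_threshold: int = 3,
                    connectivity: int = 26) -> ConsensusResult:
    """Two-step consensus: lesion triage, then per-lesion STAPLE fusion.

    ``decisions`` maps disputed candidate-lesion ids to "accept"/"reject";
    alternatively an existing consensus mask can stand in for the senior
    expert (a disputed lesion is accepted iff it overlaps that mask).
    Every accepted lesion is delineated by STAPLE over the raters who
    found it, restricted to a 3-voxel-dilated box around the candidate.
    """
    stack = masks.stack()
    labels, n, finders = _candidate_lesions(stack, connectivity)
    ref = masks.masks[0]
    out = np.zeros(ref.shape, dtype=bool)
    provenance = []
    for lid in range(1, n + 1):
        comp = labels == lid
        who = finders[lid - 1]
        if len(who) >= majority_threshold:
            status = "majority-auto"
            accept = True
        else:
            if decisions is None:
                raise ProtocolError(
                    f"disputed lesion {lid} has no senior decision")
            if isinstance(decisions, BinaryMask3D):
                accept = bool((comp & (decisions.data > 0)).any())
            elif lid in decisions:
                accept = decisions[lid] == "accept"
            else:
                raise ProtocolError(
                    f"disputed lesion {lid} has no senior decision")
            status = "disputed-accepted" if accept else "disputed-rejected"
        if accept:
            region = _lesion_region(comp)
            sub = ExpertMaskSet(
                masks=[masks.masks[j] for j in who],
                rater_ids=[masks.rater_ids[j] for j in who])
            post, _ = staple_fuse(sub, region=region)
            out |= post > 0.5
        provenance.append({"id": lid,
                           "finders": [masks.rater_ids[j] for j in who],
                           "status": status})
    mask = BinaryMask3D(out, ref.spacing, ref.affine.copy(), id="consensus")
    return ConsensusResult(mask=mask, provenance=provenance)


def majority_vote(stack: np.ndarray) -> np.ndarray:
    """Voxel-wise majority: foreground where more than half the raters
    agree; exact ties (even rater counts) go to background."""
    return stack.sum(axis=0) > stack.shape[0] / 2.0


def unbiased_ground_truth(masks: ExpertMaskSet, consensus: BinaryMask3D,
                          excluded_rater: str,
                          connectivity: int = 26) -> BinaryMask3D:
    """Leave-one-expert-out reference mask u_i.

    The excluded rater's mask is never read. Candidate lesions come from
    the union of the remaining masks; a lesion found by ≥ 2 remaining
    raters is accepted automatically, a single-finder lesion is accepted
    iff it overlaps the original consensus (the senior expert's decision,
    assumed constant across readings). Accepted lesions are delineated by
    voxel-wise majority over the remaining raters; where that majority is
    empty (single-finder lesions), the finder's own delineation is used.
    """
    if excluded_rater not in masks.rater_ids:
        raise ValueError(f"unknown rater {excluded_rater!r}")
    keep = [i for i, rid in enumerate(masks.rater_ids)
            if rid != excluded_rater]
    if len(keep) < 3:
        raise ProtocolError("need at least 3 remaining raters for a "
                            "majority vote")
    remaining = ExpertMaskSet(
        masks=[masks.masks[i] for i in keep],
        rater_ids=[masks.rater_ids[i] for i in keep])
    if tuple(consensus.shape) != tuple(remaining.masks[0].shape):
        raise GeometryError("consensus mask not on the experts' grid")
    stack = remaining.stack()
    labels, n, finders = _candidate_lesions(stack, connectivity)
    maj = majority_vote(stack)
    out = np.zeros(consensus.shape, dtype=bool)
    for lid in range(1, n + 1):
        comp = labels == lid
        who = finders[lid - 1]
        if len(who) >= 2:
            accept = True
        else:
            accept = bool((comp & (consensus.data > 0)).any())
        if not accept:
            continue
        delineation = comp & maj
        if not delineation.any():
            delineation = comp & stack[who[0]]
        out |= delineation
    ref = remaining.masks[0]
    return BinaryMask3D(out, ref.spacing, ref.affine.copy(),
                        id=f"unbiased-minus-{excluded_rater}")
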