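"""Majority-vote consensus contour (ConSeg) over individual segmentations."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask, ImageVolume, check_congruent
from .segment import (
    APParams,
    MASACParams,
    STParams,
    SegmentationResult,
    _largest_cc,
    run_all,
)

__all__ = ["ConsensusSpec", "majority_vote", "conseg"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusSpec:
    """Voting rule: a voxel is kept when at least vote_threshold masks contain it."""

    n_voters: int
    vote_threshold: int

    def __post_init__(self) -> None:
        if not (1 <= self.vote_threshold <= self.n_voters):
            raise ValueError("need 1 <= vote_threshold <= n_voters")

    @classmethod
    def strict_majority(cls, n_voters: int) -> "ConsensusSpec":
        return cls(n_voters, n_voters // 2 + 1)


def majority_vote(
    masks: list[BinaryMask] | tuple[BinaryMask, ...],
    spec: ConsensusSpec | None = None,
) -> BinaryMask:
    """Voxel-wise vote over congruent masks.

    Defaults to the strict majority floor(n/2) + 1 (3 of 4).  The output lies
    between the intersection and the union of the inputs.
    """
    if len(masks) < 2:
        raise ValueError("majority vote needs at least 2 masks")
    check_congruent(*masks)
    spec = spec or ConsensusSpec.strict_majority(len(masks))
    if spec.n_voters != len(masks):
        raise ValueError(f"spec expects {spec.n_voters} voters, got {len(masks)}")
    votes = np.zeros(masks[0].shape, dtype=np.int16)
    for m in masks:
        votes += m.data
    return BinaryMask(votes >= spec.vote_threshold, masks[0].spacing)


def conseg(
    image: ImageVolume,
    init: BinaryMask,
    *,
    vote_threshold: int | None = None,
    fraction: float = 0.41,
    st_params: STParams | None = None,
    ap_params: APParams | None = None,
    masac_params: MASACParams | None = None,
    seed: int | None = 0,
    mask_style: str | None = None,
    individual: dict[str, SegmentationResult] | None = None,
) -> SegmentationResult:
    """Run the four methods (or reuse ``individual``) and fuse by majority vote.

    An empty consensus lowers the threshold one vote at a time (flagged) until
    the fused mask is nonempty.
    """
    if individual is None:
        individual = run_all(
            image,
            init,
            fraction=fraction,
            st_params=st_params,
            ap_params=ap_params,
            masac_params=masac_params,
            seed=seed,
            mask_style=mask_style,
        )
    masks = [r.mask for r in individual.values()]
    n = len(masks)
    thr = vote_threshold if vote_threshold is not None else n // 2 + 1
    fused = majority_vote(masks, ConsensusSpec(n, thr))
    relaxed = False
    while fused.is_empty() and thr > 1:
        thr -= 1
        relaxed = True
        logger.warning("empty consensus; lowering vote threshold to %d", thr)
        fused = majority_vote(masks, ConsensusSpec(n, thr))
    out = _largest_cc(fused.data)
    return SegmentationResult(
        method="ConSeg",
        mask=BinaryMask(out, init.spacing),
        params_used={
            "n_voters": n,
            "vote_threshold": thr,
            "relaxed": relaxed,
            "voters": sorted(individual),
        },
        mask_style=mask_style,
    )
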