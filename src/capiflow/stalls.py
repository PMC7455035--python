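"""Capillary stall scoring: motion statistic, crowd votes, triage, density.

A stalled capillary contains blood cells whose dark shadows stay fixed
across the frames in which the segment is visible, while a flowing
capillary shows a different shadow pattern in each frame.  The motion
statistic quantifies this as one minus the mean frame-to-frame correlation
of the lumen intensity sampled along the segment centerline.

Classification follows the crowd-sourced protocol: many annotators of
known calibration sensitivity vote flowing/stalled per segment, the votes
are pooled into a sensitivity-weighted crowd confidence in [0, 1], and
only segments with confidence >= 0.5 are passed (in descending confidence
order) to an expert validation oracle; everything below the threshold is
auto-labeled flowing.  Stall density is reported as stalls per mm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import AngiogramStack, GroundTruth

__all__ = [
    "Annotator",
    "StallRecord",
    "motion_statistic",
    "simulate_votes",
    "crowd_confidence",
    "confidences_from_table",
    "triage_and_validate",
    "stall_density",
    "estimate_annotator_performance",
]

FLOWING = "flowing"
STALLED = "stalled"


@dataclass(frozen=True)
class Annotator:
    """A (simulated) volunteer with calibration performance rates.

    sensitivity: probability of voting "stalled" on a truly stalled segment;
    specificity: probability of voting "flowing" on a truly flowing one.
    Both estimated on calibration segments of known state.
    """

    annotator_id: int
    sensitivity: float
    specificity: float
    n_calibration: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")


@dataclass
class StallRecord:
    """Per-segment stall-scoring state."""

    segment_id: int
    motion_stat: float = np.nan
    scorable: bool = True
    votes: list = field(default_factory=list)  # (annotator_id, vote)
    crowd_confidence: float = np.nan
    final_label: str | None = None
    validated: bool = False


# --------------------------------------------------------------------------
# motion statistic
# --------------------------------------------------------------------------

def motion_statistic(stack: AngiogramStack, segment, min_common: int = 5) -> float:
    """1 - mean frame-to-frame correlation of lumen intensity along a segment.

    The segment (any object with ``centerline_um`` (z, y, x) μm and
    ``diameter_um``) is visible in frame z wherever its tube intersects
    that plane; consecutive visible frames are compared over the in-plane
    centerline positions they share.  Near 0 for stalled segments
    (identical shadows), larger for flowing ones.  Returns NaN when the
    segment is visible in fewer than two comparable frames (unscorable).
    """
    vs = np.asarray(stack.voxel_size, float)
    pts = np.asarray(segment.centerline_um, float)
    # sample strictly inside the lumen: shrinking the visibility radius by
    # half a voxel (plus the in-plane rounding already below one voxel)
    # keeps boundary/background voxels (static structure) out of the
    # correlation
    radius = max(0.6 * vs[0], segment.diameter_um / 2.0 - 0.5 * vs[0])
    yx = np.round(pts[:, 1:] / vs[1:]).astype(int)
    # deduplicate in-plane positions, keeping the first occurrence's z
    _, keep = np.unique(yx, axis=0, return_index=True)
    keep = np.sort(keep)
    yx = yx[keep]
    z_um = pts[keep, 0]
    ny, nx = stack.data.shape[1:]
    inb = (yx[:, 0] >= 0) & (yx[:, 0] < ny) & (yx[:, 1] >= 0) & (yx[:, 1] < nx)
    yx, z_um = yx[inb], z_um[inb]
    if len(yx) == 0:
        return np.nan

    vz = vs[0]
    z_lo = max(0, int(np.floor((z_um.min() - radius) / vz)))
    z_hi = min(stack.n_frames - 1, int(np.ceil((z_um.max() + radius) / vz)))
    visible = {
        z: np.abs(z_um - z * vz) <= radius for z in range(z_lo, z_hi + 1)
    }
    corrs = []
    for z in range(z_lo, z_hi):
        common = visible[z] & visible[z + 1]
        if common.sum() < min_common:
            continue
        y, x = yx[common, 0], yx[common, 1]
        a = stack.data[z, y, x].astype(float)
        b = stack.data[z + 1, y, x].astype(float)
        scale = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
        # changes far smaller than a cell shadow (which darkens the lumen by
        # tens of percent) are sampling artifacts, not motion
        tol = 0.02 * scale
        if np.ptp(a) < tol and np.ptp(b) < tol:
            continue  # featureless bright lumen: no cells in view, no evidence
        if np.max(np.abs(a - b)) < tol:
            corrs.append(1.0)  # pattern unchanged, even if featureless
        elif a.std() < 1e-12 * scale or b.std() < 1e-12 * scale:
            corrs.append(0.0)  # a shadow appeared or vanished: motion
        else:
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
    if not corrs:
        return np.nan
    return float(1.0 - np.mean(corrs))


# --------------------------------------------------------------------------
# crowd votes
# --------------------------------------------------------------------------

def simulate_votes(truth: GroundTruth, annotators: list[Annotator],
                   votes_per_segment: int = 20, seed: int = 0) -> pd.DataFrame:
    """Simulate annotator votes on every ground-truth segment.

    Each vote is a Bernoulli draw: a stalled segment is voted "stalled"
    with the annotator's sensitivity; a flowing one is voted "flowing"
    with the annotator's specificity.  Annotators are drawn uniformly with
    replacement for each of the ``votes_per_segment`` votes.
    """
    if votes_per_segment < 1:
        raise ValueError("votes_per_segment must be >= 1")
    if not annotators:
        raise ValueError("need at least one annotator")
    rng = np.random.default_rng(seed)
    rows = []
    for seg in truth.segments:
        idx = rng.integers(0, len(annotators), size=votes_per_segment)
        u = rng.random(votes_per_segment)
        for k, i in enumerate(idx):
            ann = annotators[i]
            if seg.state == STALLED:
                vote = STALLED if u[k] < ann.sensitivity else FLOWING
            else:
                vote = FLOWING if u[k] < ann.specificity else STALLED
            rows.append((seg.segment_id, ann.annotator_id, vote))
    return pd.DataFrame(rows, columns=["segment_id", "annotator_id", "vote"])


def crowd_confidence(votes, annotators: list[Annotator]) -> float:
    """Sensitivity-weighted fraction of "stalled" votes, in [0, 1].

    votes: iterable of ``(annotator_id, vote)``.  Weight w_i is annotator
    i's calibration sensitivity; the score is
    sum(w_i * [vote_i == stalled]) / sum(w_i).
    """
    weights = {a.annotator_id: a.sensitivity for a in annotators}
    votes = list(votes)
    if not votes:
        raise ValueError("at least one vote is required")
    w_total = 0.0
    w_stalled = 0.0
    for annotator_id, vote in votes:
        try:
            w = weights[annotator_id]
        except KeyError:
            raise KeyError(f"vote from unknown annotator {annotator_id}") from None
        w_total += w
        if vote == STALLED:
            w_stalled += w
    if w_total <= 0.0:
        raise ValueError("uninformative crowd: all annotator weights are zero")
    return w_stalled / w_total


def confidences_from_table(vote_table: pd.DataFrame,
                           annotators: list[Annotator]) -> pd.Series:
    """Crowd confidence per segment from a tidy vote table."""
    return vote_table.groupby("segment_id").apply(
        lambda g: crowd_confidence(zip(g["annotator_id"], g["vote"]), annotators),
        include_groups=False,
    )


def estimate_annotator_performance(vote_table: pd.DataFrame,
                                   truth: GroundTruth) -> list[Annotator]:
    """Estimate sensitivity/specificity from votes on known-state segments."""
    state = {s.segment_id: s.state for s in truth.segments}
    out = []
    for aid, g in vote_table.groupby("annotator_id"):
        truths = g["segment_id"].map(state)
        stalled = truths == STALLED
        n_st, n_fl = int(stalled.sum()), int((~stalled).sum())
        sens = float((g.loc[stalled, "vote"] == STALLED).mean()) if n_st else 0.5
        spec = float((g.loc[~stalled, "vote"] == FLOWING).mean()) if n_fl else 0.5
        out.append(Annotator(int(aid), sens, spec, n_calibration=n_st + n_fl))
    return out


# --------------------------------------------------------------------------
# triage and density
# --------------------------------------------------------------------------

def triage_and_validate(records: list[StallRecord], oracle,
                        threshold: float = 0.5) -> tuple[list[StallRecord], int]:
    """Expert triage: validate high-confidence records, auto-label the rest.

    Records with crowd confidence >= ``threshold`` (inclusive) are passed
    to ``oracle(segment_id) -> "flowing" | "stalled"`` in strictly
    descending confidence order; records below the threshold are
    auto-labeled flowing without validation.  Returns the labeled records
    and the validation workload (number of oracle calls).
    """
    order = sorted(
        (r for r in records if r.scorable and r.crowd_confidence >= threshold),
        key=lambda r: -r.crowd_confidence,
    )
    workload = 0
    for rec in order:
        rec.final_label = oracle(rec.segment_id)
        rec.validated = True
        workload += 1
    for rec in records:
        if rec.scorable and not rec.validated:
            rec.final_label = FLOWING
    return records, workload


def stall_density(records: list[StallRecord], analyzed_volume_mm3: float) -> float:
    """Stalled-capillary count per mm³; unscorable segments are excluded."""
    if analyzed_volume_mm3 <= 0:
        raise ValueError("analyzed volume must be positive")
    n_stalled = sum(
        1 for r in records if r.scorable and r.final_label == STALLED
    )
    return n_stalled / analyzed_volume_mm3
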