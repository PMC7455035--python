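"""Shared independent oracles and matching utilities for the test suite."""

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


def streak_centroid_speed(st) -> float:
    """Independent velocimetry oracle: darkness centroids of one isolated
    streak regressed along its long axis.

    Shallow streaks (slow flow) are regressed as position-per-line; steep
    streaks (fast flow, which hop many pixels between lines) as
    time-per-position.  Works on noise-free images with separable streaks;
    completely independent of the Radon projection path.
    """
    dark = 1.0 - st.data
    # dilate before labeling so a steep streak (disconnected between lines)
    # forms one component; centroids still use the raw darkness
    blob = ndimage.binary_dilation(dark > 0.4, iterations=6)
    lbl, n = ndimage.label(blob)
    if n == 0:
        return 0.0
    sizes = ndimage.sum_labels(dark > 0.4, lbl, index=np.arange(1, n + 1))
    for idx in np.argsort(sizes)[::-1]:
        speed = _component_streak_speed(st, dark, lbl == (idx + 1))
        if speed is not None:
            return speed
    return 0.0


def _component_streak_speed(st, dark, comp):
    """Fit one labeled component as a single streak; None if it is not one."""
    comp = comp & (dark > 0.4)
    rows = np.unique(np.nonzero(comp)[0])
    cols = np.unique(np.nonzero(comp)[1])
    if len(rows) < 3:
        return None
    if len(rows) >= len(cols):  # shallow: x centroid per line
        ts, xs = [], []
        for t in rows:
            w = dark[t] * comp[t]
            if w.sum() <= 0:
                continue
            xs.append((w * np.arange(st.data.shape[1])).sum() / w.sum())
            ts.append(t)
        slope, intercept = np.polyfit(ts, xs, 1)
        resid = np.asarray(xs) - (slope * np.asarray(ts) + intercept)
    else:  # steep: time centroid per column, then invert
        ts, xs = [], []
        for x in cols:
            w = dark[:, x] * comp[:, x]
            if w.sum() <= 0:
                continue
            ts.append((w * np.arange(st.data.shape[0])).sum() / w.sum())
            xs.append(x)
        inv, intercept = np.polyfit(xs, ts, 1)
        if abs(inv) < 1e-12:
            return None
        resid = np.asarray(ts) - (inv * np.asarray(xs) + intercept)
        slope = 1.0 / inv
    if np.sqrt((resid ** 2).mean()) > 1.0:
        return None  # overlapping or clipped streaks, not a single one
    return abs(slope) * st.pixel_size * st.line_rate / 1000.0  # mm/s


def interior_centerline(truth_segment, end_trim_um: float = 5.0) -> np.ndarray:
    """Interior of a ground-truth centerline, dropping the end caps.

    Skeletons retract by about one tube radius at open ends, and a cell
    shadow sitting at a vessel end occludes it entirely in the rendered
    stack, so matching is assessed on the interior: both ends trimmed by
    the tube radius plus one shadow length.
    """
    pts = truth_segment.centerline_um
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    trim = truth_segment.diameter_um / 2.0 + end_trim_um
    keep = (arc > trim) & (arc < arc[-1] - trim)
    return pts[keep] if keep.any() else pts[len(pts) // 2: len(pts) // 2 + 1]


def matched_fraction(truth, segments, tol_voxels: float = 2.0) -> float:
    """Fraction of ground-truth segments whose interior centerline lies
    within ``tol_voxels`` (one-sided Hausdorff) of an emitted segment."""
    if not segments:
        return 0.0
    trees = [cKDTree(s.centerline_um) for s in segments]
    hits = 0
    for t in truth.segments:
        pts = interior_centerline(t)
        if min(tree.query(pts)[0].max() for tree in trees) < tol_voxels:
            hits += 1
    return hits / len(truth.segments)


def auc(labels, scores) -> float:
    """Rank AUC (probability a positive outscores a negative)."""
    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    pos, neg = scores[labels], scores[~labels]
    gt = (pos[:, None] > neg[None, :]).mean()
    eq = (pos[:, None] == neg[None, :]).mean()
    return float(gt + 0.5 * eq)
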