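"""Tracking metrics: bounding-box overlap, ROP, deviations, ICC, group tables.

The hyoid body is approximated per frame by an axis-aligned square of side
D = 35 px (diagonal 49 px).  With equal-sized boxes the Dice overlap of the
true and predicted boxes reduces to intersection / D^2, which for squares
separates per axis:

    eta(t) = max(0, D - |dx|) * max(0, D - |dy|) / D^2 * 100%.

eta_M-H compares the machine with one human rater.  eta_H-H is the same
quantity pooled over all unordered pairs of human raters and all frames — the
agreement ceiling imposed by labelling variability.  The relative overlapped
percentage ROP(t) = eta_M-H(t) / eta_H-H * 100% expresses machine accuracy on
that human scale: 100% means the machine matches a rater as well as raters
match each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .targets import DEFAULT_BOX_SIDE

__all__ = [
    "overlap_pct",
    "human_agreement",
    "rop",
    "deviation_stats",
    "DeviationStats",
    "icc_absolute_agreement",
    "group_summary",
    "GroupSummary",
]


def overlap_pct(true_center: np.ndarray, pred_center: np.ndarray,
                side: float = DEFAULT_BOX_SIDE) -> np.ndarray | float:
    """Percent overlap of two equal square boxes from their center offset.

    Accepts single points (shape (2,)) or per-frame arrays (shape (T, 2));
    disjoint boxes (|delta| >= side on either axis) score 0, coincident
    centers score 100.  Symmetric in its two arguments.
    """
    if side <= 0:
        raise ValueError("box side must be positive")
    a = np.asarray(true_center, dtype=float)
    b = np.asarray(pred_center, dtype=float)
    delta = np.abs(a - b)
    ov = np.maximum(side - delta, 0.0)
    pct = ov[..., 0] * ov[..., 1] / side ** 2 * 100.0
    return float(pct) if pct.ndim == 0 else pct


def human_agreement(rater_sets: list[list[np.ndarray]],
                    side: float = DEFAULT_BOX_SIDE) -> float:
    """Pooled eta_H-H over swallows: pairwise rater overlap, frame-weighted.

    ``rater_sets`` holds, per swallow, the (T, 2) pixel trajectories of at
    least two raters (equal T within a swallow).  Per frame the overlap is
    averaged over all unordered rater pairs, then pooled over all frames of
    all swallows weighted by frame count.
    """
    total, n_frames = 0.0, 0
    for raters in rater_sets:
        if len(raters) < 2:
            raise ValueError("need at least two raters per swallow")
        arrs = [np.asarray(r, dtype=float) for r in raters]
        T = arrs[0].shape[0]
        if any(a.shape[0] != T for a in arrs):
            raise ValueError("rater trajectories differ in length")
        per_frame = np.mean(
            [overlap_pct(a, b, side) for a, b in combinations(arrs, 2)],
            axis=0)
        total += float(np.sum(per_frame))
        n_frames += T
    return total / n_frames


def rop(eta_mh: np.ndarray | float, eta_hh: float
        ) -> tuple[np.ndarray | float, float]:
    """Relative overlapped percentage and its mean over frames."""
    if eta_hh <= 0:
        raise ValueError("eta_H-H must be positive")
    series = np.asarray(eta_mh, dtype=float) / eta_hh * 100.0
    mean = float(np.mean(series))
    if series.ndim == 0:
        return float(series), mean
    return series, mean


@dataclass
class DeviationStats:
    """Per-frame pixel deviations of predictions from one rater's labels."""

    deltas: np.ndarray               # (T, 2) pred - true, pixels
    within_share: float              # % of frames within the half-box bound
    half_box: float
    theta: np.ndarray                # radians, atan2(dy, dx), image coords
    theta_hist: np.ndarray
    theta_edges: np.ndarray

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.deltas, axis=1)


def deviation_stats(pred: np.ndarray, true: np.ndarray,
                    half_box: float = 17.0, mode: str = "box",
                    n_bins: int = 16) -> DeviationStats:
    """Deviation distribution summary (the +-17 px containment analysis).

    ``mode='box'`` counts a frame as inside when |dx| <= half_box AND
    |dy| <= half_box (box containment); ``mode='radius'`` uses the Euclidean
    distance instead.  The angular deviation theta = atan2(dy, dx) is binned
    uniformly over (-pi, pi] in image coordinates (y down).
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal shapes")
    deltas = p - t
    if mode == "box":
        inside = np.all(np.abs(deltas) <= half_box, axis=1)
    elif mode == "radius":
        inside = np.linalg.norm(deltas, axis=1) <= half_box
    else:
        raise ValueError(f"unknown mode {mode!r}")
    theta = np.arctan2(deltas[:, 1], deltas[:, 0])
    hist, edges = np.histogram(theta, bins=n_bins, range=(-np.pi, np.pi))
    return DeviationStats(deltas, float(inside.mean() * 100.0), half_box,
                          theta, hist, edges)


def icc_absolute_agreement(table: np.ndarray) -> float:
    """Two-way mixed-effects, absolute-agreement, average-measures ICC.

    ``table`` is (n_subjects, n_raters) with no missing cells.  From the
    two-way ANOVA mean squares (rows = subjects, columns = raters):

        ICC = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    which is the average-measures absolute-agreement form (ICC(A,k); what
    SPSS reports for a two-way mixed model with absolute agreement).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("table contains missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (msc - mse) / n))


_GENDERS = ("male", "female")


@dataclass
class GroupSummary:
    """Mean ROP by stroke history x gender, with sample counts.

    Rows: overall, male, female; columns: no_stroke, stroke, overall —
    mirroring the standard cohort summary layout.
    """

    means: pd.DataFrame
    counts: pd.DataFrame


def group_summary(rop_per_swallow: np.ndarray,
                  metadata: pd.DataFrame) -> GroupSummary:
    """Cell/marginal mean ROP keyed by stroke history and gender.

    ``metadata`` needs one row per swallow with ``gender`` in
    {male, female} and boolean ``stroke_history``, aligned with
    ``rop_per_swallow``.
    """
    vals = np.asarray(rop_per_swallow, dtype=float)
    if len(vals) != len(metadata):
        raise ValueError("metadata must cover all swallows")
    bad = set(metadata["gender"]) - set(_GENDERS)
    if bad:
        raise ValueError(f"unknown gender label(s): {sorted(bad)}")
    df = metadata.copy()
    df["rop"] = vals
    df["stroke"] = df["stroke_history"].map(
        {True: "stroke", False: "no_stroke"})
    if df["stroke"].isna().any():
        raise ValueError("stroke_history must be boolean")
    rows = ["overall", *_GENDERS]
    cols = ["no_stroke", "stroke", "overall"]
    means = pd.DataFrame(index=rows, columns=cols, dtype=float)
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for r in rows:
        sub = df if r == "overall" else df[df["gender"] == r]
        for c in cols:
            cell = sub if c == "overall" else sub[sub["stroke"] == c]
            counts.loc[r, c] = len(cell)
            means.loc[r, c] = cell["rop"].mean() if len(cell) else np.nan
    return GroupSummary(means, counts)
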