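"""Participant-grouped k-fold cross-validation over a swallow cohort.

The experimental protocol: swallows are partitioned into k non-overlapping
groups with all of a participant's swallows in one group (no identity leaks
across roles), and for each fold one group is tested, two are validation and
the remaining k-3 train — the 70/20/10 split at k = 10.  Feature
normalisation and target scaling statistics are fitted on each fold's
training swallows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import srnn
from .preprocess import FeatureNormalizer, FrameFeatureSequence, build_features
from .simulate import Cohort
from .targets import DEFAULT_BOX_SIDE, TargetScaler, build_target

__all__ = ["FoldPlan", "make_folds", "CrossvalReport", "run_crossval"]


@dataclass
class FoldPlan:
    """Group memberships and per-fold role assignment."""

    k: int
    seed: int
    groups: list[list[str]]                 # participant ids per group
    folds: list[dict]                       # test/val/train group indices
    participant_of: dict[str, str]          # swallow id -> participant id

    def role_participants(self, fold: int, role: str) -> set[str]:
        return {pid for g in self.folds[fold][role] for pid in self.groups[g]}


def make_folds(metadata: pd.DataFrame, k: int = 10, seed: int = 0,
               n_val_groups: int = 2) -> FoldPlan:
    """Partition participants into k swallow-count-balanced groups.

    Greedy balancing: participants are visited in seeded random order, from
    most to fewest swallows, each joining the currently lightest group.  For
    fold i, group i is the test set and the next ``n_val_groups`` groups
    (cyclically) are validation; the rest train.
    """
    counts = metadata.groupby("participant_id").size()
    if len(counts) < k:
        raise ValueError(
            f"need at least k={k} participants, got {len(counts)}")
    if k < n_val_groups + 2:
        raise ValueError("k too small for test/val/train roles")
    rng = np.random.default_rng(seed)
    pids = list(counts.index)
    rng.shuffle(pids)
    pids.sort(key=lambda p: -counts[p])     # stable: ties keep shuffled order
    groups: list[list[str]] = [[] for _ in range(k)]
    load = np.zeros(k, dtype=int)
    for pid in pids:
        g = int(np.argmin(load))
        groups[g].append(pid)
        load[g] += counts[pid]
    folds = []
    for i in range(k):
        val = [(i + 1 + j) % k for j in range(n_val_groups)]
        train = [g for g in range(k) if g != i and g not in val]
        folds.append({"test": [i], "val": val, "train": train})
    participant_of = dict(zip(metadata["swallow_id"],
                              metadata["participant_id"]))
    return FoldPlan(k, seed, groups, folds, participant_of)


@dataclass
class CrossvalReport:
    """Cohort-level tracking results across all folds."""

    eta_hh: float
    per_swallow: pd.DataFrame               # one row per tested swallow
    fold_mean_eta_mh: list[float]
    fold_mean_rop: list[float]
    overall_mean_eta_mh: float              # mean of fold means
    overall_mean_rop: float
    pooled_eta_mh: float                    # frame-pooled alternative
    pooled_rop: float
    deviation: ev.DeviationStats
    groups: ev.GroupSummary
    fold_plan: FoldPlan
    fold_normalizer_minima: list[np.ndarray] = field(default_factory=list)
    histories: list[srnn.TrainingHistory] = field(default_factory=list)


def _seq(p) -> FrameFeatureSequence:
    return FrameFeatureSequence(p["features"])


def _prepare(cohort: Cohort, reference_rater: int):
    """Per-swallow features, targets and truth, truncated to common length."""
    prepared = []
    for sw in cohort.swallows:
        feats = build_features(sw.signal, frame_rate=cohort.config.frame_rate)
        ref = sw.annotations[reference_rater]
        y_traj = build_target(ref)
        T = min(feats.n_frames, ref.n_frames)
        prepared.append({
            "swallow": sw,
            "features": feats.values[:T],
            "y_traj": y_traj[:T],
            "reference": ref,
            "truth_px": ref.anterior[:T],
            "T": T,
        })
    return prepared


def run_crossval(cohort: Cohort, config: srnn.SRNNConfig | None = None,
                 k: int = 10, seed: int = 0, reference_rater: int = 0,
                 box_side: float = DEFAULT_BOX_SIDE, half_box: float = 17.0,
                 ) -> CrossvalReport:
    """Run the full protocol on a cohort and aggregate tracking metrics.

    Per fold: fit the feature normalizer and target scaler on the training
    swallows, train an SRNN with early stopping on the validation group,
    predict the held-out test swallows, map predictions back to pixels and
    score them against the reference rater.  eta_H-H is computed once from
    all raters over the whole cohort and fixes the ROP denominator.
    """
    if config is None:
        config = srnn.SRNNConfig()
    meta = cohort.metadata
    plan = make_folds(meta, k=k, seed=seed)
    prepared = _prepare(cohort, reference_rater)
    by_pid: dict[str, list[int]] = {}
    for idx, p in enumerate(prepared):
        by_pid.setdefault(p["swallow"].participant_id, []).append(idx)

    eta_hh = ev.human_agreement(
        [[ann.anterior for ann in sw.annotations] for sw in cohort.swallows],
        side=box_side)

    rows = []
    fold_mean_eta, fold_mean_rop = [], []
    all_pred, all_truth = [], []
    norm_minima, histories = [], []
    frame_eta_sum, frame_count = 0.0, 0
    for i in range(plan.k):
        idx_of = {role: sorted(
            j for pid in plan.role_participants(i, role) for j in by_pid[pid])
            for role in ("train", "val", "test")}
        train_items = [prepared[j] for j in idx_of["train"]]
        normalizer = FeatureNormalizer().fit(
            [_seq(p) for p in train_items])
        scaler = TargetScaler().fit([p["y_traj"] for p in train_items])
        norm_minima.append(normalizer.minimum.copy())

        def xy(p):
            return (normalizer.transform(_seq(p)).values,
                    scaler.scale(p["y_traj"]))

        fold_cfg = srnn.SRNNConfig(**{**config.__dict__,
                                      "seed": config.seed + 1000 * i})
        params = srnn.init_params(fold_cfg)
        params, hist = srnn.train(params,
                                  [xy(p) for p in train_items],
                                  [xy(prepared[j]) for j in idx_of["val"]],
                                  fold_cfg)
        histories.append(hist)

        etas, rops = [], []
        for j in idx_of["test"]:
            p = prepared[j]
            feats = normalizer.transform(_seq(p))
            px, _ = srnn.predict_pixels(params, feats, scaler,
                                        p["reference"], box_side)
            eta_series = ev.overlap_pct(p["truth_px"], px, side=box_side)
            _, rop_mean = ev.rop(eta_series, eta_hh)
            sw = p["swallow"]
            rows.append({"swallow_id": sw.swallow_id,
                         "participant_id": sw.participant_id,
                         "gender": sw.gender,
                         "stroke_history": sw.stroke_history,
                         "fold": i,
                         "mean_eta_mh": float(np.mean(eta_series)),
                         "mean_rop": rop_mean})
            etas.append(float(np.mean(eta_series)))
            rops.append(rop_mean)
            frame_eta_sum += float(np.sum(eta_series))
            frame_count += len(eta_series)
            all_pred.append(px)
            all_truth.append(p["truth_px"])
        fold_mean_eta.append(float(np.mean(etas)))
        fold_mean_rop.append(float(np.mean(rops)))

    per_swallow = pd.DataFrame(rows)
    pooled_eta = frame_eta_sum / frame_count
    deviation = ev.deviation_stats(np.vstack(all_pred), np.vstack(all_truth),
                                   half_box=half_box)
    groups = ev.group_summary(per_swallow["mean_rop"].to_numpy(),
                              per_swallow)
    report = CrossvalReport(
        eta_hh=eta_hh,
        per_swallow=per_swallow,
        fold_mean_eta_mh=fold_mean_eta,
        fold_mean_rop=fold_mean_rop,
        overall_mean_eta_mh=float(np.mean(fold_mean_eta)),
        overall_mean_rop=float(np.mean(fold_mean_rop)),
        pooled_eta_mh=pooled_eta,
        pooled_rop=pooled_eta / eta_hh * 100.0,
        deviation=deviation,
        groups=groups,
        fold_plan=plan,
        fold_normalizer_minima=norm_minima,
        histories=histories,
    )
    return report
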