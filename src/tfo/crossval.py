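"""Staggered round-based five-fold cross-validation and the metric suite.

Each round (one continuous hypoxia episode) is split into five
time-contiguous folds.  The validation fold is *staggered*: in iteration
``j``, round ``r`` (in round order) validates on the fold starting at
fraction ``(0.2*r + 0.2*j) mod 1`` of the round, so every iteration sees
validation samples drawn from a different part of each round's saturation
trajectory, and across the five iterations every sample is validated
exactly once.  Because each 1 Hz feature row is an average over a 1.5-min
raw-data window, training rows whose window overlaps any validation row's
window are discarded to prevent leakage across the split.

Evaluation pools all rounds' validation samples per iteration, mirrors the
confusion-matrix metric suite (accuracy, sensitivity, specificity,
precision, F1), and adds ROC/AUC with a stratified-bootstrap confidence
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve, auc as _trapezoid_auc

from .fusion import (
    FusionMLP,
    NetworkSpec,
    Standardizer,
    TrainConfig,
    build_network,
    train,
    PULSATION_COLUMNS,
    MODULATION_COLUMNS,
)

__all__ = [
    "FoldAssignment",
    "MetricsReport",
    "assign_folds",
    "exclude_overlap",
    "evaluate",
    "run_cross_validation",
    "CrossValResult",
    "N_FOLDS",
]

N_FOLDS = 5


@dataclass
class FoldAssignment:
    """Training/validation split of one round for one CV iteration.

    Indices are 0-based positions within the round's (time-sorted, valid)
    samples.  ``start_fraction`` is the fold's starting fraction of the
    round; the validation fold covers 1-based indices
    ``floor(n*l) < i <= floor((n+0.2)*l)``.
    """

    round_id: object
    iteration: int
    start_fraction: float
    val_idx: np.ndarray
    train_idx: np.ndarray
    discarded_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def _fold_bounds(length: int, start_fraction: float) -> tuple[int, int]:
    lo = int(np.floor(start_fraction * length))
    hi = int(np.floor((start_fraction + 1.0 / N_FOLDS) * length))
    return lo, hi


def assign_folds(
    round_lengths: dict,
    iteration: int,
) -> list[FoldAssignment]:
    """Staggered fold assignment for one CV iteration.

    ``round_lengths`` maps round id -> number of (valid, time-sorted)
    samples, in round order.  Round ``r`` starts its validation fold at
    fraction ``p_r = 0.2 * (r mod 5)``, shifted by ``0.2 * iteration`` and
    wrapped mod 1.  Fold boundaries use floor at both ends, so any
    remainder samples (l not divisible by 5) fall in the cycle's last fold.
    """
    if not 0 <= iteration < N_FOLDS:
        raise ValueError(f"iteration must be in [0, {N_FOLDS}), got {iteration}")
    assignments = []
    for r, (round_id, length) in enumerate(round_lengths.items()):
        if length < N_FOLDS:
            raise ValueError(
                f"round {round_id} has only {length} samples; at least {N_FOLDS} required"
            )
        start = ((r + iteration) % N_FOLDS) / N_FOLDS
        lo, hi = _fold_bounds(length, start)
        val_idx = np.arange(lo, hi)
        train_idx = np.concatenate([np.arange(0, lo), np.arange(hi, length)])
        assignments.append(
            FoldAssignment(
                round_id=round_id,
                iteration=iteration,
                start_fraction=start,
                val_idx=val_idx,
                train_idx=train_idx,
            )
        )
    return assignments


def exclude_overlap(
    assignment: FoldAssignment,
    win_start: np.ndarray,
    win_end: np.ndarray,
) -> FoldAssignment:
    """Discard training samples whose smoothing window intersects validation.

    ``win_start``/``win_end`` give each sample's raw-data window, indexed
    like the round's samples.  A training sample is discarded iff its
    window has positive-measure overlap with any validation sample's
    window (touching endpoints, or zero-width windows, do not count).
    """
    win_start = np.asarray(win_start, float)
    win_end = np.asarray(win_end, float)
    vs = win_start[assignment.val_idx]
    ve = win_end[assignment.val_idx]
    if vs.size == 0:
        return assignment
    order = np.argsort(vs)
    vs, ve = vs[order], ve[order]
    prefix_max_end = np.maximum.accumulate(ve)

    ts = win_start[assignment.train_idx]
    te = win_end[assignment.train_idx]
    # overlap with some val window j: vs_j < te and ve_j > ts
    hi = np.searchsorted(vs, te, side="left")
    max_end = np.where(hi > 0, prefix_max_end[np.maximum(hi - 1, 0)], -np.inf)
    clash = (hi > 0) & (max_end > ts)

    return FoldAssignment(
        round_id=assignment.round_id,
        iteration=assignment.iteration,
        start_fraction=assignment.start_fraction,
        val_idx=assignment.val_idx,
        train_idx=assignment.train_idx[~clash],
        discarded_idx=assignment.train_idx[clash],
    )


@dataclass
class MetricsReport:
    """Confusion-matrix metric suite at a fixed threshold, plus ROC/AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float
    auc_ci: tuple[float, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
        }


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (empty denominator); reporting NaN")
        return float("nan")
    return num / den


def evaluate(
    probabilities: np.ndarray,
    labels: np.ndarray,
    *,
    threshold: float = 0.5,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Metric suite treating hypoxemia as the positive class.

    Confusion-matrix metrics are computed at ``threshold`` (positive iff
    probability >= threshold).  The ROC sweeps the unique probabilities;
    AUC is the trapezoid-rule area, with a stratified-bootstrap percentile
    confidence interval.  With a single-class validation set the undefined
    rates (and AUC) are reported as NaN with a warning.
    """
    prob = np.asarray(probabilities, float)
    y = np.asarray(labels).astype(bool)
    if prob.size == 0:
        raise ValueError("empty validation set")
    pred = prob >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))

    accuracy = (tp + tn) / y.size
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    specificity = _safe_div(tn, tn + fp, "specificity")
    precision = _safe_div(tp, tp + fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or (precision + sensitivity) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)

    if y.all() or not y.any():
        warnings.warn("single-class validation set: ROC/AUC undefined, reporting NaN")
        auc_val = float("nan")
        ci = (float("nan"), float("nan"))
        fpr = tpr = thr = np.empty(0)
    else:
        fpr, tpr, thr = roc_curve(y.astype(int), prob)
        auc_val = float(_trapezoid_auc(fpr, tpr))
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y)
        neg = np.flatnonzero(~y)
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            ip = rng.choice(pos, size=pos.size, replace=True)
            ineg = rng.choice(neg, size=neg.size, replace=True)
            idx = np.concatenate([ip, ineg])
            f, t, _ = roc_curve(y[idx].astype(int), prob[idx])
            boot[b] = _trapezoid_auc(f, t)
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        auc=auc_val,
        auc_ci=ci,
        roc_fpr=fpr,
        roc_tpr=tpr,
        roc_thresholds=thr,
    )


@dataclass
class CrossValResult:
    """Per-iteration reports, sample counts, and the cross-iteration summary."""

    reports: list[MetricsReport]
    counts: pd.DataFrame  # per-iteration class counts, Table-shaped
    summary: dict[str, float]
    histories: list[pd.DataFrame]
    assignments: list[list[FoldAssignment]]


def run_cross_validation(
    samples: pd.DataFrame,
    net_spec: NetworkSpec | None = None,
    train_config: TrainConfig | None = None,
    *,
    threshold: float = 0.5,
    n_bootstrap: int = 200,
    standardize_with_validation: bool = False,
) -> CrossValResult:
    """Run the five staggered CV iterations on a feature table.

    ``samples`` must carry the standard feature-table columns (``t``,
    ``round_id``, the 10 pulsation and 5 modulation columns, ``label``,
    ``valid``, ``win_start``, ``win_end``).  Invalid rows are dropped
    before fold assignment, so fold lengths count valid samples only.

    Per iteration: folds are assigned per round, overlap-excluded, the
    across-rounds pulsation standardizer is fitted on the training samples
    (or on all samples when ``standardize_with_validation``), the per-round
    modulation standardizer on each round's own samples, the network is
    trained (early-stopped on validation BCE) and evaluated on the pooled
    validation samples.  The summary holds the mean of each metric over the
    five iterations (NaN-aware, for iterations with single-class pools).
    """
    net_spec = net_spec or NetworkSpec()
    train_config = train_config or TrainConfig()
    df = samples.loc[samples["valid"]].sort_values(["round_id", "t"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no valid samples")
    round_ids = list(pd.unique(df["round_id"]))
    round_lengths = {r: int((df["round_id"] == r).sum()) for r in round_ids}
    round_positions = {r: np.flatnonzero((df["round_id"] == r).to_numpy()) for r in round_ids}

    reports: list[MetricsReport] = []
    histories: list[pd.DataFrame] = []
    all_assignments: list[list[FoldAssignment]] = []
    count_rows = []
    for j in range(N_FOLDS):
        train_rows: list[np.ndarray] = []
        val_rows: list[np.ndarray] = []
        assignments = []
        for a in assign_folds(round_lengths, j):
            pos = round_positions[a.round_id]
            sub = df.iloc[pos]
            a = exclude_overlap(
                a, sub["win_start"].to_numpy(float), sub["win_end"].to_numpy(float)
            )
            assignments.append(a)
            train_rows.append(pos[a.train_idx])
            val_rows.append(pos[a.val_idx])
        all_assignments.append(assignments)
        tr = np.concatenate(train_rows)
        va = np.concatenate(val_rows)
        df_tr, df_va = df.iloc[tr], df.iloc[va]

        y_tr = df_tr["label"].to_numpy(bool)
        y_va = df_va["label"].to_numpy(bool)
        if y_tr.all() or not y_tr.any():
            raise ValueError(f"iteration {j}: training set contains a single class")

        fit_df = df if standardize_with_validation else df_tr
        puls_std = Standardizer("across_rounds").fit(fit_df, PULSATION_COLUMNS)
        mod_std = Standardizer("per_round").fit(
            df, MODULATION_COLUMNS, df["round_id"].to_numpy()
        )
        xp_tr = puls_std.transform(df_tr)
        xp_va = puls_std.transform(df_va)
        xm_tr = mod_std.transform(df_tr, df_tr["round_id"].to_numpy())
        xm_va = mod_std.transform(df_va, df_va["round_id"].to_numpy())

        model = build_network(net_spec, seed=train_config.seed + j)
        cfg = TrainConfig(
            learning_rate=train_config.learning_rate,
            weight_decay=train_config.weight_decay,
            max_epochs=train_config.max_epochs,
            patience=train_config.patience,
            batch_size=train_config.batch_size,
            seed=train_config.seed + j,
            use_class_weights=train_config.use_class_weights,
        )
        hist = train(model, (xp_tr, xm_tr, y_tr), (xp_va, xm_va, y_va), cfg)
        histories.append(hist)

        prob = model.predict_proba(xp_va, xm_va)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate(
                prob, y_va, threshold=threshold, n_bootstrap=n_bootstrap,
                seed=train_config.seed + j,
            )
        reports.append(report)
        count_rows.append(
            {
                "iteration": j + 1,
                "hypoxemic_val": int(y_va.sum()),
                "hypoxemic_train": int(y_tr.sum()),
                "normoxemic_val": int((~y_va).sum()),
                "normoxemic_train": int((~y_tr).sum()),
                "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "precision": report.precision,
                "f1": report.f1,
            }
        )

    metric_names = ["accuracy", "sensitivity", "specificity", "precision", "f1", "auc"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        summary = {
            m: float(np.nanmean([getattr(rep, m) for rep in reports]))
            for m in metric_names
        }
    return CrossValResult(
        reports=reports,
        counts=pd.DataFrame(count_rows),
        summary=summary,
        histories=histories,
        assignments=all_assignments,
    )
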