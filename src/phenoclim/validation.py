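"""Cross-validation, ROC/AUC, classification thresholds and anomaly testing.

Repeated 75/25 train/test splitting with per-replicate model selection;
AUC as Mann–Whitney pairwise concordance; the three presence/absence
thresholds standard in distribution modelling — maximum-kappa (MaxKappa),
least presence threshold (LPT) and 5% least presence threshold — and the
confusion-matrix error rates (overall accuracy, commission = false
positive rate among observed absences, omission = false negative rate
among observed presences) used to judge out-of-season bloom prediction.

The classification rule throughout is "presence if score >= threshold",
so the LPT achieves exactly zero omission on its calibration presences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import apply_scaler, fit_scaler
from .basis import OrthoPolyBasis
from .glm import ModelSpec, build_design, enumerate_candidates, select_model

__all__ = [
    "CVConfig",
    "CVReplicate",
    "ThresholdSet",
    "ConfusionMetrics",
    "split_data",
    "roc_auc",
    "max_kappa_threshold",
    "lpt_threshold",
    "derive_thresholds",
    "confusion_metrics",
    "run_repeated_cv",
    "evaluate_anomaly",
]


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CVConfig:
    """Settings for repeated cross-validation."""

    n_reps: int = 10
    train_frac: float = 0.75
    criterion: str = "aicc"
    seed: int = 0


@dataclass
class CVReplicate:
    """One train/test split with its selection outcome and AUCs."""

    replicate: int
    seed: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    selected_spec: ModelSpec | None = None
    auc_train: float = np.nan
    auc_test: float = np.nan
    error: str | None = None


def split_data(row_ids, train_frac: float = 0.75, n_reps: int = 10, seed: int = 0):
    """Independent uniform random train/test splits, reproducible from seed.

    Each replicate permutes the rows with its own child generator and
    takes the first ``round(train_frac * n)`` as training rows. Splits are
    disjoint and exhaustive within each replicate and independent across
    replicates.
    """
    ids = np.asarray(row_ids)
    n = ids.shape[0]
    n_train = int(round(train_frac * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"cannot split {n} rows into non-empty train/test at {train_frac}")
    reps = []
    children = np.random.SeedSequence(seed).spawn(n_reps)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        reps.append(
            CVReplicate(
                replicate=i,
                seed=int(child.generate_state(1)[0] % (2**31)),
                train_ids=ids[perm[:n_train]],
                test_ids=ids[perm[n_train:]],
            )
        )
    return reps


# --------------------------------------------------------------------------
# AUC and thresholds
# --------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve as Mann–Whitney concordance.

    Equals P(score_pos > score_neg) + 0.5 P(tie) over all presence/absence
    pairs, computed via midranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata

    r = rankdata(s)
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _cohen_kappa(tp, fp, tn, fn) -> float:
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe >= 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Unique scores, midpoints of adjacent unique scores, and 0/1 endpoints."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.unique(np.concatenate([[0.0], u, mids, [1.0]]))


def max_kappa_threshold(scores, labels):
    """Threshold maximising Cohen's kappa; ties broken toward the smallest.

    Candidates are the unique scores plus adjacent midpoints and the 0/1
    endpoints, which exhausts every achievable confusion table. Returns
    ``(threshold, kappa)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("kappa needs both classes present")
    cands = _candidate_thresholds(s)
    # sort scores once; cumulative positives give each threshold's table
    order = np.argsort(s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    n_pos = int(y.sum())
    n = y.shape[0]
    # index of first score >= t for each candidate
    idx = np.searchsorted(s_sorted, cands, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    pos_below = cum_pos[idx]  # presences predicted absent
    tp = n_pos - pos_below
    fn = pos_below
    fp = (n - idx) - tp
    tn = idx - fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(pe >= 1.0, 0.0, (po - pe) / (1.0 - pe))
    best = int(np.argmax(kappa))  # argmax takes the first (smallest) maximiser
    return float(cands[best]), float(kappa[best])


def lpt_threshold(scores, labels, presence_quantile: float = 0.0) -> float:
    """Least presence threshold: the cutoff keeping (1−q) of presences classified presence.

    ``presence_quantile`` 0 gives the minimum presence score (all observed
    presences classified as such); 0.05 gives the largest threshold at
    which at least 95% of presences still score at or above it — the lower
    empirical quantile of presence scores, with no interpolation.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pres = np.sort(s[y == 1])
    m = pres.shape[0]
    if m == 0:
        raise ValueError("LPT needs at least one observed presence")
    idx = min(int(np.floor(presence_quantile * m)), m - 1)
    return float(pres[idx])


@dataclass(frozen=True)
class ThresholdSet:
    """MaxKappa, LPT and LPT 5% cutoffs from the calibration data."""

    maxkappa: float
    lpt: float
    lpt5: float
    kappa_at_max: float

    def as_dict(self) -> dict:
        return {
            "maxkappa": self.maxkappa,
            "lpt": self.lpt,
            "lpt5": self.lpt5,
            "kappa_at_max": self.kappa_at_max,
        }


def derive_thresholds(scores, labels) -> ThresholdSet:
    """All three thresholds from one calibration score/label set."""
    mk, kappa = max_kappa_threshold(scores, labels)
    return ThresholdSet(
        maxkappa=mk,
        lpt=lpt_threshold(scores, labels, 0.0),
        lpt5=lpt_threshold(scores, labels, 0.05),
        kappa_at_max=kappa,
    )


# --------------------------------------------------------------------------
# confusion metrics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts plus overall accuracy, commission and omission (percent)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def overall_accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def commission_rate(self) -> float:
        """False positives among observed absences, %; NaN if no absences."""
        denom = self.fp + self.tn
        if denom == 0:
            warnings.warn("no observed absences: commission rate undefined")
            return np.nan
        return 100.0 * self.fp / denom

    @property
    def omission_rate(self) -> float:
        """False negatives among observed presences, %; NaN if no presences."""
        denom = self.fn + self.tp
        if denom == 0:
            warnings.warn("no observed presences: omission rate undefined")
            return np.nan
        return 100.0 * self.fn / denom

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "overall_accuracy": self.overall_accuracy,
            "commission_rate": self.commission_rate,
            "omission_rate": self.omission_rate,
        }


def confusion_metrics(predicted, observed) -> ConfusionMetrics:
    """Confusion counts and rates from binary predictions and observations."""
    p = np.asarray(predicted).astype(int)
    o = np.asarray(observed).astype(int)
    if p.shape[0] != o.shape[0]:
        raise ValueError("predicted and observed lengths differ")
    if p.shape[0] == 0:
        raise ValueError("empty input")
    return ConfusionMetrics(
        tp=int(np.sum((p == 1) & (o == 1))),
        fp=int(np.sum((p == 1) & (o == 0))),
        tn=int(np.sum((p == 0) & (o == 0))),
        fn=int(np.sum((p == 0) & (o == 1))),
    )


# --------------------------------------------------------------------------
# repeated cross-validation and the anomaly test
# --------------------------------------------------------------------------


def _assert_normal_period(rows: pd.DataFrame, what: str) -> None:
    """Anomaly rows must never enter calibration; enforced, not just documented."""
    if "period" in rows.columns and (rows["period"] == "anomalous").any():
        raise ValueError(f"anomalous-period rows passed to {what}; they must be held out")


def fit_on_training(train_rows: pd.DataFrame, candidates=None, criterion: str = "aicc"):
    """Scaler + polynomial basis + model selection, all on training rows only.

    Returns ``(selection, scaler, poly_basis)``; use :func:`predict_rows`
    to score any other table with the frozen transforms.
    """
    _assert_normal_period(train_rows, "model calibration")
    if candidates is None:
        candidates = enumerate_candidates()
    scaler = fit_scaler(train_rows)
    train_scaled = apply_scaler(train_rows, scaler)
    poly = OrthoPolyBasis(degree=2).fit(train_scaled["scaled_daylength"].to_numpy(float))
    sel = select_model(candidates, train_scaled, poly, criterion=criterion)
    return sel, scaler, poly


def predict_rows(rows: pd.DataFrame, results, spec, scaler, poly) -> np.ndarray:
    """Probability predictions for new rows via the frozen training transforms."""
    scaled = apply_scaler(rows, scaler)
    X, _ = build_design(scaled, spec, poly)
    return results.predict(X)


def run_repeated_cv(rows: pd.DataFrame, candidates=None, config: CVConfig | None = None):
    """Repeated random-split cross-validation with per-replicate selection.

    For each replicate the scaler and the daylength polynomial basis are
    fitted on the training rows, model selection runs on the training rows,
    and AUC is evaluated on both train and test rows through the frozen
    transforms. Replicates whose fit fails are recorded and excluded from
    the means with a warning.

    Returns ``(replicates, summary)`` where summary holds the mean train
    and test AUC and the modal selected specification with its count.
    """
    if config is None:
        config = CVConfig()
    _assert_normal_period(rows, "cross-validation")
    if candidates is None:
        candidates = enumerate_candidates()
    rows = rows.reset_index(drop=True)
    reps = split_data(rows["record_id"].to_numpy(), config.train_frac, config.n_reps, config.seed)
    by_id = rows.set_index("record_id")
    for rep in reps:
        try:
            train = by_id.loc[rep.train_ids].reset_index()
            test = by_id.loc[rep.test_ids].reset_index()
            sel, scaler, poly = fit_on_training(train, candidates, config.criterion)
            rep.selected_spec = sel.best_spec
            p_train = predict_rows(train, sel.best_results, sel.best_spec, scaler, poly)
            p_test = predict_rows(test, sel.best_results, sel.best_spec, scaler, poly)
            rep.auc_train = roc_auc(p_train, train["y"].to_numpy())
            rep.auc_test = roc_auc(p_test, test["y"].to_numpy())
        except Exception as exc:  # noqa: BLE001 — replicate-level failures are data, not bugs
            rep.error = str(exc)
            warnings.warn(f"replicate {rep.replicate} failed and is excluded: {exc}")
    ok = [r for r in reps if r.error is None]
    if ok:
        spec_labels = [r.selected_spec.label for r in ok]
        modal = max(set(spec_labels), key=spec_labels.count)
        summary = {
            "n_replicates": len(reps),
            "n_ok": len(ok),
            "mean_auc_train": float(np.mean([r.auc_train for r in ok])),
            "mean_auc_test": float(np.mean([r.auc_test for r in ok])),
            "modal_spec": modal,
            "modal_count": spec_labels.count(modal),
        }
    else:
        summary = {"n_replicates": len(reps), "n_ok": 0}
    return reps, summary


def cv_table(reps) -> pd.DataFrame:
    """Per-replicate CV results as a tidy table."""
    return pd.DataFrame(
        {
            "replicate": [r.replicate for r in reps],
            "seed": [r.seed for r in reps],
            "selected_spec": [r.selected_spec.label if r.selected_spec else None for r in reps],
            "auc_train": [r.auc_train for r in reps],
            "auc_test": [r.auc_test for r in reps],
            "error": [r.error for r in reps],
        }
    )


def evaluate_anomaly(anomaly_rows: pd.DataFrame, results, spec, scaler, poly, thresholds: ThresholdSet):
    """Score anomalous-period rows with the final model and classify at each threshold.

    The thresholds must come from normal-period calibration data — the
    whole point is to ask whether a model of normal flowering predicts the
    out-of-season event. Returns ``{threshold_name: ConfusionMetrics}``.
    """
    if "period" in anomaly_rows.columns and (anomaly_rows["period"] != "anomalous").any():
        warnings.warn("evaluate_anomaly received non-anomalous rows; evaluating as given")
    p = predict_rows(anomaly_rows, results, spec, scaler, poly)
    y = anomaly_rows["y"].to_numpy().astype(int)
    out = {}
    for name, t in (("maxkappa", thresholds.maxkappa), ("lpt", thresholds.lpt), ("lpt5", thresholds.lpt5)):
        out[name] = confusion_metrics((p >= t).astype(int), y)
    return out
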