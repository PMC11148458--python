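"""Classification metrics, membership-inference auditing, and the
accuracy-loss-vs-forgotten-fraction sweep.

Multiclass metrics are macro-averaged over one-vs-rest confusion tables;
ROC AUC is the macro one-vs-rest rank statistic on the normalised score
matrix. The F1 score is reported as the harmonic mean of the macro precision
and macro recall.

The membership-inference attack (MIA) is the standard confidence-threshold
construction: a sample's confidence is the maximum normalised output score;
the attack threshold is chosen on a held-out shadow split to maximise
balanced accuracy and evaluated on the remaining split. A model that has
memorised its training data assigns systematically higher confidence to
members, so attack accuracy above chance indicates remembered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import DataError


@dataclass
class EvalReport:
    """Bundle of classification metrics, all in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    roc_auc: float
    averaging: str = "macro"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_auc": self.roc_auc,
            "averaging": self.averaging,
        }


@dataclass
class MIAResult:
    """Membership-inference attack metrics (member = positive class)."""

    accuracy: float
    precision: float
    recall: float
    attack: str = "confidence-threshold"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "attack": self.attack,
        }


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


def confusion_metrics(true_labels, predicted_labels, score_matrix=None) -> EvalReport:
    """Macro one-vs-rest metrics from labels and a row-normalised score matrix.

    Classes absent from ``true_labels`` are excluded from the macro averages
    with a warning. When the AUC is undefined (fewer than two classes
    present, or no scores given) it falls back to 0.5 with a warning.
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError("true and predicted labels must be aligned")
    present = np.unique(y)
    all_classes = np.unique(np.concatenate([y, p]))
    absent = np.setdiff1d(all_classes, present)
    if absent.size:
        warnings.warn(
            f"classes {absent.tolist()} absent from true labels; excluded from macro averages",
            stacklevel=2,
        )
    accuracy = float(np.mean(y == p)) if y.size else 0.0
    precs, recs, specs = [], [], []
    for c in present:
        tp = np.sum((y == c) & (p == c))
        fp = np.sum((y != c) & (p == c))
        fn = np.sum((y == c) & (p != c))
        tn = np.sum((y != c) & (p != c))
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
        specs.append(tn / (tn + fp) if tn + fp else 0.0)
    precision = float(np.mean(precs))
    recall = float(np.mean(recs))
    specificity = float(np.mean(specs))
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    roc = _macro_ovr_auc(y, score_matrix, present)
    return EvalReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=float(f1),
        sensitivity=recall,
        specificity=specificity,
        roc_auc=roc,
    )


def _macro_ovr_auc(y: np.ndarray, score_matrix, present: np.ndarray) -> float:
    if score_matrix is None or present.size < 2:
        warnings.warn("ROC AUC undefined; reporting 0.5", stacklevel=3)
        return 0.5
    scores = np.asarray(score_matrix, dtype=float)
    aucs = []
    for c in present:
        target = (y == c).astype(int)
        if target.min() == target.max():
            continue
        aucs.append(roc_auc_score(target, scores[:, c]))
    if not aucs:
        warnings.warn("ROC AUC undefined; reporting 0.5", stacklevel=3)
        return 0.5
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# Membership inference
# ---------------------------------------------------------------------------


def threshold_attack(member_conf, nonmember_conf, rng_seed=0) -> MIAResult:
    """Confidence-threshold MIA on precomputed per-sample confidences.

    Both populations are split in half: the shadow halves pick the threshold
    maximising balanced accuracy, the evaluation halves provide the reported
    accuracy / precision / recall of the membership prediction. The attack
    uses the standard direction — a sample is called a member when its
    confidence is at least the threshold — reflecting the assumption that
    memorised samples receive systematically higher confidence.
    """
    m = np.asarray(member_conf, dtype=float)
    nm = np.asarray(nonmember_conf, dtype=float)
    if m.size < 10 or nm.size < 10:
        raise DataError("need at least 10 member and 10 non-member samples")
    rng = np.random.default_rng(rng_seed)
    m = rng.permutation(m)
    nm = rng.permutation(nm)
    m_shadow, m_eval = m[: m.size // 2], m[m.size // 2 :]
    nm_shadow, nm_eval = nm[: nm.size // 2], nm[nm.size // 2 :]
    # candidate thresholds: midpoints between adjacent sorted shadow values
    pool = np.sort(np.concatenate([m_shadow, nm_shadow]))
    cands = np.concatenate([[pool[0] - 1e-12], (pool[:-1] + pool[1:]) / 2, [pool[-1] + 1e-12]])
    best = (-1.0, cands[0])  # (balanced accuracy, threshold)
    for thr in cands:
        bal = (np.mean(m_shadow >= thr) + np.mean(nm_shadow < thr)) / 2
        if bal > best[0]:
            best = (bal, thr)
    thr = best[1]
    pred_m = m_eval >= thr
    pred_nm = nm_eval >= thr
    tp = int(np.sum(pred_m))
    fn = int(np.sum(~pred_m))
    fp = int(np.sum(pred_nm))
    tn = int(np.sum(~pred_nm))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return MIAResult(accuracy=float(accuracy), precision=float(precision), recall=float(recall))


def mia_attack(model, member_samples, nonmember_samples, rng_seed=0) -> MIAResult:
    """Confidence-threshold MIA against a spiking network model.

    Confidence is the maximum normalised output score obtained by simulating
    each sample; see ``threshold_attack`` for the attack construction.
    """
    from .network import evaluate_dataset

    member_samples = np.asarray(member_samples, dtype=float)
    nonmember_samples = np.asarray(nonmember_samples, dtype=float)
    if len(member_samples) < 10 or len(nonmember_samples) < 10:
        raise DataError("need at least 10 member and 10 non-member samples")
    ss = np.random.SeedSequence(rng_seed)
    s_m, s_nm, s_att = ss.spawn(3)
    _, sc_m = evaluate_dataset(model, member_samples.reshape(len(member_samples), -1), rng_seed=s_m)
    _, sc_nm = evaluate_dataset(
        model, nonmember_samples.reshape(len(nonmember_samples), -1), rng_seed=s_nm
    )
    return threshold_attack(
        sc_m.max(axis=1), sc_nm.max(axis=1), rng_seed=int(s_att.generate_state(1)[0] % (2**31))
    )


# ---------------------------------------------------------------------------
# Trade-off sweep
# ---------------------------------------------------------------------------


def unlearning_sweep(experiment_factory, fractions, seeds) -> pd.DataFrame:
    """Accuracy-loss-vs-forgotten-fraction trade-off table.

    ``experiment_factory(fraction, seed)`` must train a model, unlearn the
    given sample fraction, and return ``(baseline_accuracy, post_accuracy)``
    on the test set. Returns one row per fraction x seed with the accuracy
    loss (baseline minus post-unlearning); a fraction of exactly 0 is the
    degenerate no-op with zero loss.
    """
    rows = []
    for frac in fractions:
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        for seed in seeds:
            if frac == 0:
                rows.append(
                    {"fraction": 0.0, "seed": seed, "baseline_accuracy": np.nan,
                     "post_accuracy": np.nan, "accuracy_loss": 0.0}
                )
                continue
            base, post = experiment_factory(frac, seed)
            rows.append(
                {
                    "fraction": float(frac),
                    "seed": seed,
                    "baseline_accuracy": float(base),
                    "post_accuracy": float(post),
                    "accuracy_loss": float(base) - float(post),
                }
            )
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd accuracy loss per forgotten fraction."""
    g = table.groupby("fraction")["accuracy_loss"]
    return pd.DataFrame(
        {"mean_loss": g.mean(), "sd_loss": g.std(ddof=1).fillna(0.0), "n": g.count()}
    ).reset_index()
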