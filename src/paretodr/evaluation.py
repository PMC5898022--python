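"""Leave-one-out evaluation with top-k metrics, AUC-PR/ROC, and upper bounds.

For each target drug the golden indication row is withheld, predictions are
made from the remaining drugs, and the prediction list is scored against the
withheld row: precision@k, recall@k, F1, specificity, AUC-PR and AUC-ROC,
averaged over targets. Upper-bound curves give the best any at-most-k (or
exactly-k, when forced guessing is allowed) list could achieve on the same
golden matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import MethodConfig
from .data_model import Dataset, GoldenAssociations, ValidationError
from .items import predict
from .similarity import build_profiles, compute_similarity_matrices

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """tp/fp/fn/tn of one prediction list at cap k.

    tp: predicted and truly indicated; fp: predicted but not indicated;
    fn: indicated but not predicted; tn: the rest of the target's disease
    row. tp + fp <= k because the list holds at most k entries.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    k: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tp + self.fp > self.k:
            raise ValidationError("tp + fp exceeds the list cap k")


def confusion_at_k(
    predicted: list[str], positives: set[str], n_diseases: int, k: int
) -> ConfusionCounts:
    """Count a prediction list against the withheld positives of one target."""
    pred = set(predicted)
    tp = len(pred & positives)
    fp = len(pred - positives)
    fn = len(positives - pred)
    tn = n_diseases - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, k=k)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), F1 their harmonic mean.

    Zero denominators (an empty prediction list, or P + R = 0) yield 0 by
    convention rather than an error, penalizing abstention in averages.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    if precision + recall == 0.0:
        return precision, recall, 0.0
    f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def specificity(c: ConfusionCounts) -> float:
    """tn / (tn + fp): performance on negative (no-indication) links."""
    if c.tn + c.fp == 0:
        raise ValidationError("specificity undefined: tn + fp = 0")
    return c.tn / (c.tn + c.fp)


def _check_labels(labels: np.ndarray) -> tuple[int, int]:
    pos = int(labels.sum())
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise ValidationError("AUC undefined: need at least one positive and one negative")
    return pos, neg


def auc_pr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve of a scored ranking.

    Ties are grouped (all items sharing a score enter together), precision
    and recall are evaluated at each group boundary, and the area is the
    trapezoid over those achievable points, anchored at recall 0 with the
    first achievable precision.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, _ = _check_labels(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group boundaries: last index of each tie block
    boundary = np.nonzero(np.diff(s))[0]
    idx = np.append(boundary, s.size - 1)
    cum_tp = np.cumsum(y)[idx]
    cum_n = idx + 1
    recall = cum_tp / n_pos
    precision = cum_tp / cum_n
    r = np.concatenate(([0.0], recall))
    p = np.concatenate(([precision[0]], precision))
    return float(np.trapezoid(p, r))


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties half).

    Computed as the Mann-Whitney statistic from midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_labels(labels)
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """The achievable (recall, precision) points of the tie-grouped PR curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, _ = _check_labels(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    idx = np.append(np.nonzero(np.diff(s))[0], s.size - 1)
    cum_tp = np.cumsum(y)[idx]
    return pd.DataFrame(
        {
            "score": s[idx],
            "recall": cum_tp / n_pos,
            "precision": cum_tp / (idx + 1),
        }
    )


def upper_bounds(
    golden: GoldenAssociations, k_values: list[int], allow_guess: bool = False
) -> pd.DataFrame:
    """Best achievable mean precision/recall/F1 per k on a golden matrix.

    For a target with p positives an oracle list yields tp = min(p, k).
    With forced guessing the list is padded to exactly k, so fp = k - tp;
    without guessing fp = 0 and precision is always 1. Targets with no
    positives are excluded, as in leave-one-out.
    """
    p_per_drug = golden.values.sum(axis=1).to_numpy()
    p_per_drug = p_per_drug[p_per_drug > 0]
    if p_per_drug.size == 0:
        raise ValidationError("upper_bounds: golden matrix has no positive rows")
    rows = []
    for k in k_values:
        tp = np.minimum(p_per_drug, k)
        fp = (k - tp) if allow_guess else np.zeros_like(tp)
        fn = p_per_drug - tp
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec = tp / p_per_drug
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
        rows.append(
            {
                "k": k,
                "precision": float(prec.mean()),
                "recall": float(rec.mean()),
                "f1": float(f1.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("k")


@dataclass
class EvaluationReport:
    """Per-target leave-one-out metrics and their means for one setting."""

    config: MethodConfig
    per_target: pd.DataFrame
    seed: int | None = None
    skipped: list[str] = field(default_factory=list)

    METRICS = ("precision", "recall", "f1", "specificity", "auc_pr", "auc_roc")

    @property
    def means(self) -> dict[str, float]:
        return {m: float(self.per_target[m].mean()) for m in self.METRICS}

    def summary_row(self) -> dict:
        sim_code = ",".join(
            f"{s}:{m}" for s, m in self.config.similarity.measures.items()
        )
        return {
            "sim": sim_code,
            "mot": self.config.mot,
            "ist": self.config.ist,
            "n": self.config.n,
            "k": self.config.k,
            **self.means,
        }


def leave_one_out(
    dataset: Dataset,
    config: MethodConfig,
    targets: list[str] | None = None,
    matrices: dict[str, pd.DataFrame] | None = None,
    pooled_auc: bool = False,
    seed: int | None = None,
) -> EvaluationReport:
    """Withhold each target's golden row, predict it, and score the prediction.

    Targets default to every golden drug with at least one indication; drugs
    with none are skipped with a warning (nothing to recover). Feature-source
    similarities never involve the golden matrix, so only the f(n, c) lookups
    need the withheld view. AUC metrics are computed per target over the
    target's full disease row — prediction-list scores for listed diseases,
    zero elsewhere — then averaged; ``pooled_auc`` instead pools all
    (score, label) pairs across targets into one curve.
    """
    golden = dataset.golden
    all_targets = targets if targets is not None else golden.drug_ids
    if matrices is None:
        matrices = compute_similarity_matrices(dataset, config.similarity)
    diseases = golden.disease_ids
    n_dis = len(diseases)
    disease_pos = {d: i for i, d in enumerate(diseases)}

    records = []
    skipped = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for t in all_targets:
        positives = set(golden.indications(t))
        if not positives:
            logger.warning("leave_one_out: target %r has no golden positives, skipped", t)
            skipped.append(t)
            continue
        withheld = golden.drop_drug(t)
        profiles = build_profiles(dataset, t, config.similarity, matrices=matrices)
        pred = predict(
            t, dataset, config, matrices=matrices, golden=withheld, profiles=profiles
        )
        c = confusion_at_k(pred.diseases, positives, n_dis, config.k)
        prec, rec, f1 = precision_recall_f1(c)
        # a target whose positives cover every unpredicted disease has no
        # negative universe; its specificity is undefined and left out of means
        spc = specificity(c) if (c.tn + c.fp) > 0 else np.nan

        score_vec = np.zeros(n_dis)
        for d, s in pred.entries:
            score_vec[disease_pos[d]] = s
        label_vec = golden.values.loc[t].to_numpy().astype(int)
        if pooled_auc:
            pooled_scores.append(score_vec)
            pooled_labels.append(label_vec)
            a_pr = a_roc = np.nan
        elif label_vec.sum() < label_vec.size:
            a_pr = auc_pr(score_vec, label_vec)
            a_roc = auc_roc(score_vec, label_vec)
        else:  # every disease indicated: no negatives, AUC undefined
            a_pr = a_roc = np.nan
        records.append(
            {
                "target": t,
                "n_predicted": len(pred),
                "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                "precision": prec, "recall": rec, "f1": f1,
                "specificity": spc, "auc_pr": a_pr, "auc_roc": a_roc,
            }
        )
    if not records:
        raise ValidationError("leave_one_out: no evaluable targets")
    per_target = pd.DataFrame(records).set_index("target")
    if pooled_auc:
        scores = np.concatenate(pooled_scores)
        labels = np.concatenate(pooled_labels)
        per_target["auc_pr"] = auc_pr(scores, labels)
        per_target["auc_roc"] = auc_roc(scores, labels)
    return EvaluationReport(config=config, per_target=per_target, seed=seed, skipped=skipped)


def evaluate_grid(
    dataset: Dataset,
    sim_codes: list[str],
    mots: list[str],
    ists: list[str],
    n_values: list[int],
    k_values: list[int],
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean metrics for every (sim, mot, ist, n, k) combination, one row each.

    Similarity matrices are computed once per sim setting and reused across
    the whole (mot, ist, n, k) grid.
    """
    rows = []
    for sim in sim_codes:
        cfg0 = MethodConfig.from_shorthand(sim=sim)
        matrices = compute_similarity_matrices(dataset, cfg0.similarity)
        for mot in mots:
            for ist in ists:
                for n in n_values:
                    for k in k_values:
                        cfg = MethodConfig.from_shorthand(sim=sim, mot=mot, ist=ist, n=n, k=k)
                        rep = leave_one_out(dataset, cfg, matrices=matrices, seed=seed)
                        rows.append(rep.summary_row())
    return pd.DataFrame(rows)
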