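"""Open-set decision rule and metrics: CSA, AUROC, OSCR, Acc/F1, openness.

Scoring convention.  Every test sample receives a scalar *known-ness score*,
here the maximum combined distance from its feature to the reciprocal points
(known-class features are trained to sit far from reciprocal points, so
higher = more likely known).  Rejection compares the score to a threshold
tau: a sample is declared unknown iff its score falls below tau.  The
threshold-free metrics sweep tau over all observed scores.

* CSA (closed-set accuracy): percent of known test samples whose predicted
  known class is correct; unknown samples are excluded.
* AUROC: all knowns are pooled into one super-known class and all unknowns
  into a super-unknown class; the area under the ROC of the known-ness score
  equals the probability that a random known outscores a random unknown
  (ties credit 1/2).
* OSCR: area under the curve of CCR (fraction of knowns passing the
  threshold AND correctly classified) against FPR (fraction of unknowns
  passing the threshold), swept over all observed scores.  OSCR <= CSA
  always, since CCR is capped by closed-set accuracy.
* Openness: how open the problem is given the number of classes seen in
  training versus at test; two published variants are provided (see
  :func:`openness`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from openherd.backbone import embed
from openherd.heads import am_softmax_logits, arpl_distance
from openherd.training import SplitSpec, TrainedModel, load_split_images
from openherd.synthetic import DatasetManifest

__all__ = ["UndefinedMetricError", "OpennessConfig", "MetricReport", "score_test_set",
           "decide", "auroc", "oscr", "csa", "closed_set_report", "openness", "aggregate"]


class UndefinedMetricError(ValueError):
    """Raised when a metric's preconditions (e.g. both knowns and unknowns
    present) are not met by the score table."""


@dataclass(frozen=True)
class OpennessConfig:
    """Class counts entering the openness formulas."""

    k_train: int
    k_test: int
    k_target: int | None = None
    variant: str = "sqrt"

    def __post_init__(self) -> None:
        if self.k_train < 1:
            raise ValueError("k_train must be >= 1")
        if self.k_train > self.k_test:
            raise ValueError("k_train cannot exceed k_test")
        if self.variant not in ("ratio", "sqrt"):
            raise ValueError("variant must be 'ratio' or 'sqrt'")


def openness(config: OpennessConfig) -> float:
    """Problem openness in percent.

    ``ratio``: ``(1 - k_train / k_test) * 100`` — the simple class-count
    ratio.  ``sqrt``: ``(1 - sqrt(2 k_train / (k_test + k_target))) * 100`` —
    the classical definition; ``k_target`` defaults to ``k_test``.  At 1
    known / 7 unknown individuals the sqrt variant gives 64.64 %.
    """
    if config.variant == "ratio":
        return (1.0 - config.k_train / config.k_test) * 100.0
    k_target = config.k_test if config.k_target is None else config.k_target
    return (1.0 - np.sqrt(2.0 * config.k_train / (config.k_test + k_target))) * 100.0


def score_test_set(model: TrainedModel, manifest: DatasetManifest, split: SplitSpec,
                   day: str | None = None, batch_size: int = 64) -> pd.DataFrame:
    """Score every test image of the split's individuals on the given day.

    Returns a score table with one row per test sample:

    ``known_score``      max over classes of the combined reciprocal-point
                         distance (higher = more likely known);
    ``predicted_class``  known-class index from the configured head
                         (AM-Softmax cosine argmax by default, reciprocal-
                         point distance argmax with ``predict_from:
                         rp_distance``); ties break to the lowest index;
    ``predicted_label``  the corresponding individual id;
    ``true_label``       ground-truth individual id;
    ``is_known``         whether the true individual was in the known set.

    The table's ``attrs['known_ids']`` records the label map.
    """
    if len(model.label_map) != len(split.known_ids) or \
            set(model.label_map) != set(split.known_ids):
        raise ValueError("trained state and split disagree on the known classes")
    ids = tuple(split.known_ids) + tuple(split.unknown_ids)
    images, labels = load_split_images(manifest, ids, day=day)

    scores, preds = [], []
    for start in range(0, len(images), batch_size):
        feats = embed(images[start:start + batch_size], model.spec, model.extractor)
        d = arpl_distance(feats, model.points)
        scores.append(d.max(axis=1))
        if model.config.predict_from == "rp_distance":
            preds.append(d.argmax(axis=1))
        else:
            logits = am_softmax_logits(feats, model.head)
            preds.append(logits.argmax(axis=1))
    known_score = np.concatenate(scores)
    predicted_class = np.concatenate(preds)

    table = pd.DataFrame({
        "known_score": known_score,
        "predicted_class": predicted_class,
        "predicted_label": [model.label_map[i] for i in predicted_class],
        "true_label": labels,
        "is_known": np.isin(labels, list(split.known_ids)),
    })
    table.attrs["known_ids"] = list(model.label_map)
    return table


def decide(table: pd.DataFrame, tau: float) -> np.ndarray:
    """Threshold decision: 'unknown' iff ``known_score < tau``, else the
    predicted known individual."""
    labels = table["predicted_label"].to_numpy(dtype=object).copy()
    labels[table["known_score"].to_numpy() < tau] = "unknown"
    return labels


def _split_scores(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    is_known = table["is_known"].to_numpy(dtype=bool)
    scores = table["known_score"].to_numpy(dtype=float)
    if not is_known.any() or is_known.all():
        raise UndefinedMetricError(
            "table must contain at least one known and one unknown sample")
    return scores, is_known


def auroc(table: pd.DataFrame) -> float:
    """Super-known vs super-unknown AUROC of the known-ness score, percent."""
    scores, is_known = _split_scores(table)
    return float(skm.roc_auc_score(is_known, scores) * 100.0)


def oscr(table: pd.DataFrame) -> float:
    """Open-set classification rate: area under CCR vs FPR, percent.

    Thresholds sweep the distinct observed scores (samples pass at
    ``score >= s``); the area uses right-continuous step integration, taking
    the CCR attained at each FPR level.
    """
    scores, is_known = _split_scores(table)
    correct = (table["predicted_label"].to_numpy() == table["true_label"].to_numpy())
    n_known = int(is_known.sum())
    n_unknown = int((~is_known).sum())

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    known_correct = (is_known & correct)[order]
    unknown_flag = (~is_known)[order]

    cum_ccr = np.cumsum(known_correct) / n_known
    cum_fpr = np.cumsum(unknown_flag) / n_unknown
    # evaluate at each distinct score (last occurrence includes all ties)
    last_of_value = np.nonzero(np.append(s_sorted[1:] != s_sorted[:-1], True))[0]
    ccr = cum_ccr[last_of_value]
    fpr = cum_fpr[last_of_value]
    prev_fpr = np.concatenate([[0.0], fpr[:-1]])
    return float(np.sum(ccr * (fpr - prev_fpr)) * 100.0)


def csa(table: pd.DataFrame) -> float:
    """Closed-set accuracy over known test samples, percent."""
    is_known = table["is_known"].to_numpy(dtype=bool)
    if not is_known.any():
        raise UndefinedMetricError("CSA needs at least one known sample")
    sub = table[is_known]
    return float(np.mean(sub["predicted_label"].to_numpy() == sub["true_label"].to_numpy())
                 * 100.0)


def closed_set_report(table: pd.DataFrame) -> dict:
    """Closed-set accuracy, macro F1 and confusion matrices.

    Every sample must belong to a known class (an all-known experiment).
    Returns ``acc`` and ``f1`` in percent plus the confusion matrix as raw
    counts and as row-normalised percentages (rows = true classes).
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    if not table["is_known"].all():
        raise ValueError("closed_set_report requires an all-known table")
    y_true = table["true_label"].to_numpy()
    y_pred = table["predicted_label"].to_numpy()
    classes = sorted(set(y_true) | set(y_pred))
    counts = skm.confusion_matrix(y_true, y_pred, labels=classes)
    row_sums = counts.sum(axis=1, keepdims=True)
    percents = np.divide(counts * 100.0, row_sums, where=row_sums > 0,
                         out=np.zeros_like(counts, dtype=float))
    return {
        "acc": float(skm.accuracy_score(y_true, y_pred) * 100.0),
        "f1": float(skm.f1_score(y_true, y_pred, labels=classes, average="macro",
                                 zero_division=0) * 100.0),
        "classes": classes,
        "confusion_counts": counts,
        "confusion_percent": percents,
    }


@dataclass
class MetricReport:
    """Per-trial metric values with mean and spread.

    ``per_trial`` has one row per trial and one column per metric (values in
    percent).  ``spread`` is the standard deviation under the configured
    convention (``sample`` = ddof 1, ``population`` = ddof 0), labelled
    explicitly because published "±" figures often leave this ambiguous.
    """

    per_trial: pd.DataFrame
    sd_convention: str = "sample"

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.per_trial.mean().items()}

    @property
    def spread(self) -> dict[str, float]:
        ddof = 1 if self.sd_convention == "sample" else 0
        if len(self.per_trial) < 2:
            return {k: 0.0 for k in self.per_trial.columns}
        return {k: float(v) for k, v in self.per_trial.std(ddof=ddof).items()}

    def summary(self) -> dict:
        return {
            "n_trials": int(len(self.per_trial)),
            "sd_convention": self.sd_convention,
            "mean": self.mean,
            "sd": self.spread,
            "per_trial": self.per_trial.to_dict(orient="records"),
        }


def evaluate_table(table: pd.DataFrame) -> dict[str, float]:
    """CSA/AUROC/OSCR of one score table (open-set trial), percent."""
    return {"csa": csa(table), "auroc": auroc(table), "oscr": oscr(table)}


def aggregate(reports: list, sd_convention: str = "sample") -> MetricReport:
    """Aggregate per-trial metric dicts (or MetricReports) into one report."""
    if not reports:
        raise ValueError("need at least one trial report")
    rows = []
    for r in reports:
        if isinstance(r, MetricReport):
            rows.extend(r.per_trial.to_dict(orient="records"))
        else:
            rows.append(dict(r))
    if sd_convention not in ("sample", "population"):
        raise ValueError("sd_convention must be 'sample' or 'population'")
    return MetricReport(per_trial=pd.DataFrame(rows), sd_convention=sd_convention)
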