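"""Segmentation and classification evaluation metrics.

Segmentation quality is measured per image by the dice similarity
coefficient (DSC), Jaccard index (JI) and relative volume difference
(RVD) between the annotated and predicted lesion pixel sets.
Classification quality over a test set of positive and negative images is
measured by pixel accuracy (PA), precision, TPR/FPR and the ROC AUC,
computed from image-level lesion scores (the predicted lesion-pixel
fraction) via the rank (Mann–Whitney) estimator of P(X1 > X0).

Conventions (negative images have empty annotations by construction):
DSC = JI = 1 when both masks are empty (a correct all-negative
segmentation); RVD is undefined for an empty annotation and such images
are excluded from its aggregate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "dsc",
    "jaccard",
    "rvd",
    "confusion",
    "auc",
    "evaluate_testset",
]


def _validate_pair(annotation: np.ndarray, prediction: np.ndarray):
    annotation = np.asarray(annotation)
    prediction = np.asarray(prediction)
    if annotation.shape != prediction.shape:
        raise ValueError(
            f"mask shape mismatch: annotation {annotation.shape} "
            f"vs prediction {prediction.shape}"
        )
    for name, m in (("annotation", annotation), ("prediction", prediction)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (0/1)")
    return annotation.astype(bool), prediction.astype(bool)


def dsc(annotation, prediction) -> float:
    """Dice similarity coefficient 2|A∩P| / (|A|+|P|); 1 when both empty."""
    a, p = _validate_pair(annotation, prediction)
    denom = a.sum() + p.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, p).sum() / denom


def jaccard(annotation, prediction) -> float:
    """Jaccard index |A∩P| / |A∪P|; 1 when both empty."""
    a, p = _validate_pair(annotation, prediction)
    union = np.logical_or(a, p).sum()
    if union == 0:
        return 1.0
    return np.logical_and(a, p).sum() / union


def rvd(annotation, prediction) -> float:
    """Relative volume difference (|P| - |A|) / |A|; needs a nonempty annotation."""
    a, p = _validate_pair(annotation, prediction)
    na = a.sum()
    if na == 0:
        raise ValueError("RVD undefined for an empty annotation")
    return (p.sum() - na) / na


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def pixel_accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts calling an instance positive when score > threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def auc(scores, labels) -> float:
    """ROC area as the rank estimate of P(X1 > X0), ties counted half.

    Equals the trapezoidal area under the ROC curve; requires at least one
    positive and one negative instance.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(
            f"AUC needs both classes; got {n1} positives and {n0} negatives"
        )
    ranks = rankdata(scores)  # midranks
    r1 = ranks[labels].sum()
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@dataclass
class MetricsReport:
    """Test-set summary: the six headline columns plus aggregation metadata."""

    dsc: float
    auc: float
    pa: float
    ji: float
    rvd: float
    precision: float
    pa_pixel: float
    n_images: int
    n_positive: int
    conventions: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_tsv(self) -> str:
        cols = ["DSC", "AUC", "PA", "JI", "RVD", "Precision"]
        vals = [self.dsc, self.auc, self.pa, self.ji, self.rvd, self.precision]
        return (
            "\t".join(cols) + "\n" + "\t".join(f"{v:.4f}" for v in vals) + "\n"
        )


def evaluate_testset(
    predictions,
    annotations,
    image_labels=None,
    positive_fraction_threshold: float = 1e-3,
) -> MetricsReport:
    """Aggregate metrics over aligned lists of binary masks.

    DSC/JI/RVD are averaged over images with a nonempty annotation. Each
    image receives a lesion score (predicted foreground fraction) and is
    called positive when the score exceeds ``positive_fraction_threshold``;
    PA, precision and AUC come from this image-level classification. AUC is
    NaN when the test set contains a single class.
    ``pa_pixel`` is the pooled pixel-level accuracy, reported alongside.
    ``image_labels`` defaults to annotation nonemptiness and is validated
    against it when given.
    """
    predictions = list(predictions)
    annotations = list(annotations)
    if len(predictions) != len(annotations):
        raise ValueError(
            f"misaligned lists: {len(predictions)} predictions "
            f"vs {len(annotations)} annotations"
        )
    derived = [int(np.asarray(a).sum() > 0) for a in annotations]
    if image_labels is None:
        image_labels = derived
    else:
        image_labels = [int(l) for l in image_labels]
        if image_labels != derived:
            raise ValueError("image labels inconsistent with annotation masks")
    dscs, jis, rvds = [], [], []
    scores = []
    tp = fp = tn = fn = 0
    for pred, ann, label in zip(predictions, annotations, image_labels):
        a, p = _validate_pair(ann, pred)
        if label:
            dscs.append(dsc(a.astype(int), p.astype(int)))
            jis.append(jaccard(a.astype(int), p.astype(int)))
            rvds.append(rvd(a.astype(int), p.astype(int)))
        scores.append(p.mean())
        tp += int(np.sum(p & a))
        tn += int(np.sum(~p & ~a))
        fp += int(np.sum(p & ~a))
        fn += int(np.sum(~p & a))
    counts = confusion(scores, image_labels, positive_fraction_threshold)
    pixel_total = tp + tn + fp + fn
    single_class = len(set(image_labels)) < 2
    return MetricsReport(
        dsc=float(np.mean(dscs)) if dscs else float("nan"),
        auc=float("nan") if single_class else auc(scores, image_labels),
        pa=counts.pixel_accuracy,
        ji=float(np.mean(jis)) if jis else float("nan"),
        rvd=float(np.mean(rvds)) if rvds else float("nan"),
        precision=counts.precision,
        pa_pixel=(tp + tn) / pixel_total if pixel_total else 0.0,
        n_images=len(predictions),
        n_positive=sum(image_labels),
        conventions={
            "dsc_ji_rvd": "averaged over images with nonempty annotations",
            "image_score": "predicted foreground pixel fraction",
            "positive_rule": f"score > {positive_fraction_threshold}",
            "pa": "image-level accuracy (pa_pixel gives pooled pixel accuracy)",
            "auc": "rank estimate of P(X1 > X0), midrank ties",
        },
    )
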