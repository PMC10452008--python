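"""Metric implementations against brute-force set-arithmetic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ghostseg import metrics

from conftest import random_mask_pair


# -- independent oracles (pixel-set loops, no vectorized shortcuts) -------


def oracle_sets(annotation, prediction):
    a = {tuple(ix) for ix in np.argwhere(np.asarray(annotation) == 1)}
    p = {tuple(ix) for ix in np.argwhere(np.asarray(prediction) == 1)}
    return a, p


def oracle_dsc(annotation, prediction):
    a, p = oracle_sets(annotation, prediction)
    if not a and not p:
        return 1.0
    return 2 * len(a & p) / (len(a) + len(p))


def oracle_jaccard(annotation, prediction):
    a, p = oracle_sets(annotation, prediction)
    if not a and not p:
        return 1.0
    return len(a & p) / len(a | p)


def oracle_rvd(annotation, prediction):
    a, p = oracle_sets(annotation, prediction)
    return (len(p) - len(a)) / len(a)


def oracle_auc(scores, labels):
    """Exhaustive pair counting of P(X1 > X0) with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for x1 in pos:
        for x0 in neg:
            total += 1.0 if x1 > x0 else (0.5 if x1 == x0 else 0.0)
    return total / (len(pos) * len(neg))


# -- tests -----------------------------------------------------------------


def test_dsc_examples():
    a = np.zeros(12, dtype=int)
    p = np.zeros(12, dtype=int)
    a[:4] = 1  # |A| = 4
    p[1:7] = 1  # |P| = 6, |A∩P| = 3
    assert metrics.dsc(a, p) == pytest.approx(0.6, abs=1e-12)
    assert metrics.jaccard(a, p) == pytest.approx(3 / 7, abs=1e-12)
    assert metrics.rvd(a, p) == pytest.approx(0.5, abs=1e-12)
    assert metrics.dsc(a, a) == 1.0
    assert metrics.dsc(np.zeros(4, int), np.zeros(4, int)) == 1.0
    disjoint = 1 - a
    assert metrics.dsc(a, disjoint) == 0.0
    assert metrics.rvd(a, np.zeros(12, int)) == -1.0
    with pytest.raises(ValueError, match="empty annotation"):
        metrics.rvd(np.zeros(4, int), p[:4])
    with pytest.raises(ValueError, match="shape"):
        metrics.dsc(np.zeros((2, 2), int), np.zeros((3, 3), int))


def test_masks_must_be_binary():
    with pytest.raises(ValueError, match="binary"):
        metrics.dsc(np.array([0, 2]), np.array([0, 1]))


def test_oracle_equivalence_on_random_pairs(rng):
    for _ in range(200):
        a, p = random_mask_pair(rng)
        assert abs(metrics.dsc(a, p) - oracle_dsc(a, p)) <= 1e-12
        assert abs(metrics.jaccard(a, p) - oracle_jaccard(a, p)) <= 1e-12
        if a.sum():
            assert abs(metrics.rvd(a, p) - oracle_rvd(a, p)) <= 1e-12


def test_dsc_jaccard_identities(rng):
    for _ in range(200):
        a, p = random_mask_pair(rng)
        d, j = metrics.dsc(a, p), metrics.jaccard(a, p)
        assert d >= j - 1e-15
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


def test_confusion_example_and_degenerate_thresholds():
    # TP=2, FP=1, TN=3, FN=2
    scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.05, 0.3, 0.15])
    labels = np.array([1, 1, 0, 1, 1, 0, 0, 0])
    c = metrics.confusion(scores, labels, threshold=0.5)
    assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 3, 2)
    assert c.precision == pytest.approx(2 / 3)
    assert c.tpr == pytest.approx(0.5)
    assert c.fpr == pytest.approx(0.25)
    assert c.pixel_accuracy == pytest.approx(5 / 8)
    hi = metrics.confusion(scores, labels, threshold=2.0)
    assert hi.tp == hi.fp == 0 and hi.precision == 0.0  # 0/0 -> 0
    perfect = metrics.confusion(labels.astype(float), labels, threshold=0.5)
    assert perfect.tpr == 1.0 and perfect.fpr == 0.0


def test_auc_closed_cases_and_pair_counting(rng):
    assert metrics.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert metrics.auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    for _ in range(50):
        scores = rng.integers(0, 5, size=8) / 4.0  # discrete -> ties occur
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert metrics.auc(scores, labels) == pytest.approx(
            oracle_auc(scores, labels), abs=1e-12
        )
    with pytest.raises(ValueError, match="both classes"):
        metrics.auc([0.1, 0.2], [1, 1])


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=20)
    labels = (rng.random(20) < 0.5).astype(int)
    labels[0], labels[1] = 0, 1
    base = metrics.auc(scores, labels)
    for f in (np.exp, np.tanh, lambda s: 3 * s + 7):
        assert metrics.auc(f(scores), labels) == pytest.approx(base, abs=1e-12)


def test_evaluate_testset_perfect_and_balanced():
    pos = np.zeros((8, 8), dtype=int)
    pos[2:5, 2:5] = 1
    neg = np.zeros((8, 8), dtype=int)
    report = metrics.evaluate_testset([pos, neg], [pos, neg])
    assert report.dsc == 1.0 and report.ji == 1.0 and report.rvd == 0.0
    assert report.pa == 1.0 and report.auc == 1.0 and report.precision == 1.0
    assert report.n_images == 2 and report.n_positive == 1


def test_evaluate_testset_matches_per_metric_oracles(rng):
    anns, preds = [], []
    for i in range(20):
        a, p = random_mask_pair(rng, shape=(12, 12), p=0.25 if i % 2 else 0.0)
        if i % 2 == 0:
            a = np.zeros_like(a)  # negatives: empty annotation
        anns.append(a)
        preds.append(p)
    report = metrics.evaluate_testset(preds, anns)
    pos = [i for i in range(20) if anns[i].sum() > 0]
    assert report.dsc == pytest.approx(
        np.mean([oracle_dsc(anns[i], preds[i]) for i in pos]), abs=1e-12
    )
    assert report.ji == pytest.approx(
        np.mean([oracle_jaccard(anns[i], preds[i]) for i in pos]), abs=1e-12
    )
    assert report.rvd == pytest.approx(
        np.mean([oracle_rvd(anns[i], preds[i]) for i in pos]), abs=1e-12
    )
    scores = [p.mean() for p in preds]
    labels = [int(a.sum() > 0) for a in anns]
    assert report.auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)


binary_mask = arrays(np.int8, (6, 6), elements=st.integers(0, 1))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(a=binary_mask, p=binary_mask)
def test_dsc_jaccard_relation_holds_for_all_masks(a, p):
    d, j = metrics.dsc(a, p), metrics.jaccard(a, p)
    assert 0.0 <= j <= d <= 1.0
    assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    scores=arrays(np.float64, 8, elements=st.floats(0, 1, allow_nan=False)),
    labels=arrays(np.int8, 8, elements=st.integers(0, 1)),
)
def test_auc_matches_pair_counting_for_all_inputs(scores, labels):
    if labels.sum() in (0, len(labels)):
        with pytest.raises(ValueError):
            metrics.auc(scores, labels)
    else:
        assert metrics.auc(scores, labels) == pytest.approx(
            oracle_auc(scores, labels), abs=1e-12
        )


def test_evaluate_testset_input_validation():
    m = np.zeros((4, 4), dtype=int)
    with pytest.raises(ValueError, match="misaligned"):
        metrics.evaluate_testset([m], [m, m])
    with pytest.raises(ValueError, match="inconsistent"):
        metrics.evaluate_testset([m], [m], image_labels=[1])


def test_report_serialization_round_trip():
    pos = np.ones((4, 4), dtype=int)
    neg = np.zeros((4, 4), dtype=int)
    report = metrics.evaluate_testset([pos, neg], [pos, neg])
    d = report.to_dict()
    assert {"dsc", "auc", "pa", "ji", "rvd", "precision"} <= set(d)
    tsv = report.to_tsv()
    assert tsv.splitlines()[0].split("\t") == [
        "DSC", "AUC", "PA", "JI", "RVD", "Precision",
    ]
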