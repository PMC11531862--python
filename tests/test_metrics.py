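import warnings

import numpy as np
import pytest
from sklearn.metrics import label_ranking_loss

from mtloc.metrics import MetricReport, evaluate, fmax_score, pr_curves


def brute_force_metrics(scores, labels, threshold=0.5):
    """Independent loop implementation of the full metric suite."""
    from sklearn.metrics import (average_precision_score, auc,
                                 precision_recall_curve, roc_auc_score)
    n, c = scores.shape
    ap, auroc, aupr = [], [], []
    for j in range(c):
        y = labels[:, j]
        if y.min() == y.max():
            continue
        ap.append(average_precision_score(y, scores[:, j]))
        auroc.append(roc_auc_score(y, scores[:, j]))
        p, r, _ = precision_recall_curve(y, scores[:, j])
        aupr.append(auc(r, p))
    pred = scores >= threshold
    jac = []
    for i in range(n):
        inter = int((pred[i] & (labels[i] > 0)).sum())
        union = int((pred[i] | (labels[i] > 0)).sum())
        jac.append(1.0 if union == 0 else inter / union)
    hloss = float((pred != (labels > 0)).mean())
    rl = []
    for i in range(n):
        pos = np.flatnonzero(labels[i] > 0)
        neg = np.flatnonzero(labels[i] == 0)
        if pos.size and neg.size:
            bad = 0.0
            for p_ in pos:
                for q in neg:
                    if scores[i, p_] < scores[i, q]:
                        bad += 1
                    elif scores[i, p_] == scores[i, q]:
                        bad += 0.5
            rl.append(bad / (pos.size * neg.size))
    oe = []
    for i in range(n):
        if labels[i].sum() > 0:
            oe.append(float(labels[i, scores[i].argmax()] == 0))
    return dict(ap=np.mean(ap), auroc=np.mean(auroc), aupr=np.mean(aupr),
                acc=np.mean(jac), hloss=hloss, rl=np.mean(rl),
                oerror=np.mean(oe))


def random_problem(rng, n=40, c=5):
    labels = (rng.random((n, c)) < 0.4).astype(int)
    scores = np.clip(0.6 * labels + rng.normal(0, 0.3, (n, c)), 0, 1)
    return scores, labels


def test_evaluate_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        scores, labels = random_problem(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = evaluate(scores, labels)
            ref = brute_force_metrics(scores, labels)
        for key, val in ref.items():
            assert getattr(report, key) == pytest.approx(val, abs=1e-10), key


def test_hamming_loss_hand_fixture():
    scores = np.array([[0.9, 0.2], [0.4, 0.7]])
    labels = np.array([[1, 1], [0, 1]])
    # predictions at 0.5: [[1,0],[0,1]] -> 1 of 4 bits wrong
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate(scores, labels)
    assert report.hloss == pytest.approx(0.25)


def test_perfect_scores_give_perfect_metrics():
    labels = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
    report = evaluate(labels.astype(float), labels)
    assert report.ap == pytest.approx(1.0)
    assert report.auroc == pytest.approx(1.0)
    assert report.acc == pytest.approx(1.0)
    assert report.fmax == pytest.approx(1.0)
    assert report.hloss == pytest.approx(0.0)
    assert report.rl == pytest.approx(0.0)
    assert report.oerror == pytest.approx(0.0)


def test_ranking_loss_matches_sklearn_without_ties():
    rng = np.random.default_rng(5)
    labels = (rng.random((30, 6)) < 0.5).astype(int)
    labels[0] = [1, 0, 0, 0, 0, 0]  # ensure mixed rows exist
    scores = rng.random((30, 6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate(scores, labels)
    keep = (labels.sum(axis=1) > 0) & (labels.sum(axis=1) < labels.shape[1])
    expected = label_ranking_loss(labels[keep], scores[keep])
    assert report.rl == pytest.approx(expected, abs=1e-10)


def test_ranking_loss_counts_ties_half():
    scores = np.array([[0.5, 0.5]])
    labels = np.array([[1, 0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate(scores, labels)
    assert report.rl == pytest.approx(0.5)


def test_fmax_known_case():
    scores = np.array([[0.9, 0.6, 0.1], [0.8, 0.2, 0.3]])
    labels = np.array([[1, 1, 0], [1, 0, 0]])
    fmax, t = fmax_score(scores, labels)
    # at t<=0.6: predictions [[1,1,0],[1,0,0]] are exact -> F1 = 1
    assert fmax == pytest.approx(1.0)
    assert t <= 0.6


def test_jaccard_empty_union_counts_as_one():
    scores = np.array([[0.1, 0.2]])
    labels = np.array([[0, 0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate(scores, labels)
    assert report.acc == pytest.approx(1.0)


def test_single_class_labels_skipped_with_warning():
    scores = np.array([[0.9, 0.4], [0.8, 0.6]])
    labels = np.array([[1, 1], [1, 0]])  # first label constant
    with pytest.warns(UserWarning, match="skipped"):
        report = evaluate(scores, labels)
    assert np.isfinite(report.auroc)


def test_evaluate_validates_inputs():
    with pytest.raises(ValueError):
        evaluate(np.zeros((2, 3)), np.zeros((3, 2)))
    with pytest.raises(ValueError):
        evaluate(np.zeros((2, 2)), np.array([[0, 2], [1, 0]]))


def test_metric_report_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    scores, labels = random_problem(rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate(scores, labels)
    path = tmp_path / "metrics.json"
    report.to_json(path)
    import json
    loaded = json.loads(path.read_text())
    assert loaded["auroc"] == pytest.approx(report.auroc)


def test_pr_curves_long_format():
    rng = np.random.default_rng(2)
    scores, labels = random_problem(rng, n=20, c=3)
    df = pr_curves(scores, labels, class_names=["a", "b", "c"])
    assert set(df.columns) == {"class", "recall", "precision"}
    assert set(df["class"]) <= {"a", "b", "c"}
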