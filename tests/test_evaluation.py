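"""Metrics, ANOVA and class-activation mapping."""

import logging

import numpy as np
import pytest
from scipy import stats

from fecnet import benchmarks
from fecnet.backbone import build_network, scheme_config
from fecnet.evaluation import (
    AnovaResult,
    InvalidInputError,
    confusion,
    grad_cam,
    harmonic_f1,
    metrics_report,
    one_way_anova,
)

TINY = dict(base_width=8, stem_channels=8, stage_depths=(1, 1, 1, 1))


# ----------------------------------------------------------------- confusion
def test_confusion_perfect_diagonal():
    cm = confusion([0, 1, 2, 3, 2], [0, 1, 2, 3, 2], 4)
    assert np.trace(cm.matrix) == 5
    assert cm.matrix.sum() == 5


def test_confusion_single_column():
    cm = confusion([0, 1, 2, 3], [1, 1, 1, 1], 4)
    assert cm.matrix[:, 1].sum() == 4
    assert cm.matrix[:, [0, 2, 3]].sum() == 0


def test_confusion_loop_oracle(rng):
    yt = rng.integers(0, 4, 500)
    yp = rng.integers(0, 4, 500)
    cm = confusion(yt, yp, 4)
    loop = np.zeros((4, 4), dtype=int)
    for a, b in zip(yt, yp):
        loop[a, b] += 1
    np.testing.assert_array_equal(cm.matrix, loop)


def test_confusion_errors():
    with pytest.raises(InvalidInputError):
        confusion([0, 1], [0], 2)
    with pytest.raises(InvalidInputError):
        confusion([0, 5], [0, 1], 4)


def test_confusion_one_vs_rest_accounting(rng):
    yt = rng.integers(0, 3, 200)
    yp = rng.integers(0, 3, 200)
    cm = confusion(yt, yp, 3)
    for c in range(3):
        d = cm.per_class(c)
        assert d["TP"] + d["FP"] + d["TN"] + d["FN"] == 200
    np.testing.assert_array_equal(cm.supports, np.bincount(yt, minlength=3))


# ------------------------------------------------------------------- metrics
def test_harmonic_f1_published_rows():
    p, r = benchmarks.AGGREGATE_PRECISION_RECALL["MC-SCMNet"]
    assert harmonic_f1(p, r) == 88.91
    p, r = benchmarks.AGGREGATE_PRECISION_RECALL["ResNeSt50"]
    assert harmonic_f1(p, r) == 84.09


def test_perfect_classifier_all_hundred():
    cm = confusion([0, 1, 2, 3] * 5, [0, 1, 2, 3] * 5, 4)
    rep = metrics_report(cm)
    assert rep.accuracy == 100.0
    for mode in rep.aggregates.values():
        assert mode["precision"] == 100.0
        assert mode["recall"] == 100.0
        assert mode["f1"] == 100.0


def test_metric_ranges_and_f1_betweenness(rng):
    yt = rng.integers(0, 4, 300)
    yp = np.where(rng.random(300) < 0.7, yt, rng.integers(0, 4, 300))
    rep = metrics_report(confusion(yt, yp, 4))
    for name in rep.class_names:
        p, r, f = (
            rep.per_class_precision[name],
            rep.per_class_recall[name],
            rep.per_class_f1[name],
        )
        assert 0 <= p <= 100 and 0 <= r <= 100 and 0 <= f <= 100
        assert min(p, r) - 0.01 <= f <= max(p, r) + 0.01
    assert 0 <= rep.accuracy <= 100


def test_accuracy_equals_trace_over_total(rng):
    yt = rng.integers(0, 4, 250)
    yp = rng.integers(0, 4, 250)
    cm = confusion(yt, yp, 4)
    rep = metrics_report(cm)
    assert rep.accuracy == round(100 * np.trace(cm.matrix) / 250, 2)


def test_per_class_f1_is_harmonic_mean(rng):
    yt = rng.integers(0, 3, 400)
    yp = rng.integers(0, 3, 400)
    cm = confusion(yt, yp, 3)
    for c in range(3):
        d = cm.per_class(c)
        p = d["TP"] / (d["TP"] + d["FP"])
        r = d["TP"] / (d["TP"] + d["FN"])
        f1 = 2 * p * r / (p + r)
        # identity of the two printed F1 formulas, to 1e-10
        alt = 2 * d["TP"] / (2 * d["TP"] + d["FP"] + d["FN"])
        assert f1 == pytest.approx(alt, abs=1e-10)
        assert metrics_report(cm).per_class_f1[str(c)] == round(100 * f1, 2)


def test_degenerate_class_reports_zero(caplog):
    # class 2 never predicted and never true positive
    cm = confusion([0, 0, 1, 1], [0, 1, 0, 1], 3)
    with caplog.at_level(logging.WARNING):
        rep = metrics_report(cm)
    assert rep.per_class_precision["2"] == 0.0
    assert "degenerate" in caplog.text


# --------------------------------------------------------------------- ANOVA
def _hand_anova(groups):
    """Independent textbook sum-of-squares oracle."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw), ssb, ssw


def test_anova_identical_groups_zero_f():
    res = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
    assert res.F == 0.0 and res.p_value == 1.0


def test_anova_degenerate_infinite_f():
    res = one_way_anova([[0.0, 0.0], [1.0, 1.0]])
    assert res.F == float("inf") and res.p_value == 0.0


def test_anova_matches_hand_oracle(rng):
    groups = [rng.normal(loc=m, size=6).tolist() for m in (0.0, 0.5, 1.0)]
    res = one_way_anova(groups)
    f_hand, ssb, ssw = _hand_anova(groups)
    assert res.F == pytest.approx(f_hand, abs=1e-10)
    assert res.ss_between == pytest.approx(ssb, abs=1e-10)
    assert res.ss_within == pytest.approx(ssw, abs=1e-10)


def test_anova_ss_decomposition_identity(rng):
    for _ in range(10):
        groups = [rng.normal(size=int(rng.integers(2, 8))) for _ in range(4)]
        res = one_way_anova(groups)
        allv = np.concatenate(groups)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        assert res.ss_total == pytest.approx(ss_total, rel=1e-8)
        assert res.ss_between + res.ss_within == pytest.approx(ss_total, rel=1e-8)


def test_anova_published_comparison_table():
    """Twelve networks x four category accuracies reproduce the printed test."""
    groups = list(benchmarks.anova_groups().values())
    assert len(groups) == 12
    res = one_way_anova(groups, alpha=0.05)
    assert res.df_between == 11
    assert res.df_within == 36
    assert round(res.F, 4) == 4.1364
    assert round(res.f_crit, 4) == 2.0666
    assert res.p_value == pytest.approx(0.000579, abs=5e-7)
    assert res.F > res.f_crit


def test_anova_against_scipy(rng):
    groups = [rng.normal(size=5) for _ in range(3)]
    res = one_way_anova(groups)
    f, p = stats.f_oneway(*groups)
    assert res.F == pytest.approx(f, rel=1e-10)
    assert res.p_value == pytest.approx(p, rel=1e-8)


def test_anova_errors():
    with pytest.raises(InvalidInputError):
        one_way_anova([[1.0, 2.0]])
    with pytest.raises(InvalidInputError):
        one_way_anova([[1.0], [2.0, 3.0]])


# ------------------------------------------------------------------ Grad-CAM
def test_grad_cam_shape_and_range(rng):
    net = build_network(scheme_config(14, **TINY))
    img = rng.random((3, 64, 64)).astype(np.float32)
    cam = grad_cam(net, img)
    assert cam.shape == (64, 64)
    assert cam.min() >= 0.0 and cam.max() <= 1.0
    if cam.std() > 0:
        assert cam.max() == pytest.approx(1.0)


def test_grad_cam_unknown_layer_lists_options(rng):
    net = build_network(scheme_config(14, **TINY))
    img = rng.random((3, 64, 64)).astype(np.float32)
    with pytest.raises(InvalidInputError) as exc:
        grad_cam(net, img, target_layer="bogus")
    assert "stage4" in str(exc.value)


def test_grad_cam_explicit_layer_and_class(rng):
    net = build_network(scheme_config(14, **TINY))
    img = rng.random((3, 64, 64)).astype(np.float32)
    cam = grad_cam(net, img, target_layer="stage3", target_class=2)
    assert cam.shape == (64, 64)


def test_grad_cam_localizes_foreground(trained_tiny_model):
    """Statistical localization oracle on held-out renders with known masks:
    mean heat density inside the object mask exceeds the density outside."""
    from fecnet.data import CLASS_NAMES, SyntheticSpec, render_sample

    net, _ = trained_tiny_model
    spec = SyntheticSpec(
        image_size=64, n_per_class=200, distractor_density=0.25,
        background_clutter_level=0.25, noise_sigma=0.01, seed=11,
    )
    ratios, wins = [], 0
    for i in range(24):
        cls = i % 4
        idx = 200 + i // 4  # beyond the dataset pool: genuinely unseen renders
        rr = np.random.default_rng([11, cls, idx])
        img, mask = render_sample(CLASS_NAMES[cls], rr, spec)
        x = (img.astype(np.float32) / 255).transpose(2, 0, 1)
        cam = grad_cam(net, x, target_layer="stage3", target_class=cls)
        din, dout = cam[mask].mean(), cam[~mask].mean()
        ratios.append(din / max(dout, 1e-9))
        wins += din > dout
    assert np.mean(ratios) > 1.0
    assert wins > 12
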