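"""Tests of confusion metrics, ROC/AUC and the cross-validated fusion harness."""

import numpy as np
import pandas as pd
import pytest

from mmdti import (
    ConfusionMatrix,
    MarkovPanelModel,
    build_feature_table,
    confusion_metrics,
    cross_validated_eval,
    roc_auc,
)
from mmdti.evaluation import generate_smri_features

from oracles import auc_by_pairwise_comparison


class TestConfusionMetrics:
    @pytest.mark.parametrize("cm, expected", [
        (ConfusionMatrix(50, 50, 0, 0), (1.0, 1.0, 1.0)),
        (ConfusionMatrix(99, 97, 3, 1), (0.98, 0.97, 0.99)),
        (ConfusionMatrix(0, 10, 0, 10), (0.5, 1.0, 0.0)),
    ])
    def test_arithmetic(self, cm, expected):
        m = confusion_metrics(cm)
        assert (m["accuracy"], m["specificity"], m["sensitivity"]) == \
            pytest.approx(expected)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = confusion_metrics(ConfusionMatrix(5, 0, 0, 0))
        assert np.isnan(m["specificity"])
        assert m["sensitivity"] == 1.0

    def test_printed_variant_is_precision_like(self):
        m = confusion_metrics(ConfusionMatrix(tp=8, tn=5, fp=2, fn=4), as_printed=True)
        assert m["sensitivity"] == pytest.approx(8 / 10)  # TP/(TP+FP)

    def test_accuracy_identity(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            cm = ConfusionMatrix(int(tp), int(tn), int(fp), int(fn))
            m = confusion_metrics(cm)
            P, N = tp + fn, tn + fp
            assert m["accuracy"] == pytest.approx(
                (m["sensitivity"] * P + m["specificity"] * N) / (P + N))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 2)


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_constant_scores_give_half(self):
        roc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert roc.auc == 0.5

    def test_anchors_and_monotonicity(self, rng):
        roc = roc_auc(rng.normal(size=50), rng.integers(0, 2, 50))
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_matches_pairwise_comparison_oracle(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 5, 20).astype(float)  # ties on purpose
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_by_pairwise_comparison(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transforms(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        ranks = scores.argsort().argsort().astype(float)
        assert roc_auc(ranks, labels).auc == pytest.approx(base, abs=1e-12)

    def test_label_flip_maps_auc(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


@pytest.fixture(scope="module")
def fitted(small_cohort_module):
    return MarkovPanelModel(small_cohort_module, covariate_names=()).fit()


@pytest.fixture(scope="module")
def small_cohort_module():
    from mmdti import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="module")
def profiles_module(small_cohort_module):
    from mmdti import ProfileConfig, generate_tract_profiles

    return generate_tract_profiles(ProfileConfig(seed=12), small_cohort_module.groups)


class TestFeatureTable:
    def test_dti_only_feature_count(self, profiles_module):
        from mmdti import exclude_untrackable_tracts

        table = build_feature_table(profiles=profiles_module, blocks=("dti",))
        feat = [c for c in table.columns if c != "label"]
        retained, _ = exclude_untrackable_tracts(profiles_module, 0.25)
        assert len(feat) == len(retained) * 2  # retained tracts x {FA, MD}
        assert all(c.startswith("dti__") for c in feat)

    def test_standardization(self, profiles_module):
        table = build_feature_table(profiles=profiles_module, blocks=("dti",))
        feat = table.drop(columns="label")
        assert np.allclose(feat.mean(), 0.0, atol=1e-8)
        assert np.allclose(feat.std(ddof=0), 1.0, atol=1e-8)

    def test_adding_block_preserves_rows_and_labels(self, fitted, profiles_module):
        t1 = build_feature_table(profiles=profiles_module, blocks=("dti",))
        t2 = build_feature_table(fit=fitted, profiles=profiles_module,
                                 blocks=("mm", "dti"))
        assert list(t1.index) == list(t2.index)
        assert (t1["label"] == t2["label"]).all()

    def test_smri_block(self, profiles_module):
        groups = dict(zip(profiles_module.subject_ids, profiles_module.group))
        smri = generate_smri_features(groups, seed=4)
        table = build_feature_table(profiles=profiles_module, smri=smri,
                                    blocks=("dti", "smri"))
        assert sum(c.startswith("smri__") for c in table.columns) == 3

    def test_missing_subject_is_explicit_error(self, fitted, profiles_module):
        groups = dict(zip(profiles_module.subject_ids, profiles_module.group))
        smri = generate_smri_features(groups, seed=4).iloc[:-1]
        with pytest.raises(ValueError, match="subject mismatch"):
            build_feature_table(profiles=profiles_module, smri=smri,
                                blocks=("dti", "smri"))


class TestCrossValidatedEval:
    def test_deterministic_given_seed(self, profiles_module):
        table = build_feature_table(profiles=profiles_module, blocks=("dti",))
        r1 = cross_validated_eval(table, folds=5, seed=3)
        r2 = cross_validated_eval(table, folds=5, seed=3)
        (k1, v1), (k2, v2) = r1.popitem(), r2.popitem()
        assert v1.confusion == v2.confusion
        assert v1.roc.auc == v2.roc.auc

    def test_null_features_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                {"label": ["AD"] * 30 + ["NC"] * 30}
                | {f"dti__f{j}": rng.normal(size=60) for j in range(5)},
                index=[f"s{i}" for i in range(60)])
            res = cross_validated_eval(table, folds=5, seed=seed)
            aucs.append(res[("dti",)].roc.auc)
        assert 0.4 <= np.median(aucs) <= 0.6

    def test_fusion_does_not_hurt_strong_block(self, fitted, profiles_module):
        table = build_feature_table(fit=fitted, profiles=profiles_module,
                                    blocks=("mm", "dti"))
        wins = 0
        for seed in range(10):
            res = cross_validated_eval(table, folds=5, seed=seed,
                                       block_combinations=[("dti",), ("mm", "dti")])
            if res[("mm", "dti")].roc.auc >= res[("dti",)].roc.auc - 0.02:
                wins += 1
        assert wins >= 9

    def test_too_few_class_members_rejected(self):
        table = pd.DataFrame({"label": ["AD", "NC", "NC", "NC", "NC", "NC"],
                              "dti__x": np.arange(6.0)},
                             index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="stratified"):
            cross_validated_eval(table, folds=3)


def test_plotting_smoke(profiles_module, rng):
    import matplotlib

    matplotlib.use("Agg")
    from mmdti.plotting import plot_roc, plot_tract_profiles

    ax = plot_tract_profiles(profiles_module, "Left Cingulum Cingulate", "FA")
    assert ax.get_title() == "Left Cingulum Cingulate"
    roc = roc_auc(rng.normal(size=40), rng.integers(0, 2, 40))
    ax2 = plot_roc(roc, label="demo")
    assert "demo" in ax2.get_legend().get_texts()[0].get_text()
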