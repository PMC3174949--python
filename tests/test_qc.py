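"""Band labeling, class balancing, the reliability forest, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rapmad.errors import DataError, QCError
from rapmad import qc as qc_mod
from rapmad.qc import (
    EXCLUDED,
    aggregate_replicates,
    aggregate_table,
    balance_classes,
    band_label,
    predict_reliability,
    train_reliability_classifier,
)
from rapmad.pipeline import normalize_slide, replicate_pivot


def replicate_frame(n=500, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(8.0, 1.0, n)
    df = pd.DataFrame(
        {s: base + rng.normal(0.0, noise, n) for s in (1, 2, 3)},
        index=[f"P{i:03d}" for i in range(n)],
    )
    df.index.name = "peptide_id"
    return df


class TestBandLabel:
    def test_perturbed_spot_flagged_and_matches_closed_form_oracle(self):
        """A +10 log2 perturbation is flagged, and the whole flag set equals
        an independent evaluation of the closed-form band formula."""
        from scipy import stats as sps

        df = replicate_frame(noise=0.3)
        df.loc["P010", 2] += 10.0
        lab = band_label(df)
        flagged = set(map(tuple, lab.loc[lab["label"] == "unreliable", ["peptide_id", "subarray"]].values))
        assert ("P010", 2) in flagged

        # independent oracle: scipy linregress + explicit band formula
        n = len(df)
        tcrit = sps.t.ppf(0.975, n - 2)
        oracle = set()
        for a in df.columns:
            masks = []
            for b in df.columns:
                if b == a:
                    continue
                reg = sps.linregress(df[b], df[a])
                resid = df[a] - (reg.intercept + reg.slope * df[b])
                s = 1.4826 * np.median(np.abs(resid - np.median(resid)))
                xbar = df[b].mean()
                sxx = ((df[b] - xbar) ** 2).sum()
                half = tcrit * s * np.sqrt(1 + 1 / n + (df[b] - xbar) ** 2 / sxx)
                masks.append((np.abs(resid) > half).to_numpy())
            out = np.logical_and.reduce(masks)
            oracle |= {(pid, a) for pid, o in zip(df.index, out) if o}
        assert flagged == oracle
        # false flags are rare: only band-tail noise spots besides the outlier
        assert len(flagged) - 1 <= 0.02 * 3 * n

    def test_collinear_replicates_all_reliable(self):
        lab = band_label(replicate_frame())
        assert (lab["label"] == "reliable").all()
        assert (lab["probability_reliable"] == 1.0).all()

    def test_monotone_in_level(self):
        df = replicate_frame(seed=3, noise=0.3)
        flags = {}
        for level in (1e-9, 0.5, 0.95, 1 - 1e-12):
            lab = band_label(df, level=level)
            flags[level] = set(map(tuple, lab.loc[lab["label"] == "unreliable", ["peptide_id", "subarray"]].values))
        assert flags[1 - 1e-12] <= flags[0.95] <= flags[0.5] <= flags[1e-9]
        assert len(flags[1e-9]) == 3 * len(df)  # every noisy spot outside a zero-width band
        assert len(flags[1 - 1e-12]) == 0

    def test_artifact_detection_on_reference_slide(self, experiment, normalized_high):
        """At the fixture seed, the single-regression (any-partner) rule
        flags at least 80% of the ±4 sd artifact spots."""
        per_spot, _ = normalized_high
        lab = band_label(replicate_pivot(per_spot), partner_rule="any")
        truth = experiment.truth.spots["array3"].merge(
            experiment.design[["block", "row", "col", "peptide_id", "subarray", "control_class"]],
            on=["block", "row", "col"],
        )
        truth = truth[truth["control_class"] == "experimental"]
        m = truth.merge(lab, on=["peptide_id", "subarray"])
        art = m["is_artifact"].to_numpy()
        flagged = (m["label"] == "unreliable").to_numpy()
        assert flagged[art].mean() >= 0.80
        # the conservative default (all partners) trades recall for far fewer
        # false flags on clean spots
        lab_all = band_label(replicate_pivot(per_spot))
        m_all = truth.merge(lab_all, on=["peptide_id", "subarray"])
        f_all = (m_all["label"] == "unreliable").to_numpy()
        assert f_all[~m_all["is_artifact"]].mean() < flagged[~art].mean()

    def test_too_few_subarrays(self):
        with pytest.raises(QCError):
            band_label(replicate_frame().iloc[:, :2])

    def test_degenerate_predictor(self):
        df = replicate_frame()
        df[2] = 5.0
        with pytest.raises(QCError, match="zero variance"):
            band_label(df)

    def test_confidence_band_flags_no_less_than_prediction(self):
        df = replicate_frame(seed=5, noise=0.4)
        pred = band_label(df, band="prediction")
        conf = band_label(df, band="confidence")
        n_pred = (pred["label"] == "unreliable").sum()
        n_conf = (conf["label"] == "unreliable").sum()
        assert n_conf >= n_pred


class TestBalanceClasses:
    def test_downsampling(self):
        labels = ["reliable"] * 100 + ["unreliable"] * 10
        idx = balance_classes(labels, seed=0)
        picked = np.asarray(labels)[idx]
        assert (picked == "reliable").sum() == 10
        assert (picked == "unreliable").sum() == 10

    def test_already_balanced_identity(self):
        labels = ["reliable"] * 10 + ["unreliable"] * 10
        assert list(balance_classes(labels, seed=1)) == list(range(20))

    def test_deterministic_under_seed(self):
        labels = ["reliable"] * 50 + ["unreliable"] * 7
        a = balance_classes(labels, seed=5)
        b = balance_classes(labels, seed=5)
        assert (a == b).all()

    def test_single_class_rejected(self):
        with pytest.raises(QCError):
            balance_classes(["reliable"] * 5)


def separable_features(n=400, seed=0, artifact_rate=0.3):
    rng = np.random.default_rng(seed)
    art = rng.random(n) < artifact_rate
    return (
        pd.DataFrame(
            {
                "pixel_variation": np.where(art, 10.0, 1.0) * rng.lognormal(0.0, 0.2, n),
                "diameter": rng.normal(120, 5, n) + np.where(art, 40, 0),
                "background": rng.normal(50, 5, n),
            }
        ),
        np.where(art, "unreliable", "reliable"),
    )


class TestReliabilityClassifier:
    def test_separable_features_high_accuracy(self):
        X, y = separable_features(seed=1)
        clf = train_reliability_classifier(X.iloc[:300], y[:300], n_trees=100, seed=0)
        pred = predict_reliability(clf, X.iloc[300:])
        acc = (pred["label"].to_numpy() == y[300:]).mean()
        assert acc >= 0.95

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(2)
        X, _ = separable_features(seed=2, artifact_rate=0.0)
        y = np.where(rng.random(len(X)) < 0.5, "reliable", "unreliable")
        clf = train_reliability_classifier(X.iloc[:300], y[:300], n_trees=100, seed=0)
        pred = predict_reliability(clf, X.iloc[300:])
        acc = (pred["label"].to_numpy() == y[300:]).mean()
        assert 0.35 <= acc <= 0.65

    def test_deterministic_under_seed(self):
        X, y = separable_features(seed=3)
        p1 = predict_reliability(train_reliability_classifier(X, y, n_trees=50, seed=9), X)
        p2 = predict_reliability(train_reliability_classifier(X, y, n_trees=50, seed=9), X)
        assert (p1["probability_reliable"] == p2["probability_reliable"]).all()

    def test_missing_feature_rejected(self):
        X, y = separable_features(seed=4)
        clf = train_reliability_classifier(X, y, n_trees=20, seed=0)
        with pytest.raises(QCError, match="missing"):
            predict_reliability(clf, X.drop(columns=["pixel_variation"]))

    def test_too_few_spots_rejected(self):
        X, y = separable_features(n=30, seed=5, artifact_rate=0.1)
        with pytest.raises(QCError):
            train_reliability_classifier(X.iloc[:12], y[:12], n_trees=10, seed=0)

    def test_oob_metadata_recorded(self, qc_classifier):
        assert 0.5 < qc_classifier.metadata["oob_accuracy"] <= 1.0
        assert qc_classifier.metadata["n_trees"] == 200

    def test_persistence_roundtrip(self, qc_classifier, tmp_path):
        p = tmp_path / "clf.joblib"
        qc_classifier.save(p)
        back = qc_mod.ReliabilityClassifier.load(p)
        assert back.feature_names == qc_classifier.feature_names
        assert back.version == qc_classifier.version


class TestAggregateReplicates:
    def test_weighted_mean(self):
        v = aggregate_replicates([10.0, 12.0], probabilities=[0.5, 1.0], labels=["reliable", "reliable"])
        assert v == pytest.approx((0.5 * 10 + 1.0 * 12) / 1.5)

    def test_all_unreliable_excluded(self):
        assert aggregate_replicates([1.0, 2.0, 3.0], [0.1, 0.1, 0.1],
                                    ["unreliable"] * 3) is EXCLUDED

    def test_equal_weights_is_plain_mean(self):
        assert aggregate_replicates([1.0, 2.0, 6.0]) == pytest.approx(3.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(DataError):
            aggregate_replicates([1.0], probabilities=[-0.5], labels=["reliable"])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        values=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
        data=st.data(),
    )
    def test_result_within_retained_range(self, values, data):
        n = len(values)
        probs = data.draw(st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.sampled_from(["reliable", "unreliable"]), min_size=n, max_size=n))
        out = aggregate_replicates(values, probs, labels)
        kept = [v for v, l in zip(values, labels) if l == "reliable"]
        if not kept:
            assert out is EXCLUDED
        else:
            assert min(kept) - 1e-9 <= out <= max(kept) + 1e-9

    def test_table_aggregation_matches_scalar_path(self):
        df = pd.DataFrame(
            {
                "peptide_id": ["A", "A", "A", "B", "B", "B"],
                "normalized": [10.0, 12.0, 11.0, 1.0, 2.0, 3.0],
                "probability_reliable": [0.5, 1.0, 0.8, 1.0, 1.0, 1.0],
                "label": ["reliable", "reliable", "unreliable"] + ["unreliable"] * 3,
            }
        )
        out = aggregate_table(df)
        assert out.loc["A", "value"] == pytest.approx(
            aggregate_replicates([10.0, 12.0], [0.5, 1.0], ["reliable", "reliable"])
        )
        assert bool(out.loc["B", "excluded"])
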