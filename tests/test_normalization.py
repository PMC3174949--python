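"""Binary-log transform, control-peptide effects model, correction, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from rapmad.errors import CorrectionError, DataError, FitError, StateError
from rapmad.gpr_io import SpotTable
from rapmad.layout import build_design
from rapmad.normalization import (
    EffectsModel,
    correct,
    fit_effects_model,
    log2_transform,
    variance_reduction,
)
from rapmad.pipeline import normalize_slide
from rapmad.synthetic import GeneratorParams, generate_experiment

_ZERO_SPATIAL = dict(needle_sd=0, subarray_sd=0, row_gradient=0, row_jitter=0,
                     col_gradient=0, col_jitter=0, artifact_fraction=(0, 0))


class TestLog2Transform:
    def test_power_of_two(self):
        assert log2_transform(1024.0) == 10.0

    def test_zero_floored(self):
        assert log2_transform(0.0) == 0.0

    def test_against_independent_arithmetic(self):
        assert log2_transform(1000.0) == pytest.approx(math.log(1000) / math.log(2), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(DataError):
            log2_transform(-1.0)

    def test_monotone(self):
        x = np.linspace(0, 50, 201)
        y = log2_transform(x)
        assert (np.diff(y) >= 0).all()


def small_control_frame(layout, seed=0, sd=0.3, effects=None):
    """Controls of a 1200-spot layout (120 observations) with known effects."""
    design, _ = build_design(layout)
    ctr = design[design["control_class"] != "experimental"].copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, sd, len(ctr))
    if effects:
        for factor, col, mapping in effects:
            y = y + ctr[col].map(mapping).fillna(0.0).to_numpy()
    ctr["log_intensity"] = 8.0 + y
    return ctr


FACTOR_COLS = [("Peptide", "peptide_id"), ("Subarray", "subarray"), ("Needle", "needle"),
               ("Row", "global_row"), ("Column", "global_col")]


def sequential_pinv_oracle(ctr):
    """Brute-force sequential least squares via numpy pinv/lstsq: per-term
    df (rank increments) and Type I sums of squares."""
    y = ctr["log_intensity"].to_numpy(dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    rank_prev = 1
    out = {}
    for term, col in FACTOR_COLS:
        dummies = pd.get_dummies(ctr[col].astype("category"), drop_first=True).to_numpy(float)
        X = np.hstack([X, dummies])
        beta = np.linalg.pinv(X) @ y
        rss = float(((y - X @ beta) ** 2).sum())
        rank = np.linalg.matrix_rank(X)
        out[term] = {"df": rank - rank_prev, "ss": rss_prev - rss}
        rss_prev, rank_prev = rss, rank
    out["Residuals"] = {"df": n - rank_prev, "ss": rss_prev}
    return out


class TestFitEffectsModel:
    def test_anova_df_pattern_on_reference_slide(self, normalized_high):
        """The stacking convention forces the printed degrees of freedom:
        3 subarrays -> 2, 16 needles -> 15, rows lose the block-row margins
        (240-6=234), columns the block-column margins (80-4=76)."""
        _, model = normalized_high
        tab = model.anova.set_index("Term")
        assert tab.loc["Peptide", "Df"] == 12
        assert tab.loc["Subarray", "Df"] == 2
        assert tab.loc["Needle", "Df"] == 15
        assert tab.loc["Row", "Df"] == 234
        assert tab.loc["Column", "Df"] == 76
        assert tab["Df"].sum() == model.n_obs - 1

    def test_sequential_ss_totals(self, normalized_high):
        _, model = normalized_high
        tab = model.anova.set_index("Term")
        # sequential SS must decompose the total centered SS exactly
        per_spot, _ = normalized_high
        ctr = per_spot[per_spot["control_class"] != "experimental"]
        y = ctr["log_intensity"].to_numpy()
        total = float(((y - y.mean()) ** 2).sum())
        assert tab["SumSq"].sum() == pytest.approx(total, rel=1e-8)

    def test_matches_pinv_oracle_on_small_instance(self, small_layout):
        ctr = small_control_frame(small_layout, seed=2, effects=[
            ("Needle", "needle", {1: 0.5, 2: -0.2, 3: 0.1, 4: -0.4}),
            ("Subarray", "subarray", {1: 0.2, 2: 0.0, 3: -0.2}),
        ])
        assert len(ctr) <= 200
        model = fit_effects_model(ctr)
        oracle = sequential_pinv_oracle(ctr)
        tab = model.anova.set_index("Term")
        for term in ["Peptide", "Subarray", "Needle", "Row", "Column", "Residuals"]:
            assert tab.loc[term, "Df"] == oracle[term]["df"], term
            assert tab.loc[term, "SumSq"] == pytest.approx(oracle[term]["ss"], rel=1e-8, abs=1e-8), term

    def test_matches_statsmodels_rss(self, small_layout):
        sm = pytest.importorskip("statsmodels.api")
        ctr = small_control_frame(small_layout, seed=3)
        model = fit_effects_model(ctr)
        X = np.ones((len(ctr), 1))
        for _, col in FACTOR_COLS:
            X = np.hstack([X, pd.get_dummies(ctr[col].astype("category"), drop_first=True).to_numpy(float)])
        fit = sm.OLS(ctr["log_intensity"].to_numpy(), X).fit()
        assert float(model.anova.set_index("Term").loc["Residuals", "SumSq"]) == pytest.approx(
            float(fit.ssr), rel=1e-8
        )

    def test_thin_level_rejected(self, small_layout):
        ctr = small_control_frame(small_layout, seed=1)
        ctr.loc[ctr.index[0], "needle"] = 99  # a needle level with one control spot
        with pytest.raises(FitError, match="needle"):
            fit_effects_model(ctr)

    def test_zero_effect_estimates_within_sampling_bounds(self, small_layout):
        """Pure-noise controls: centered effect estimates stay within 4x their
        exact design-based standard errors (pinv covariance oracle)."""
        sd = 0.3
        ctr = small_control_frame(small_layout, seed=7, sd=sd)
        model = fit_effects_model(ctr)
        # oracle: exact covariance of the kept-coefficient vector
        X = np.ones((len(ctr), 1))
        labels = [("Intercept", None)]
        for term, col in FACTOR_COLS:
            levels = sorted(ctr[col].unique())
            for lev in levels[1:]:
                X = np.hstack([X, (ctr[col] == lev).to_numpy(float)[:, None]])
                labels.append((term, lev))
        keep = []
        for j in range(X.shape[1]):  # mirror greedy order-respecting alias drop
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
        Xk = X[:, keep]
        cov = sd ** 2 * np.linalg.pinv(Xk.T @ Xk)
        kept_labels = [labels[j] for j in keep]
        counts_by = {t: ctr[c].value_counts() for t, c in FACTOR_COLS}
        for factor in ("Subarray", "Needle", "Row", "Column"):
            levels = sorted(counts_by[factor].index)
            w = counts_by[factor].reindex(levels).to_numpy(float)
            w = w / w.sum()
            # selector matrix: raw level effects (baseline/aliased rows zero)
            S = np.zeros((len(levels), Xk.shape[1]))
            for i, lev in enumerate(levels):
                if (factor, lev) in kept_labels:
                    S[i, kept_labels.index((factor, lev))] = 1.0
            A = S - w[None, :] @ S  # centering
            se = np.sqrt(np.clip(np.diag(A @ cov @ A.T), 0, None))
            est = np.array([model.effects[factor][lev] for lev in levels])
            assert (np.abs(est) <= 4 * se + 1e-9).all(), factor

    def test_injected_needle_effect_removed_by_correction(self):
        """A +1 log2 bump injected on one needle is flattened by correction
        to within ±0.1, even though the raw coefficient split between the
        collinear factors is noisier."""
        params = GeneratorParams(seed=4, **_ZERO_SPATIAL)
        exp = generate_experiment(params)
        d = exp.design
        mask = (d["needle"] == 7).to_numpy()
        tab = exp.incubation["array1"].data.copy()
        tab.loc[mask, "raw_intensity"] *= 2.0  # +1.0 on the log2 scale
        per_spot, _ = normalize_slide(SpotTable(tab), exp.annotation)
        before = per_spot["log_intensity"][mask].mean() - per_spot["log_intensity"][~mask].mean()
        after = per_spot["normalized"][mask].mean() - per_spot["normalized"][~mask].mean()
        assert before == pytest.approx(1.0, abs=0.15)
        assert abs(after) <= 0.1


class TestCorrect:
    def test_zero_model_is_identity(self, small_layout):
        ctr = small_control_frame(small_layout, seed=0)
        model = EffectsModel(intercept=0.0, effects={})
        out = correct(ctr, model)
        assert np.allclose(out, ctr["log_intensity"])

    def test_single_needle_effect(self):
        spots = pd.DataFrame({"log_intensity": [10.0], "needle": [3]})
        model = EffectsModel(intercept=0.0, effects={"Needle": {3: 2.0}})
        assert correct(spots, model).iloc[0] == 8.0

    def test_unknown_level_rejected(self):
        spots = pd.DataFrame({"log_intensity": [10.0], "needle": [4]})
        model = EffectsModel(intercept=0.0, effects={"Needle": {3: 2.0}})
        with pytest.raises(CorrectionError, match="Needle"):
            correct(spots, model)

    def test_variance_never_increased_on_controls(self, normalized_high):
        per_spot, _ = normalized_high
        ctr = per_spot[per_spot["control_class"] != "experimental"]
        # within control peptides: correction removes systematic spread
        before = ctr.groupby("peptide_id")["log_intensity"].var().mean()
        after = ctr.groupby("peptide_id")["normalized"].var().mean()
        assert after <= before

    def test_control_mean_preserved(self, normalized_high):
        per_spot, _ = normalized_high
        ctr = per_spot[per_spot["control_class"] != "experimental"]
        assert ctr["normalized"].mean() == pytest.approx(ctr["log_intensity"].mean(), abs=1e-8)


class TestVarianceReduction:
    def test_unfitted_model_rejected(self):
        with pytest.raises(StateError):
            variance_reduction(EffectsModel(intercept=0.0))

    def test_null_small(self):
        exp = generate_experiment(GeneratorParams(seed=3, **_ZERO_SPATIAL))
        _, model = normalize_slide(exp.incubation["array1"], exp.annotation)
        assert variance_reduction(model) < 0.2

    def test_systematic_dominating_nine_to_one(self):
        params = GeneratorParams(seed=5, noise_sd=0.2, needle_sd=0, subarray_sd=0,
                                 row_gradient=0, col_gradient=0,
                                 row_jitter=0.42, col_jitter=0.42, artifact_fraction=(0, 0))
        exp = generate_experiment(params)
        _, model = normalize_slide(exp.incubation["array1"], exp.annotation)
        assert variance_reduction(model) == pytest.approx(0.9, abs=0.05)

    def test_zero_residual_gives_one(self):
        exp = generate_experiment(GeneratorParams(seed=6, noise_sd=0.0, artifact_fraction=(0, 0)))
        _, model = normalize_slide(exp.incubation["array1"], exp.annotation)
        assert variance_reduction(model) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_injected_effect(self, small_layout):
        """Adding a genuine systematic effect never decreases the explained
        fraction in expectation (checked over 20 seeds)."""
        lows, highs = [], []
        for seed in range(20):
            for needle_sd, acc in ((0.0, lows), (0.5, highs)):
                params = GeneratorParams(layout=small_layout, seed=300 + seed, noise_sd=0.3,
                                         needle_sd=needle_sd, subarray_sd=0,
                                         row_gradient=0, col_gradient=0,
                                         row_jitter=0, col_jitter=0, artifact_fraction=(0, 0),
                                         n_reactive=20, n_nonreactive_panel=15, n_secondary_binders=10)
                exp = generate_experiment(params)
                ctr = exp.design[exp.design["control_class"] != "experimental"].copy()
                from rapmad.normalization import log2_transform as lt
                raw = exp.incubation["array1"].data["raw_intensity"].to_numpy()
                ctr["log_intensity"] = lt(raw)[ctr.index]
                acc.append(variance_reduction(fit_effects_model(ctr)))
        assert np.mean(highs) > np.mean(lows)
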