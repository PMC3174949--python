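"""Shared fixtures: one synthetic six-slide experiment, its on-disk form,
and one full pipeline run, computed once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from rapmad.layout import ArrayLayout
from rapmad.pipeline import PipelineConfig, normalize_slide, run_pipeline, train_qc_classifier
from rapmad.synthetic import GeneratorParams, generate_experiment, expected_truth

#: Fixture seed for the reference experiment used throughout the suite.
EXPERIMENT_SEED = 1


@pytest.fixture(scope="session")
def experiment():
    """The reference six-slide synthetic experiment, in memory."""
    return generate_experiment(GeneratorParams(seed=EXPERIMENT_SEED))


@pytest.fixture(scope="session")
def experiment_dir(experiment, tmp_path_factory):
    """The reference experiment written as GPR files + manifest + truth."""
    out = tmp_path_factory.mktemp("experiment")
    generate_experiment(GeneratorParams(seed=EXPERIMENT_SEED), out_dir=out)
    truth = expected_truth(experiment.truth)
    pd.DataFrame({"peptide_id": truth.index, "expected_reactive": truth.values}).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    return out


@pytest.fixture(scope="session")
def normalized_high(experiment):
    """Per-spot normalized frame + effects model for the batch-1 high slide."""
    return normalize_slide(experiment.incubation["array3"], experiment.annotation)


@pytest.fixture(scope="session")
def bundle(experiment_dir):
    """Full pipeline run on the reference experiment, with evaluation."""
    cfg = PipelineConfig(
        manifest="manifest.csv",
        control_annotation="controls.csv",
        truth="truth.tsv",
        bootstrap_n=200,
        seed=7,
    )
    return run_pipeline(cfg, base_dir=experiment_dir)


@pytest.fixture(scope="session")
def qc_classifier(tmp_path_factory):
    """Reliability classifier trained on two historic slides (separate seed)."""
    out = tmp_path_factory.mktemp("historic")
    generate_experiment(GeneratorParams(seed=99), out_dir=out)
    pd.DataFrame(
        {
            "gpr_path": ["array3.gpr", "array6.gpr"],
            "scatterlight_path": ["array3_scatterlight.gpr", "array6_scatterlight.gpr"],
        }
    ).to_csv(out / "hist_manifest.csv", index=False)
    from rapmad.synthetic import GeneratorParams as GP

    exp = generate_experiment(GP(seed=99))
    return train_qc_classifier("hist_manifest.csv", exp.annotation, base_dir=out, n_trees=200, seed=3)


@pytest.fixture
def small_layout():
    """A 1200-spot layout for cheap constructions."""
    return ArrayLayout(n_subarrays=3, grid_rows=2, grid_cols=2, rows_per_block=10, cols_per_block=10)
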