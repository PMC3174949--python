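"""Synthetic peptide-microarray experiments with known ground truth.

The generator emulates the study design the pipeline targets: six slides of
identical layout printed in two batches, where each batch contributes one
empty slide (diluent only — exposes direct secondary-antibody binding), one
slide incubated with plasma plus a low concentration of a spike-in antibody,
and one with a high concentration.  Per-spot log2 intensities follow the
additive model the normalization stage assumes,

    y = baseline + array + subarray + needle + row + column + peptide
        + reaction + artifact + eps,

with raw intensities 2**y, so the raw scale shows the heteroscedasticity
(variance growing with the mean) that motivates the binary-log transform.
Row and column systematic effects are smooth spatial gradients (a decline in
signal across the slide) plus per-level jitter; the model still treats them
as unordered factors.  Secondary binders react on every slide including the
empty ones; spiked reactive peptides react only on plasma slides, scaled by
the slide's concentration level; artifact spots receive large independent
perturbations and correlated aberrant features in both the incubation scan
and the scatterlight quality-control scan.  Everything is deterministic
under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from rapmad.errors import ConfigError, EvaluationError
from rapmad.gpr_io import (
    DEFAULT_INTENSITY_COLUMN,
    DEFAULT_SCATTERLIGHT_COLUMN,
    SpotTable,
    write_gpr,
)
from rapmad.layout import (
    ArrayLayout,
    ControlAnnotation,
    EXPERIMENTAL,
    build_design,
)


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for one synthetic experiment.

    Effect scales are in log2-intensity units.  Defaults describe the
    reference design: a 19200-spot slide with 10% controls, residual noise
    sd 0.45 (residual variance ~0.2), spatial gradients as the dominant
    systematic effects, 222 spiked reactive peptides (a contiguous tiled
    protein), a disjoint 171-peptide expected-nonreactive panel, 150
    secondary-antibody binders, and ~5% artifact spots.  The low and high
    spike effects differ by log2(3) ~ 1.6, mirroring the 1 vs 3 ng/ml
    concentration levels.
    """

    layout: ArrayLayout = ArrayLayout()
    seed: int = 0
    baseline: float = 8.0
    noise_sd: float = 0.45
    peptide_sd: float = 0.5
    needle_sd: float = 0.15
    subarray_sd: float = 0.10
    array_sd: float = 0.15
    batch_offset_sd: float = 0.30
    row_gradient: float = 1.5
    row_jitter: float = 0.15
    col_gradient: float = 1.5
    col_jitter: float = 0.15
    n_reactive: int = 222
    n_nonreactive_panel: int = 171
    spike_low: float = 1.5
    spike_high: float = 3.1
    n_secondary_binders: int = 150
    binder_effect: float = 3.0
    positive_control_effect: float = 4.0
    process_control_effect: float = 2.0
    artifact_fraction: tuple = (0.04, 0.06)  # per print batch
    artifact_magnitude: float = 4.0  # in multiples of noise_sd
    flagged_fraction: float = 0.0
    control_fractions: Optional[dict] = None
    control_peptides: Optional[dict] = None

    def __post_init__(self):
        for name in ("noise_sd", "peptide_sd", "needle_sd", "subarray_sd", "array_sd",
                     "batch_offset_sd", "row_jitter", "col_jitter", "artifact_magnitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for f in self.artifact_fraction:
            if not (0.0 <= f <= 1.0):
                raise ConfigError("artifact fractions must lie in [0, 1]")
        if self.n_reactive < 0 or self.n_secondary_binders < 0 or self.n_nonreactive_panel < 0:
            raise ConfigError("peptide counts must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of a generated experiment."""

    peptides: pd.DataFrame  # peptide_id, control_class, is_reactive, is_secondary_binder, in_nonreactive_panel
    spots: dict  # array_id -> DataFrame(block, row, col, is_artifact)
    effects: dict  # factor -> {level: injected effect}; plus per-array offsets
    params: GeneratorParams


@dataclass
class SyntheticExperiment:
    """A complete generated slide set plus its ground truth."""

    manifest: pd.DataFrame
    design: pd.DataFrame
    annotation: ControlAnnotation
    incubation: dict  # array_id -> SpotTable
    scatterlight: dict  # array_id -> SpotTable
    truth: TruthTable


def _slide_plan() -> list[tuple[str, int, str, Optional[str]]]:
    """(array_id, print_batch, role, spike level) for the six-slide design."""
    plan = []
    i = 0
    for batch in (1, 2):
        for role, level in (("empty", None), ("sample", "low"), ("sample", "high")):
            i += 1
            plan.append((f"array{i}", batch, role, level))
    return plan


def generate_experiment(params: GeneratorParams = GeneratorParams(), out_dir=None) -> SyntheticExperiment:
    """Generate the six-slide experiment (2 batches x empty/low/high).

    When ``out_dir`` is given, GPR files (incubation + scatterlight), the
    slide manifest, the control annotation and the truth tables are written
    there; the manifest paths then point at the written files.
    """
    lay = params.layout
    design, annotation = build_design(lay, params.control_fractions, params.control_peptides)
    ss = np.random.SeedSequence(params.seed)
    rng_struct, *slide_seeds = ss.spawn(1 + 6)
    rng = np.random.default_rng(rng_struct)

    # --- shared structure: systematic effects and peptide identities
    needle_eff = rng.normal(0.0, params.needle_sd, lay.blocks_per_subarray)
    needle_eff -= needle_eff.mean()
    sub_eff = rng.normal(0.0, params.subarray_sd, lay.n_subarrays)
    sub_eff -= sub_eff.mean()
    nR, nC = lay.n_global_rows, lay.n_global_cols
    ramp_r = params.row_gradient * (0.5 - (np.arange(nR)) / max(nR - 1, 1))
    row_eff = ramp_r + rng.normal(0.0, params.row_jitter, nR)
    row_eff -= row_eff.mean()
    ramp_c = params.col_gradient * (0.5 - (np.arange(nC)) / max(nC - 1, 1))
    col_eff = ramp_c + rng.normal(0.0, params.col_jitter, nC)
    col_eff -= col_eff.mean()
    batch_off = rng.normal(0.0, params.batch_offset_sd, 2)

    exp_ids = sorted(design.loc[design["control_class"] == EXPERIMENTAL, "peptide_id"].unique())
    ctrl_ids = sorted(design.loc[design["control_class"] != EXPERIMENTAL, "peptide_id"].unique())
    n_exp = len(exp_ids)
    if params.n_reactive + params.n_nonreactive_panel + params.n_secondary_binders > n_exp:
        raise ConfigError("reactive + panel + binder counts exceed experimental peptides")

    # contiguous tiling blocks for the spiked protein and the non-reactive panel
    reactive = set(exp_ids[: params.n_reactive])
    panel = set(exp_ids[params.n_reactive : params.n_reactive + params.n_nonreactive_panel])
    pool = [p for p in exp_ids if p not in reactive]
    binders = set(rng.choice(pool, size=params.n_secondary_binders, replace=False)) if params.n_secondary_binders else set()

    pep_eff = {p: rng.normal(0.0, params.peptide_sd) for p in exp_ids}
    for p in ctrl_ids:
        pep_eff[p] = 0.0

    cls = design["control_class"].to_numpy()
    pid = design["peptide_id"].to_numpy()
    base_pep = np.array([pep_eff[p] for p in pid])
    is_reactive_spot = np.isin(pid, list(reactive))
    is_binder_spot = np.isin(pid, list(binders)) | (cls == "secondary_antibody")
    is_positive = cls == "positive"
    is_process = cls == "process"

    systematic = (
        sub_eff[design["subarray"].to_numpy() - 1]
        + needle_eff[design["needle"].to_numpy() - 1]
        + row_eff[design["global_row"].to_numpy() - 1]
        + col_eff[design["global_col"].to_numpy() - 1]
    )

    plan = _slide_plan()
    incubation: dict[str, SpotTable] = {}
    scatterlight: dict[str, SpotTable] = {}
    spot_truth: dict[str, pd.DataFrame] = {}
    array_offsets: dict[str, float] = {}
    n_spots = len(design)

    for (array_id, batch, role, level), child in zip(plan, slide_seeds):
        srng = np.random.default_rng(child)
        a_off = batch_off[batch - 1] + srng.normal(0.0, params.array_sd)
        array_offsets[array_id] = float(a_off)

        y = params.baseline + a_off + systematic + base_pep
        y = y + np.where(is_binder_spot, params.binder_effect, 0.0)
        y = y + np.where(is_process, params.process_control_effect, 0.0)
        if role == "sample":
            spike = params.spike_low if level == "low" else params.spike_high
            y = y + np.where(is_reactive_spot, spike, 0.0)
            y = y + np.where(is_positive, params.positive_control_effect, 0.0)
        eps = srng.normal(0.0, params.noise_sd, n_spots)
        frac = params.artifact_fraction[batch - 1]
        n_art = int(round(frac * n_spots))
        art_idx = srng.choice(n_spots, size=n_art, replace=False) if n_art else np.array([], dtype=int)
        is_art = np.zeros(n_spots, dtype=bool)
        is_art[art_idx] = True
        sign = srng.choice([-1.0, 1.0], size=n_spots)
        delta = np.where(is_art, sign * params.artifact_magnitude * params.noise_sd, 0.0)
        y_final = y + eps + delta
        raw = np.round(np.power(2.0, y_final), 1)

        flags = np.zeros(n_spots, dtype=int)
        if params.flagged_fraction > 0:
            n_fl = int(round(params.flagged_fraction * n_spots))
            flags[srng.choice(n_spots, size=n_fl, replace=False)] = -100

        f635_sd = raw * 0.08 * (1.0 + srng.normal(0.0, 0.2, n_spots)).clip(0.2)
        f635_sd = np.where(is_art, f635_sd * 6.0, f635_sd)
        b635 = np.abs(srng.normal(50.0, 5.0, n_spots))
        dia = srng.normal(120.0, 5.0, n_spots)
        dia = np.where(is_art, dia + sign * srng.normal(35.0, 8.0, n_spots), dia)

        inc = pd.DataFrame(
            {
                "block": design["block"],
                "row": design["row"],
                "col": design["col"],
                "peptide_id": design["peptide_id"],
                "raw_intensity": raw,
                "flag": flags,
                "F635 SD": np.round(f635_sd, 2),
                "B635 Mean": np.round(b635, 2),
                "Dia.": np.round(dia, 1),
            }
        )
        incubation[array_id] = SpotTable(inc, channel="635", intensity_column=DEFAULT_INTENSITY_COLUMN,
                                         header={"Type": "GenePix Results 3", "ArrayID": array_id})

        sl_raw = np.round(np.power(2.0, 7.0 + srng.normal(0.0, 0.2, n_spots)), 1)
        sl_sd = np.abs(srng.normal(40.0, 8.0, n_spots))
        sl_sd = np.where(is_art, sl_sd * 8.0, sl_sd)
        circ = np.clip(srng.normal(0.95, 0.02, n_spots) - np.where(is_art, 0.3, 0.0), 0.0, 1.0)
        sl = pd.DataFrame(
            {
                "block": design["block"],
                "row": design["row"],
                "col": design["col"],
                "peptide_id": design["peptide_id"],
                "raw_intensity": sl_raw,
                "flag": 0,
                "F532 SD": np.round(sl_sd, 2),
                "Dia.": np.round(dia + srng.normal(0.0, 2.0, n_spots), 1),
                "Circularity": np.round(circ, 3),
            }
        )
        scatterlight[array_id] = SpotTable(sl, channel="532", intensity_column=DEFAULT_SCATTERLIGHT_COLUMN,
                                           header={"Type": "GenePix Results 3", "ArrayID": array_id, "Scan": "scatterlight"})
        spot_truth[array_id] = pd.DataFrame(
            {"block": design["block"], "row": design["row"], "col": design["col"], "is_artifact": is_art}
        )

    all_ids = sorted(set(pid))
    pep_truth = pd.DataFrame(
        {
            "peptide_id": all_ids,
            "control_class": [annotation.class_of(p) for p in all_ids],
            "is_reactive": [p in reactive for p in all_ids],
            "is_secondary_binder": [p in binders or annotation.class_of(p) == "secondary_antibody" for p in all_ids],
            "in_nonreactive_panel": [p in panel for p in all_ids],
            "peptide_effect": [pep_eff[p] for p in all_ids],
        }
    )

    manifest = pd.DataFrame(
        [
            {
                "array_id": aid,
                "gpr_path": "",
                "scatterlight_path": "",
                "role": role,
                "print_batch": batch,
                "spike_in_level": level if level else "",
            }
            for aid, batch, role, level in plan
        ]
    )

    effects = {
        "subarray": {i + 1: float(v) for i, v in enumerate(sub_eff)},
        "needle": {i + 1: float(v) for i, v in enumerate(needle_eff)},
        "row": {i + 1: float(v) for i, v in enumerate(row_eff)},
        "column": {i + 1: float(v) for i, v in enumerate(col_eff)},
        "array": array_offsets,
    }
    truth = TruthTable(peptides=pep_truth, spots=spot_truth, effects=effects, params=params)
    exp = SyntheticExperiment(
        manifest=manifest, design=design, annotation=annotation,
        incubation=incubation, scatterlight=scatterlight, truth=truth,
    )
    if out_dir is not None:
        _write_experiment(exp, Path(out_dir))
    return exp


def _write_experiment(exp: SyntheticExperiment, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for aid in exp.incubation:
        gpr = out_dir / f"{aid}.gpr"
        sl = out_dir / f"{aid}_scatterlight.gpr"
        write_gpr(exp.incubation[aid], gpr)
        write_gpr(exp.scatterlight[aid], sl)
        m = exp.manifest["array_id"] == aid
        exp.manifest.loc[m, "gpr_path"] = gpr.name
        exp.manifest.loc[m, "scatterlight_path"] = sl.name
    exp.manifest.to_csv(out_dir / "manifest.csv", index=False)
    exp.annotation.to_csv(out_dir / "controls.csv")
    exp.truth.peptides.to_csv(out_dir / "truth_peptides.tsv", sep="\t", index=False)
    for aid, st in exp.truth.spots.items():
        st.to_csv(out_dir / f"truth_spots_{aid}.tsv", sep="\t", index=False)


def expected_truth(truth: TruthTable) -> pd.Series:
    """Evaluation truth: True for spiked reactive peptides, False for the
    expected-nonreactive panel; all other peptides are out of the panel."""
    t = truth.peptides
    mask = t["is_reactive"] | t["in_nonreactive_panel"]
    return pd.Series(t.loc[mask, "is_reactive"].to_numpy(), index=t.loc[mask, "peptide_id"]).astype(bool)


def truth_metrics(calls: pd.DataFrame, truth: TruthTable) -> dict:
    """Oracle confusion matrix computed directly from the truth flags.

    Independent of :func:`rapmad.pipeline.evaluate`: plain counting over the
    truth table.  ``calls`` is a call table indexed by peptide_id with
    columns ``reactive`` and ``excluded_reason``.
    """
    t = truth.peptides.set_index("peptide_id")
    unknown = [p for p in calls.index if p not in t.index]
    if unknown:
        raise EvaluationError(f"call table has peptides missing from truth: {unknown[:5]}")
    tp = fp = tn = fn = 0
    for pid, rec in t.iterrows():
        if not (rec["is_reactive"] or rec["in_nonreactive_panel"]):
            continue
        if pid not in calls.index:
            continue
        row = calls.loc[pid]
        if isinstance(row.get("excluded_reason"), str) and row.get("excluded_reason"):
            continue
        called = bool(row["reactive"])
        if rec["is_reactive"]:
            tp, fn = (tp + 1, fn) if called else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if called else (fp, tn + 1)
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
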