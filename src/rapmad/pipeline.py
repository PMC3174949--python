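"""Pipeline orchestration: normalize, QC, exclude secondary binders, call
signals, evaluate.

The stages run in a fixed order per slide: read the GPR table, binary-log
transform, fit the control-peptide effects model and correct every spot,
optionally score spot reliability with a trained classifier, aggregate the
subarray replicates per peptide (reliability-weighted), then per print
batch: fit the secondary-binding mixture on that batch's empty slide and
exclude the flagged peptides from the batch's sample slides, fit the
signal-call mixture on each sample slide and call peptides whose noise
exceedance probability falls below alpha.  When a truth table is supplied,
calls are scored as sensitivity/specificity/accuracy with percentile
bootstrap confidence intervals (resampling peptides within each truth
class and re-thresholding against the fitted cutoff).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from rapmad.errors import ConfigError, DataError, EvaluationError, StateError
from rapmad import qc as qc_mod
from rapmad.gpr_io import (
    DEFAULT_INTENSITY_COLUMN,
    DEFAULT_SCATTERLIGHT_COLUMN,
    SpotTable,
    join_scans,
    read_gpr,
)
from rapmad.layout import ArrayLayout, ControlAnnotation, EXPERIMENTAL, address_frame
from rapmad.mixtures import (
    MixtureFit,
    em_fit,
    exceedance_probs,
    init_from_controls,
    noise_quantile,
)
from rapmad.normalization import correct, fit_effects_model, log2_transform

log = logging.getLogger(__name__)

SECONDARY_BINDER = "secondary_binder"
ALL_UNRELIABLE = "all_replicates_unreliable"


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline` (YAML-serializable)."""

    manifest: str = "manifest.csv"
    control_annotation: str = "controls.csv"
    layout: ArrayLayout = field(default_factory=ArrayLayout)
    intensity_column: str = DEFAULT_INTENSITY_COLUMN
    scatterlight_column: str = DEFAULT_SCATTERLIGHT_COLUMN
    alpha_secondary: float = 0.05
    alpha_signal: float = 0.05
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    qc_enabled: bool = False
    qc_classifier: Optional[str] = None
    exclude_flagged: bool = False
    excluded_policy: str = "omit"  # or "noncall"
    truth: Optional[str] = None  # TSV with peptide_id, expected_reactive
    bootstrap_n: int = 1000
    bootstrap_level: float = 0.95
    seed: int = 0
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        lay = raw.pop("layout", None)
        cfg = cls(**raw)
        if lay:
            cfg.layout = ArrayLayout(**lay)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class EvaluationResult:
    """Confusion counts, the three summary metrics, and bootstrap CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ci: dict = field(default_factory=dict)  # metric -> (lower, upper)
    n_bootstrap: int = 0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_bootstrap": self.n_bootstrap,
        }


def normalize_slide(
    table: SpotTable,
    annotation: ControlAnnotation,
    layout: ArrayLayout = ArrayLayout(),
    exclude_flagged: bool = False,
) -> tuple[pd.DataFrame, "object"]:
    """Log-transform one slide and remove its systematic effects.

    Returns the per-spot frame (with address columns, control class,
    ``log_intensity`` and ``normalized``) and the fitted effects model.
    Spots with negative GenePix flags are dropped first when
    ``exclude_flagged`` is set; otherwise they are retained and left for
    the QC stage to judge.
    """
    df = table.data.copy()
    if exclude_flagged:
        df = df[df["flag"] >= 0].reset_index(drop=True)
    addr = address_frame(layout, df["block"], df["row"], df["col"])
    df = pd.concat([df.reset_index(drop=True), addr], axis=1)
    df["control_class"] = df["peptide_id"].map(lambda p: annotation.class_of(p))
    df["log_intensity"] = log2_transform(df["raw_intensity"].to_numpy())
    controls = df[df["control_class"] != EXPERIMENTAL]
    model = fit_effects_model(controls)
    df["normalized"] = correct(df, model)
    return df, model


def score_reliability(
    normalized: pd.DataFrame,
    incubation: SpotTable,
    scatterlight: SpotTable,
    classifier: qc_mod.ReliabilityClassifier,
) -> pd.DataFrame:
    """Attach predicted reliability columns to a normalized per-spot frame."""
    joined = join_scans(incubation, scatterlight)
    feats = joined.data.drop(columns=[c for c in ("sequence",) if c in joined.data.columns])
    pred = qc_mod.predict_reliability(classifier, feats)
    keys = ["block", "row", "col"]
    pred = pd.concat([joined.data[keys], pred.reset_index(drop=True)], axis=1)
    return normalized.merge(pred, on=keys, how="left")


def aggregate_slide(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide reliability-weighted aggregation of one slide."""
    return qc_mod.aggregate_table(normalized, value_column="normalized")


def _control_values(per_spot: pd.DataFrame, cls: str) -> np.ndarray:
    vals = per_spot.loc[per_spot["control_class"] == cls, "normalized"].to_numpy(dtype=float)
    if vals.size < 2:
        raise DataError(f"fewer than 2 normalized control spots of class {cls!r}")
    return vals


def detect_secondary_binders(
    peptide_values: pd.Series,
    annotation: ControlAnnotation,
    alpha: float = 0.05,
    init_nonreactive: Optional[Sequence[float]] = None,
    init_reactive: Optional[Sequence[float]] = None,
    em_tol: float = 1e-8,
    em_max_iter: int = 1000,
) -> tuple[set, MixtureFit]:
    """Identify peptides reacting directly with the secondary antibody.

    Fitted on the empty slide's per-peptide normalized values: the mixture
    is initialized from the negative controls (non-reactive group) and the
    secondary-antibody controls (reactive group); experimental peptides
    whose noise exceedance probability falls below ``alpha`` are returned
    as the exclusion set for every sample slide of the same print batch.
    """
    if init_nonreactive is None:
        init_nonreactive = [v for p, v in peptide_values.items() if annotation.class_of(p) == "negative"]
    if init_reactive is None:
        init_reactive = [v for p, v in peptide_values.items() if annotation.class_of(p) == "secondary_antibody"]
    init = init_from_controls(init_nonreactive, init_reactive)
    fit = em_fit(peptide_values.to_numpy(dtype=float), init, tol=em_tol, max_iter=em_max_iter)
    p_hat = exceedance_probs(peptide_values.to_numpy(dtype=float), fit)
    flagged = peptide_values.index[(p_hat < alpha)]
    excluded = {p for p in flagged if annotation.class_of(p) == EXPERIMENTAL}
    return excluded, fit


def call_signals(
    peptide_values: pd.Series,
    exclusions: set,
    annotation: ControlAnnotation,
    alpha: float = 0.05,
    init_reactive: Optional[Sequence[float]] = None,
    init_nonreactive: Optional[Sequence[float]] = None,
    qc_excluded: Optional[set] = None,
    em_tol: float = 1e-8,
    em_max_iter: int = 1000,
) -> tuple[pd.DataFrame, MixtureFit]:
    """Signal call on one sample slide's per-peptide normalized values.

    Excluded peptides (secondary binders from the batch's empty slide, and
    peptides whose replicates were all unreliable) are removed before the
    mixture fit and carry ``excluded_reason`` instead of a call.  The
    mixture is initialized from the positive controls (reaction expected)
    and negative controls; a peptide is reactive iff its exceedance
    probability against the fitted noise component is strictly below
    ``alpha``.  Returns the call table (indexed by peptide_id) and the fit.
    """
    qc_excluded = qc_excluded or set()
    if init_reactive is None:
        init_reactive = [v for p, v in peptide_values.items() if annotation.class_of(p) == "positive"]
    if init_nonreactive is None:
        init_nonreactive = [v for p, v in peptide_values.items() if annotation.class_of(p) == "negative"]
    init = init_from_controls(init_nonreactive, init_reactive)
    mask = ~peptide_values.index.isin(exclusions | qc_excluded)
    kept = peptide_values[mask]
    fit = em_fit(kept.to_numpy(dtype=float), init, tol=em_tol, max_iter=em_max_iter)
    p_hat = exceedance_probs(kept.to_numpy(dtype=float), fit)

    # QC-excluded peptides have no aggregated value but still get a row
    index = peptide_values.index.union(pd.Index(sorted(qc_excluded)), sort=False)
    calls = pd.DataFrame(index=index)
    calls["normalized_intensity"] = peptide_values.reindex(index)
    calls["control_class"] = [annotation.class_of(p) for p in calls.index]
    calls["secondary_binder"] = calls.index.isin(exclusions)
    calls["p_hat"] = np.nan
    calls.loc[kept.index, "p_hat"] = p_hat
    calls["reactive"] = False
    calls.loc[kept.index, "reactive"] = p_hat < alpha
    calls["excluded_reason"] = ""
    calls.loc[calls.index.isin(exclusions), "excluded_reason"] = SECONDARY_BINDER
    calls.loc[calls.index.isin(qc_excluded), "excluded_reason"] = ALL_UNRELIABLE
    calls.index.name = "peptide_id"
    return calls, fit


def _metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / (tp + tn + fp + fn) if tp + tn + fp + fn else np.nan
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def evaluate(
    calls: pd.DataFrame,
    truth: Union[pd.Series, dict],
    excluded_policy: str = "omit",
) -> EvaluationResult:
    """Score a call table against expected reactivity.

    ``truth`` maps peptide_id -> True (expected reactive) / False (expected
    non-reactive) and must cover every evaluated peptide.  Excluded peptides
    are omitted from the denominators by default (``"omit"``); with
    ``"noncall"`` they are counted as negative calls instead.
    """
    if excluded_policy not in ("omit", "noncall"):
        raise ConfigError(f"unknown excluded_policy {excluded_policy!r}")
    truth = pd.Series(truth).astype(bool)
    missing = [p for p in truth.index if p not in calls.index]
    if missing:
        raise EvaluationError(f"truth peptides missing from the call table: {missing[:5]}")
    evaluated = calls[calls.index.isin(truth.index)]
    tp = fp = tn = fn = 0
    for pid, row in evaluated.iterrows():
        is_excluded = bool(row["excluded_reason"])
        if is_excluded and excluded_policy == "omit":
            continue
        called = bool(row["reactive"]) and not is_excluded
        if truth[pid]:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    m = _metrics(tp, fp, tn, fn)
    return EvaluationResult(tp=tp, fp=fp, tn=tn, fn=fn, **m)


def bootstrap_ci(
    metric: Union[str, Callable],
    reactive_values: Sequence[float],
    nonreactive_values: Sequence[float],
    fit: MixtureFit,
    alpha: float = 0.05,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    refit: bool = False,
    init: Optional[MixtureFit] = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for an evaluation metric.

    Peptide values are resampled with replacement within each truth class;
    calls are recomputed against the fixed fitted noise cutoff (or, with
    ``refit``, by re-running EM on each resample, initialized from
    ``init``), and the metric recomputed.  Deterministic under ``seed``.
    """
    if B < 2:
        raise ConfigError(f"bootstrap needs B >= 2, got {B}")
    if not (0.0 < level < 1.0):
        raise ConfigError("bootstrap level must lie in (0, 1)")
    pos = np.asarray(reactive_values, dtype=float)
    neg = np.asarray(nonreactive_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both truth classes must be non-empty for the bootstrap")
    rng = np.random.default_rng(seed)
    if isinstance(metric, str):
        name = metric
        metric_fn = lambda tp, fp, tn, fn: _metrics(tp, fp, tn, fn)[name]
    else:
        metric_fn = metric

    stats_out = np.empty(B)
    if not refit:
        q = noise_quantile(fit, alpha)
        pos_idx = rng.integers(0, pos.size, size=(B, pos.size))
        neg_idx = rng.integers(0, neg.size, size=(B, neg.size))
        tp = (pos[pos_idx] > q).sum(axis=1)
        fn = pos.size - tp
        fp = (neg[neg_idx] > q).sum(axis=1)
        tn = neg.size - fp
        for b in range(B):
            stats_out[b] = metric_fn(int(tp[b]), int(fp[b]), int(tn[b]), int(fn[b]))
    else:
        if init is None:
            raise ConfigError("refit bootstrap needs the initial mixture parameters")
        for b in range(B):
            rp = rng.choice(pos, size=pos.size, replace=True)
            rn = rng.choice(neg, size=neg.size, replace=True)
            f = em_fit(np.concatenate([rp, rn]), init)
            q = noise_quantile(f, alpha)
            tp = int((rp > q).sum())
            fp = int((rn > q).sum())
            stats_out[b] = metric_fn(tp, fp, neg.size - fp, pos.size - tp)
    lo = float(np.quantile(stats_out, (1 - level) / 2))
    hi = float(np.quantile(stats_out, 1 - (1 - level) / 2))
    return lo, hi


def attach_bootstrap(
    result: EvaluationResult,
    calls: pd.DataFrame,
    truth: pd.Series,
    fit: MixtureFit,
    alpha: float,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EvaluationResult:
    """Fill the CI slots of an evaluation result from the call table."""
    truth = pd.Series(truth).astype(bool)
    ev = calls[calls.index.isin(truth.index) & (calls["excluded_reason"] == "")]
    pos = ev.loc[[p for p in ev.index if truth[p]], "normalized_intensity"].to_numpy()
    neg = ev.loc[[p for p in ev.index if not truth[p]], "normalized_intensity"].to_numpy()
    for metric in ("sensitivity", "specificity", "accuracy"):
        result.ci[metric] = bootstrap_ci(metric, pos, neg, fit, alpha=alpha, B=B, level=level, seed=seed)
    result.n_bootstrap = B
    return result


def replicate_pivot(per_spot: pd.DataFrame) -> pd.DataFrame:
    """Experimental peptides x subarrays matrix of normalized values."""
    exp = per_spot[per_spot["control_class"] == EXPERIMENTAL]
    piv = exp.pivot_table(index="peptide_id", columns="subarray", values="normalized", aggfunc="mean")
    piv.index.name = "peptide_id"
    return piv


def train_qc_classifier(
    manifest_path,
    annotation: ControlAnnotation,
    layout: ArrayLayout = ArrayLayout(),
    intensity_column: str = DEFAULT_INTENSITY_COLUMN,
    scatterlight_column: str = DEFAULT_SCATTERLIGHT_COLUMN,
    band_level: float = 0.95,
    band: str = "prediction",
    n_trees: int = 500,
    seed: int = 0,
    base_dir: Optional[Path] = None,
) -> qc_mod.ReliabilityClassifier:
    """Train the reliability classifier from historic slides.

    The manifest lists GPR/scatterlight pairs of slides with the same
    layout.  Each slide is normalized, its experimental peptides' subarray
    replicates are band-labeled, labels are joined with the spot features
    of both scans, classes are balanced, and one forest is trained on the
    pool of all slides.
    """
    base = Path(base_dir) if base_dir else Path(".")
    manifest = pd.read_csv(base / manifest_path)
    mdir = (base / manifest_path).parent  # slide paths are manifest-relative
    feats_all, labels_all = [], []
    for rec in manifest.itertuples(index=False):
        inc = read_gpr(mdir / rec.gpr_path, intensity_column=intensity_column)
        sl = read_gpr(mdir / rec.scatterlight_path, intensity_column=scatterlight_column)
        per_spot, _ = normalize_slide(inc, annotation, layout=layout)
        piv = replicate_pivot(per_spot)
        lab = qc_mod.band_label(piv, level=band_level, band=band)
        joined = join_scans(inc, sl)
        addr = address_frame(layout, joined.data["block"], joined.data["row"], joined.data["col"])
        jd = pd.concat([joined.data, addr[["subarray"]]], axis=1)
        merged = jd.merge(lab, on=["peptide_id", "subarray"], how="inner")
        feats_all.append(merged.drop(columns=["label", "source", "probability_reliable"]))
        labels_all.append(merged["label"])
    features = pd.concat(feats_all, ignore_index=True)
    labels = pd.concat(labels_all, ignore_index=True).to_numpy()
    return qc_mod.train_reliability_classifier(features, labels, n_trees=n_trees, seed=seed)


def run_pipeline(config: PipelineConfig, base_dir: Optional[Path] = None) -> dict:
    """Execute the full workflow described by ``config``.

    Returns a result bundle: per-sample-slide call tables, per-batch
    exclusion sets and mixture summaries, per-slide ANOVA tables, and (when
    a truth table is configured) evaluation results with bootstrap CIs.
    Writes TSV/JSON outputs when ``config.output_dir`` is set.
    """
    base = Path(base_dir) if base_dir else Path(".")
    manifest = pd.read_csv(base / config.manifest)
    mdir = (base / config.manifest).parent  # slide paths are manifest-relative
    required = {"array_id", "gpr_path", "role", "print_batch"}
    if not required.issubset(manifest.columns):
        raise ConfigError(f"manifest needs columns {sorted(required)}")
    annotation = ControlAnnotation.from_csv(base / config.control_annotation)

    classifier = None
    if config.qc_enabled and config.qc_classifier:
        classifier = qc_mod.ReliabilityClassifier.load(base / config.qc_classifier)

    slides: dict[str, dict] = {}
    stage = "read/normalize"
    try:
        for rec in manifest.itertuples(index=False):
            aid = str(rec.array_id)
            table = read_gpr(mdir / rec.gpr_path, intensity_column=config.intensity_column)
            per_spot, model = normalize_slide(
                table, annotation, layout=config.layout, exclude_flagged=config.exclude_flagged
            )
            qc_excluded: set = set()
            if classifier is not None and getattr(rec, "scatterlight_path", ""):
                stage = "qc"
                sl = read_gpr(mdir / rec.scatterlight_path, intensity_column=config.scatterlight_column)
                per_spot = score_reliability(per_spot, table, sl, classifier)
                stage = "read/normalize"
            agg = aggregate_slide(per_spot)
            qc_excluded = set(agg.index[agg["excluded"]])
            slides[aid] = {
                "role": str(rec.role),
                "batch": int(rec.print_batch),
                "level": str(getattr(rec, "spike_in_level", "") or ""),
                "per_spot": per_spot,
                "model": model,
                "values": agg.loc[~agg["excluded"], "value"],
                "qc_excluded": qc_excluded,
            }
    except Exception as e:
        raise type(e)(f"[stage: {stage}] {e}") from e

    # secondary-binder exclusion per print batch
    exclusions: dict[int, set] = {}
    secondary_fits: dict[int, MixtureFit] = {}
    for batch in sorted({s["batch"] for s in slides.values()}):
        empties = [aid for aid, s in slides.items() if s["batch"] == batch and s["role"] == "empty"]
        if not empties:
            log.warning("print batch %s has no empty slide; skipping secondary-binder "
                        "exclusion (increased false-positive risk)", batch)
            exclusions[batch] = set()
            continue
        s = slides[empties[0]]
        excl, fit = detect_secondary_binders(
            s["values"], annotation, alpha=config.alpha_secondary,
            init_nonreactive=_control_values(s["per_spot"], "negative"),
            init_reactive=_control_values(s["per_spot"], "secondary_antibody"),
            em_tol=config.em_tol, em_max_iter=config.em_max_iter,
        )
        exclusions[batch] = excl
        secondary_fits[batch] = fit

    truth = None
    if config.truth:
        tdf = pd.read_csv(base / config.truth, sep="\t")
        truth = pd.Series(tdf["expected_reactive"].to_numpy(), index=tdf["peptide_id"]).astype(bool)

    calls: dict[str, pd.DataFrame] = {}
    signal_fits: dict[str, MixtureFit] = {}
    evaluations: dict[str, EvaluationResult] = {}
    for aid, s in slides.items():
        if s["role"] != "sample":
            continue
        ct, fit = call_signals(
            s["values"], exclusions.get(s["batch"], set()), annotation,
            alpha=config.alpha_signal,
            init_reactive=_control_values(s["per_spot"], "positive"),
            init_nonreactive=_control_values(s["per_spot"], "negative"),
            qc_excluded=s["qc_excluded"],
            em_tol=config.em_tol, em_max_iter=config.em_max_iter,
        )
        calls[aid] = ct
        signal_fits[aid] = fit
        if truth is not None:
            res = evaluate(ct, truth, excluded_policy=config.excluded_policy)
            res = attach_bootstrap(res, ct, truth, fit, config.alpha_signal,
                                   B=config.bootstrap_n, level=config.bootstrap_level, seed=config.seed)
            evaluations[aid] = res

    bundle = {
        "config": config.to_dict(),
        "slides": {aid: {k: s[k] for k in ("role", "batch", "level", "qc_excluded")} for aid, s in slides.items()},
        "models": {aid: s["model"] for aid, s in slides.items()},
        "values": {aid: s["values"] for aid, s in slides.items()},
        "exclusions": exclusions,
        "secondary_fits": secondary_fits,
        "calls": calls,
        "signal_fits": signal_fits,
        "evaluations": evaluations,
    }
    if config.output_dir:
        _write_bundle(bundle, base / config.output_dir)
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for aid, ct in bundle["calls"].items():
        ct.to_csv(out / f"calls_{aid}.tsv", sep="\t")
    for aid, model in bundle["models"].items():
        model.anova.to_csv(out / f"anova_{aid}.tsv", sep="\t", index=False)
    mix = {
        "secondary": {str(b): f.summary() for b, f in bundle["secondary_fits"].items()},
        "signal": {aid: f.summary() for aid, f in bundle["signal_fits"].items()},
    }
    (out / "mixtures.json").write_text(json.dumps(mix, indent=2))
    (out / "exclusions.json").write_text(
        json.dumps({str(b): sorted(s) for b, s in bundle["exclusions"].items()}, indent=2)
    )
    if bundle["evaluations"]:
        (out / "evaluation.json").write_text(
            json.dumps({aid: r.to_dict() for aid, r in bundle["evaluations"].items()}, indent=2)
        )
    cfg = dict(bundle["config"])
    (out / "run_log.json").write_text(json.dumps(cfg, indent=2, default=str))
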