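"""Optional unreliable-spot detection and reliability-weighted aggregation.

Spots can be corrupted by effects no additive model captures — peptide decay,
dust, grid misalignment.  When historic slides with the same layout exist,
they supply automatic training labels: each peptide is replicated once per
subarray, so for every ordered pair of subarrays (a, b) the values of
subarray a are regressed on those of subarray b over all shared peptides,
and a spot is labeled unreliable when it falls outside the 95% regression
band in at least one of its partner regressions.  A random-forest classifier
is then trained on these labels — using every numeric column of the result
file plus every column of the matching scatterlight quality-control scan —
after class balancing by downsampling, and applied to new slides.  Replicate
aggregation discards predicted-unreliable spots and averages the remainder
weighted by their predicted probability of being reliable; peptides whose
replicates are all unreliable are excluded.

The whole stage is optional: with QC disabled every spot gets weight one and
aggregation reduces to the plain replicate mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from rapmad.errors import DataError, QCError

log = logging.getLogger(__name__)

#: Forest defaults: 500 trees, sqrt-of-feature-count subsampling.
DEFAULT_N_TREES = 500
MIN_TRAINING_SPOTS = 20

RELIABLE = "reliable"
UNRELIABLE = "unreliable"

#: Columns never used as classifier features.
_NON_FEATURES = {"peptide_id", "sequence"}


@dataclass
class ReliabilityClassifier:
    """A trained reliability ensemble plus the exact feature list it expects."""

    model: RandomForestClassifier
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)
    version: int = 1

    def save(self, path) -> None:
        joblib.dump({"version": self.version, "model": self.model,
                     "feature_names": self.feature_names, "metadata": self.metadata}, path)

    @classmethod
    def load(cls, path) -> "ReliabilityClassifier":
        blob = joblib.load(path)
        return cls(model=blob["model"], feature_names=blob["feature_names"],
                   metadata=blob["metadata"], version=blob["version"])


def _band_halfwidth(x: np.ndarray, s: float, n: int, level: float, kind: str) -> np.ndarray:
    xbar = x.mean()
    sxx = ((x - xbar) ** 2).sum()
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 2)
    lever = 1.0 / n + (x - xbar) ** 2 / sxx
    if kind == "prediction":
        lever = lever + 1.0
    return tcrit * s * np.sqrt(lever)


def band_label(
    replicates: pd.DataFrame,
    level: float = 0.95,
    band: str = "prediction",
    scale: str = "robust",
    partner_rule: str = "all",
) -> pd.DataFrame:
    """Label spots as reliable/unreliable from cross-subarray regressions.

    ``replicates`` is a peptides x subarrays frame of log intensities (index
    = peptide ids, one column per subarray).  For each subarray a and each
    partner b, a simple linear regression of a's values on b's values is fit
    over all shared peptides, and a's spot for a peptide is unreliable when
    it lies outside the ``level`` band in every partner regression
    (``partner_rule="all"``, the default: the spot is within the band of
    neither partner).  This keeps a spot from being flagged merely because
    one *partner* replicate is corrupt — a bad predictor value displaces
    that single regression's residual while the other partner clears the
    spot.  ``partner_rule="any"`` flags on a single outlying regression
    instead.

    ``band`` selects the band type: ``"prediction"`` (default; the band for
    a new observation) or ``"confidence"`` (band for the mean response,
    which is far narrower and flags most spots at realistic n).  ``scale``
    selects the residual scale estimate the band is built from:
    ``"robust"`` (default; normalized median absolute deviation, so the
    corrupt spots being hunted do not widen their own band) or
    ``"classical"`` (root mean squared residual).

    Returns a tidy frame with columns peptide_id, subarray, label, source,
    probability_reliable.
    """
    if band not in ("prediction", "confidence"):
        raise QCError(f"unknown band type {band!r}")
    if scale not in ("robust", "classical"):
        raise QCError(f"unknown scale estimator {scale!r}")
    if partner_rule not in ("all", "any"):
        raise QCError(f"unknown partner rule {partner_rule!r}")
    if not (0.0 < level < 1.0):
        raise QCError(f"band level must lie in (0,1), got {level}")
    subarrays = list(replicates.columns)
    if len(subarrays) < 3:
        raise QCError("band labeling needs >= 3 subarrays so each spot has >= 2 partner regressions")
    clean = replicates.dropna()
    if len(clean) < 10:
        raise QCError(f"only {len(clean)} shared peptides; need >= 10 per regression")
    n = len(clean)
    unreliable = pd.DataFrame(False, index=clean.index, columns=subarrays)
    for a in subarrays:
        y = clean[a].to_numpy(dtype=float)
        outside_masks = []
        for b in subarrays:
            if b == a:
                continue
            x = clean[b].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise QCError(f"degenerate regression: subarray {b} has zero variance")
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (intercept + slope * x)
            if scale == "robust":
                s = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
            else:
                rss = float(resid @ resid)
                s = np.sqrt(rss / (n - 2)) if n > 2 else 0.0
            if s == 0.0:
                # zero-width band (collinear bulk): any real residual is outside
                tol = 1e-8 * max(1.0, float(np.abs(y).max()))
                outside_masks.append(np.abs(resid) > tol)
                continue
            half = _band_halfwidth(x, s, n, level, band)
            outside_masks.append(np.abs(resid) > half)
        combined = np.logical_and.reduce(outside_masks) if partner_rule == "all" else np.logical_or.reduce(outside_masks)
        unreliable[a] = combined
    out = unreliable.reset_index().melt(id_vars=replicates.index.name or "index",
                                        var_name="subarray", value_name="_bad")
    out = out.rename(columns={replicates.index.name or "index": "peptide_id"})
    out["label"] = np.where(out["_bad"], UNRELIABLE, RELIABLE)
    out["source"] = "training-band"
    out["probability_reliable"] = np.where(out["_bad"], 0.0, 1.0)
    return out.drop(columns="_bad")


def balance_classes(labels: Sequence, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset: majority class downsampled
    without replacement to the minority size.  Deterministic under ``seed``."""
    lab = np.asarray(labels)
    classes, counts = np.unique(lab, return_counts=True)
    if len(classes) < 2:
        raise QCError("both reliability classes must be present to balance")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    picked = []
    for c in classes:
        idx = np.flatnonzero(lab == c)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        picked.append(idx)
    return np.sort(np.concatenate(picked))


def _clean_features(features: pd.DataFrame, feature_names: Optional[list[str]] = None) -> pd.DataFrame:
    X = features.drop(columns=[c for c in _NON_FEATURES if c in features.columns])
    X = X.select_dtypes(include=[np.number])
    if feature_names is None:
        constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
        if constant:
            log.info("dropping constant feature columns %s", constant)
            X = X.drop(columns=constant)
    else:
        missing = [c for c in feature_names if c not in X.columns]
        if missing:
            raise QCError(f"feature columns missing at prediction time: {missing}")
        X = X[feature_names]
    return X.fillna(X.median(numeric_only=True))


def train_reliability_classifier(
    features: pd.DataFrame,
    labels: Sequence,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    balance: bool = True,
) -> ReliabilityClassifier:
    """Train the random-forest reliability classifier.

    ``labels`` holds ``"reliable"``/``"unreliable"`` (or booleans, True =
    reliable) aligned with the feature rows.  Identifier and sequence
    columns are excluded, constant columns dropped, missing values median-
    imputed.  With ``balance`` the classes are downsampled to equal size
    first.  Out-of-bag accuracy is recorded in the metadata.
    """
    lab = np.asarray(labels)
    if lab.dtype == bool:
        lab = np.where(lab, RELIABLE, UNRELIABLE)
    X = _clean_features(features)
    if len(X) != len(lab):
        raise DataError("features and labels differ in length")
    idx = balance_classes(lab, seed=seed) if balance else np.arange(len(lab))
    if idx.size < MIN_TRAINING_SPOTS:
        raise QCError(f"only {idx.size} balanced training spots; need >= {MIN_TRAINING_SPOTS}")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        random_state=seed, n_jobs=1,
    )
    model.fit(X.iloc[idx], lab[idx])
    classes, counts = np.unique(lab[idx], return_counts=True)
    meta = {
        "n_trees": n_trees,
        "seed": seed,
        "class_balance": dict(zip(classes.tolist(), counts.astype(int).tolist())),
        "oob_accuracy": float(model.oob_score_),
    }
    return ReliabilityClassifier(model=model, feature_names=list(X.columns), metadata=meta)


def predict_reliability(clf: ReliabilityClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Per-spot probability of being reliable, plus the hard label.

    The feature frame must contain exactly the training feature columns;
    missing columns are an error, never silently imputed.
    """
    X = _clean_features(features, feature_names=clf.feature_names)
    proba = clf.model.predict_proba(X)
    rel_col = list(clf.model.classes_).index(RELIABLE)
    p = proba[:, rel_col]
    return pd.DataFrame(
        {
            "probability_reliable": p,
            "label": np.where(p >= 0.5, RELIABLE, UNRELIABLE),
            "source": "predicted",
        },
        index=features.index,
    )


EXCLUDED = object()  # sentinel: every replicate of the peptide was unreliable


def aggregate_replicates(
    values: Sequence[float],
    probabilities: Optional[Sequence[float]] = None,
    labels: Optional[Sequence[str]] = None,
):
    """Reliability-weighted mean of one peptide's replicate values.

    Unreliable replicates are discarded; the rest are averaged with weights
    equal to their probability of being reliable.  Returns the aggregate, or
    :data:`EXCLUDED` when no reliable replicate remains.  Without QC
    (``probabilities``/``labels`` omitted) this is the plain mean.
    """
    vals = [v for v in values]
    if len(vals) == 0:
        raise DataError("at least one replicate value required")
    n = len(vals)
    probs = list(probabilities) if probabilities is not None else [1.0] * n
    labs = list(labels) if labels is not None else [RELIABLE] * n
    if not (len(probs) == n and len(labs) == n):
        raise DataError("values, probabilities and labels must align")
    keep_v, keep_w = [], []
    for v, w, l in zip(vals, probs, labs):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if w < 0:
            raise DataError(f"negative reliability weight {w}")
        if l == UNRELIABLE:
            continue
        keep_v.append(float(v))
        keep_w.append(float(w))
    if not keep_v or sum(keep_w) == 0:
        return EXCLUDED
    return float(np.average(keep_v, weights=keep_w))


def aggregate_table(per_spot: pd.DataFrame, value_column: str = "normalized") -> pd.DataFrame:
    """Vectorized per-peptide aggregation over a per-spot frame.

    ``per_spot`` needs columns peptide_id and ``value_column``; optional
    columns probability_reliable and label enable QC weighting.  Returns a
    frame indexed by peptide_id with columns value, excluded, n_used.
    """
    df = per_spot.copy()
    if "probability_reliable" not in df.columns:
        df["probability_reliable"] = 1.0
    if "label" not in df.columns:
        df["label"] = RELIABLE
    if (df["probability_reliable"] < 0).any():
        raise DataError("negative reliability weight")
    df["_keep"] = (df["label"] != UNRELIABLE) & df[value_column].notna()
    df["_w"] = np.where(df["_keep"], df["probability_reliable"], 0.0)
    df["_wv"] = df["_w"] * df[value_column].fillna(0.0)
    g = df.groupby("peptide_id", sort=True)
    wsum = g["_w"].sum()
    value = g["_wv"].sum() / wsum.replace(0.0, np.nan)
    out = pd.DataFrame({"value": value, "n_used": g["_keep"].sum().astype(int)})
    out["excluded"] = wsum == 0.0
    return out
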