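"""Variance stabilization and control-peptide linear-model normalization.

Raw fluorescence intensities are strongly heteroscedastic (variance grows
with the mean), so all modeling happens on the binary-log scale.  Systematic
array effects are then removed with an additive linear model fitted on the
control spots only,

    Y = intercept + Peptide + (Array) + Subarray + Needle + Row + Column + eps,

where every factor is categorical (Row and Column are the global physical
positions), no interactions are included, and eps is homoscedastic Gaussian.
Restricting the fit to controls — printed with many repeats for every needle
and subarray — avoids confounding genuine peptide reactivity with positional
effects; the peptide term is fitted (it absorbs the control identities'
different baseline levels) but never used for correction, because peptide
effects cannot be estimated for the experimental peptides.

The design is rank deficient by construction (e.g. the subarray indicators
lie inside the row space); columns that add no rank are dropped greedily in
fitting order and recorded, and the ANOVA decomposition is sequential
(Type I) in the order Peptide, Array, Subarray, Needle, Row, Column.
Applied effects are re-centered to mean zero over the control observations
so correction preserves the overall intensity scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from rapmad.errors import CorrectionError, DataError, FitError, StateError

log = logging.getLogger(__name__)

#: Intensity floor for the binary-log transform: zero counts map to log2(1)=0.
LOG_FLOOR = 1.0

#: Factor fitting order.  Peptide first so the sequential decomposition
#: attributes shared variation to peptide identity before position.
FACTOR_ORDER = ("Peptide", "Array", "Subarray", "Needle", "Row", "Column")

_FACTOR_COLUMNS = {
    "Peptide": "peptide_id",
    "Array": "array_id",
    "Subarray": "subarray",
    "Needle": "needle",
    "Row": "global_row",
    "Column": "global_col",
}

#: Factors whose estimated effects are subtracted from every spot.
APPLIED_FACTORS = ("Array", "Subarray", "Needle", "Row", "Column")


def log2_transform(raw_intensity, floor: float = LOG_FLOOR):
    """Binary logarithm with a floor: log2(max(x, floor)).

    Accepts scalars or arrays; negative intensities are a domain error.
    """
    x = np.asarray(raw_intensity, dtype=float)
    if (x < 0).any():
        raise DataError("raw intensity must be non-negative")
    out = np.log2(np.maximum(x, floor))
    return float(out) if np.isscalar(raw_intensity) or out.ndim == 0 else out


@dataclass
class EffectsModel:
    """Fitted systematic-effect coefficients for one (or several) arrays.

    ``effects[factor]`` maps each observed level to its applied, centered
    deviation; ``peptide_effects`` holds the fitted control-peptide terms
    (never applied).  ``aliased_terms`` lists the dropped design columns as
    ``"Factor[level]"`` strings.
    """

    intercept: float
    effects: dict = field(default_factory=dict)
    peptide_effects: dict = field(default_factory=dict)
    residual_variance: float = 0.0
    anova: Optional[pd.DataFrame] = None
    aliased_terms: list = field(default_factory=list)
    n_obs: int = 0

    def anova_tsv(self, path) -> None:
        if self.anova is None:
            raise StateError("model has no ANOVA table")
        self.anova.to_csv(path, sep="\t", index=False)


def _dummy_block(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Full-rank-candidate treatment dummies: indicator columns for levels 1..L-1."""
    X = np.zeros((codes.size, n_levels - 1))
    for lev in range(1, n_levels):
        X[codes == lev, lev - 1] = 1.0
    return X


def fit_effects_model(controls: pd.DataFrame, applied_factors=None) -> EffectsModel:
    """Fit the additive effects model on control-spot log intensities.

    ``controls`` needs columns ``log_intensity``, ``peptide_id``,
    ``subarray``, ``needle``, ``global_row``, ``global_col`` and, for joint
    multi-array fits, ``array_id``.  The Array term enters only when more
    than one array is present.

    Raises :class:`FitError` when any needle or subarray level carries fewer
    than two control observations.
    """
    required = {"log_intensity", "peptide_id", "subarray", "needle", "global_row", "global_col"}
    missing = required - set(controls.columns)
    if missing:
        raise DataError(f"control frame missing columns {sorted(missing)}")
    df = controls.reset_index(drop=True)
    y = df["log_intensity"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise DataError("non-finite control log intensities")
    n = y.size
    if n < 4:
        raise FitError("too few control observations to fit the effects model")

    for factor in ("needle", "subarray"):
        counts = df[factor].value_counts()
        thin = counts[counts < 2]
        if not thin.empty:
            lev = thin.index[0]
            raise FitError(f"{factor} level {lev!r} has {int(thin.iloc[0])} control spot(s); need >= 2")

    factors = [f for f in FACTOR_ORDER if f != "Array"]
    if "array_id" in df.columns and df["array_id"].nunique() > 1:
        factors = [f for f in FACTOR_ORDER]
    if applied_factors is None:
        applied_factors = [f for f in APPLIED_FACTORS if f in factors]

    # level codes per factor, in sorted level order
    levels: dict[str, list] = {}
    codes: dict[str, np.ndarray] = {}
    for f in factors:
        col = _FACTOR_COLUMNS[f]
        levs = sorted(df[col].unique())
        levels[f] = levs
        lut = {l: i for i, l in enumerate(levs)}
        codes[f] = df[col].map(lut).to_numpy()

    max_cols = 1 + sum(len(levels[f]) - 1 for f in factors)
    Q = np.empty((n, max_cols))
    r = 0
    # intercept
    Q[:, 0] = 1.0 / np.sqrt(n)
    r = 1
    ry = y - y.mean()
    total_ss = float(ry @ ry)

    kept: list[tuple[str, object]] = []  # (factor, level)
    kept_cols: list[np.ndarray] = [np.ones(n)]
    aliased: list[str] = []
    term_ss: dict[str, float] = {}
    term_df: dict[str, int] = {}
    tol = 1e-8

    for f in factors:
        rss_before = float(ry @ ry)
        df_f = 0
        for lev_idx in range(1, len(levels[f])):
            col = (codes[f] == lev_idx).astype(float)
            nrm0 = np.linalg.norm(col)
            v = col - Q[:, :r] @ (Q[:, :r].T @ col)
            v -= Q[:, :r] @ (Q[:, :r].T @ v)  # reorthogonalize
            nrm = np.linalg.norm(v)
            if nrm <= tol * max(nrm0, 1.0):
                aliased.append(f"{f}[{levels[f][lev_idx]}]")
                continue
            q = v / nrm
            Q[:, r] = q
            r += 1
            ry = ry - q * (q @ ry)
            kept.append((f, levels[f][lev_idx]))
            kept_cols.append(col)
            df_f += 1
        term_df[f] = df_f
        term_ss[f] = rss_before - float(ry @ ry)

    rss = float(ry @ ry)
    df_resid = n - 1 - sum(term_df.values())
    residual_variance = rss / df_resid if df_resid > 0 else 0.0

    # coefficient solve on the retained columns
    X = np.column_stack(kept_cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept = float(beta[0])
    coef = {("Intercept", None): intercept}
    for (f, lev), b in zip(kept, beta[1:]):
        coef[(f, lev)] = float(b)

    # per-factor raw effects (baseline and aliased levels at 0), then center
    # weighted by control observation counts so corrections sum to zero
    effects: dict[str, dict] = {}
    peptide_effects: dict = {}
    for f in factors:
        raw = {lev: coef.get((f, lev), 0.0) for lev in levels[f]}
        if f == "Peptide":
            peptide_effects = raw
            continue
        if f not in applied_factors:
            continue
        counts = np.bincount(codes[f], minlength=len(levels[f])).astype(float)
        vals = np.array([raw[lev] for lev in levels[f]])
        centered = vals - float(np.average(vals, weights=counts))
        effects[f] = {lev: float(e) for lev, e in zip(levels[f], centered)}

    mean_sq = {f: (term_ss[f] / term_df[f] if term_df[f] else np.nan) for f in factors}
    rows = []
    for f in factors:
        F = mean_sq[f] / residual_variance if (term_df[f] and residual_variance > 0) else np.nan
        p = float(stats.f.sf(F, term_df[f], df_resid)) if np.isfinite(F) else np.nan
        rows.append((f, term_df[f], term_ss[f], mean_sq[f], F, p))
    rows.append(("Residuals", df_resid, rss, residual_variance if df_resid > 0 else np.nan, np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["Term", "Df", "SumSq", "MeanSq", "F", "p"])

    if aliased:
        log.info("dropped %d aliased design columns: %s%s", len(aliased), aliased[:6], "..." if len(aliased) > 6 else "")

    return EffectsModel(
        intercept=intercept,
        effects=effects,
        peptide_effects=peptide_effects,
        residual_variance=residual_variance,
        anova=anova,
        aliased_terms=aliased,
        n_obs=n,
    )


def correct(spots: pd.DataFrame, model: EffectsModel, value_column: str = "log_intensity") -> pd.Series:
    """Subtract the fitted systematic effects from every spot.

    The peptide term is never subtracted.  Spots at levels the model dropped
    as aliased are corrected with the retained effects only; a level the fit
    has never seen at all raises :class:`CorrectionError`.
    """
    out = spots[value_column].to_numpy(dtype=float).copy()
    for f, eff in model.effects.items():
        col = _FACTOR_COLUMNS[f]
        if col not in spots.columns:
            raise CorrectionError(f"spot frame lacks column {col!r} needed for factor {f}")
        mapped = spots[col].map(eff)
        if mapped.isna().any():
            bad = spots.loc[mapped.isna(), col].iloc[0]
            raise CorrectionError(f"{f} level {bad!r} absent from the fitted model")
        out -= mapped.to_numpy(dtype=float)
    return pd.Series(out, index=spots.index, name="normalized")


def variance_reduction(model: EffectsModel) -> float:
    """Fraction of non-peptide variation explained by the systematic terms.

    Computed from the sequential sums of squares (Peptide fitted first) as
    SS(systematic) / (SS(systematic) + SS(residual)).
    """
    if model.anova is None:
        raise StateError("model has no ANOVA table; fit it first")
    tab = model.anova.set_index("Term")
    sys_terms = [t for t in tab.index if t not in ("Peptide", "Residuals")]
    ss_sys = float(tab.loc[sys_terms, "SumSq"].sum())
    ss_res = float(tab.loc["Residuals", "SumSq"])
    denom = ss_sys + ss_res
    if denom == 0:
        return 0.0
    return ss_sys / denom
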