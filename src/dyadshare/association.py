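"""Per-feature covariate association on arcsin-sqrt transformed abundances.

Each feature's relative abundance (as a fraction) is variance-stabilized with
asin(sqrt(x)) and modeled by an additive linear model on the target covariate
plus fixed-effect adjusters (the clinical covariates, infant age and
sequencing depth).  The target coefficient's t-test p-values are
BH-corrected across features and associations below FDR 0.25 are reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .community_stats import bh_fdr

logger = logging.getLogger("dyadshare")

#: reference levels chosen so coefficient signs read as the effect of the
#: non-reference condition (e.g. cesarean vs vaginal)
REFERENCE_LEVELS = {
    "delivery_mode": "vaginal",
    "feeding": "exclusive_bf",
    "infant_antibiotics": "F",
    "gestational_age": "full-term",
    "maternal_abx_before_delivery": "F",
    "maternal_intrapartum_abx": "F",
    "birth_weight_class": "normal",
    "maternal_bmi_class": "normal",
    "sex": "F",
    "maternal_age_class": "19-29",
    "csection_type": "elective",
}

DEFAULT_FDR = 0.25


def arcsin_sqrt(x):
    """Variance-stabilizing transform asin(sqrt(x)) for fractions in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any() or (x > 1).any():
        raise ValueError("arcsin-sqrt input must lie in [0, 1]")
    return np.arcsin(np.sqrt(x))


def _encode(md: pd.DataFrame, columns, numeric_columns) -> pd.DataFrame:
    """One-hot encode categoricals against their reference level; z-scale
    numeric adjusters."""
    parts = []
    for col in columns:
        s = md[col]
        ref = REFERENCE_LEVELS.get(col)
        levels = [lv for lv in pd.unique(s.dropna()) if lv != ref]
        ref_levels = ([ref] if ref in set(s.dropna()) else []) + sorted(map(str, levels))
        cat = pd.Categorical(s.astype(str), categories=ref_levels)
        dummies = pd.get_dummies(cat, prefix=col, drop_first=True, dtype=float)
        dummies.index = md.index
        parts.append(dummies)
    for col in numeric_columns:
        v = md[col].astype(float)
        sd = v.std(ddof=0)
        parts.append(((v - v.mean()) / sd if sd > 0 else v * 0.0).rename(col))
    return pd.concat(parts, axis=1)


def _drop_aliased(X: pd.DataFrame, protect: list[str]) -> pd.DataFrame:
    """Drop columns that make the design rank-deficient (protected columns,
    i.e. the target's, are kept)."""
    cols = list(X.columns)
    ordered = protect + [c for c in cols if c not in protect]
    kept: list[str] = []
    for c in ordered:
        trial = kept + [c]
        m = np.column_stack([np.ones(len(X))] + [X[t].values for t in trial])
        if np.linalg.matrix_rank(m) == m.shape[1]:
            kept.append(c)
        else:
            logger.info("dropping aliased design column %s", c)
    return X[[c for c in cols if c in kept]]


def fit_associations(
    table,
    metadata: pd.DataFrame,
    target_covariate: str,
    adjustment_covariates=(),
    numeric_adjusters=("day", "sequencing_depth"),
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Additive linear model of transformed abundance per feature.

    Returns one row per (feature, target level) with coefficient, standard
    error, p, BH q across features, and a ``reported`` flag for q < ``fdr``.
    Zero-variance features and samples with missing model variables are
    dropped.
    """
    md = metadata.set_index("sample_id")
    samples = [s for s in table.sample_ids if s in md.index]
    md = md.loc[samples]
    cat_cols = [target_covariate] + [c for c in adjustment_covariates
                                     if c != target_covariate]
    model_cols = cat_cols + [c for c in numeric_adjusters if c in md.columns]
    usable = md[model_cols].replace("", np.nan).dropna().index
    md = md.loc[usable]
    if len(md) < len(model_cols) + 2:
        raise ValueError("too few complete samples for the design")
    X = _encode(md, cat_cols, [c for c in numeric_adjusters if c in md.columns])
    target_cols = [c for c in X.columns if c.startswith(f"{target_covariate}_")]
    if not target_cols:
        raise ValueError(f"target {target_covariate!r} has a single level")
    X = _drop_aliased(X, target_cols)
    design = sm.add_constant(X.astype(float))

    rows = []
    for feat in table.feature_ids:
        y_raw = table.values.loc[feat, list(md.index)].astype(float) / 100.0
        if y_raw.nunique() <= 1:
            logger.info("associations: %s dropped (zero variance)", feat)
            continue
        y = arcsin_sqrt(y_raw.values)
        fit = sm.OLS(y, design).fit()
        for tc in target_cols:
            rows.append({
                "feature_id": feat, "covariate": target_covariate,
                "level": tc[len(target_covariate) + 1:],
                "coefficient": float(fit.params[tc]),
                "std_error": float(fit.bse[tc]),
                "p_value": float(fit.pvalues[tc]),
                "n_used": int(len(md)),
            })
    out = pd.DataFrame(rows, columns=["feature_id", "covariate", "level",
                                      "coefficient", "std_error", "p_value",
                                      "n_used"])
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].values)
        out["reported"] = out["q_value"] < fdr
    else:
        out["q_value"] = []
        out["reported"] = []
    return out
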