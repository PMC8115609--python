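"""Dyad-level feature sharing: mother-infant shared species/pathways,
related-vs-unrelated similarity, core shared set and sharing dynamics.

A feature is shared by a dyad when it is present (abundance > 0) in both the
mother's delivery-window sample and an infant sample, regardless of
abundance.  The shared fraction is infant-referenced by default: the number
of shared features divided by the infant's feature count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_stats import bray_curtis
from .profiles_io import DEFAULT_SCHEME, AbundanceTable, assign_time_bins

logger = logging.getLogger("dyadshare")


@dataclass
class SharingRecord:
    dyad_id: str
    infant_sample: str
    mother_sample: str
    shared_feature_set: frozenset
    n_shared: int
    infant_feature_count: int
    mother_feature_count: int
    shared_fraction_infant: float
    shared_fraction_mother: float
    feature_kind: str


def pair_dyads(metadata: pd.DataFrame, mother_window: str = "delivery",
               scheme=None) -> pd.DataFrame:
    """Pair every infant sample with its mother's sample in the window.

    The mother sample nearest delivery (smallest postnatal day; ties broken
    by sample id) represents the dyad; dyads whose mother has no sample in
    the window are excluded with a log message.  Returns a DataFrame with
    columns dyad_id, mother_sample, infant_sample.
    """
    scheme = scheme or DEFAULT_SCHEME
    md = assign_time_bins(metadata, scheme)
    mothers = md[(md["role"] == "mother") & (md["time_bin"] == mother_window)]
    infants = md[md["role"] == "infant"]
    chosen = (
        mothers.sort_values(["day", "sample_id"])
        .groupby("dyad_id", sort=True)
        .first()["sample_id"]
    )
    rows = []
    for dyad, grp in infants.groupby("dyad_id", sort=True):
        if dyad not in chosen.index:
            logger.info("dyad %s excluded: no mother sample in window %r", dyad, mother_window)
            continue
        for inf_sample in sorted(grp["sample_id"]):
            rows.append({"dyad_id": dyad, "mother_sample": chosen[dyad],
                         "infant_sample": inf_sample})
    return pd.DataFrame(rows, columns=["dyad_id", "mother_sample", "infant_sample"])


def shared_features(mother_profile: pd.Series, infant_profile: pd.Series,
                    dyad_id: str = "", mother_sample: str = "",
                    infant_sample: str = "", feature_kind: str = "taxon") -> SharingRecord:
    """Presence/absence sharing of one mother-infant sample pair."""
    m = mother_profile > 0
    i = infant_profile > 0
    shared = frozenset(mother_profile.index[m & i])
    n_inf, n_mom = int(i.sum()), int(m.sum())
    return SharingRecord(
        dyad_id=dyad_id, infant_sample=infant_sample, mother_sample=mother_sample,
        shared_feature_set=shared, n_shared=len(shared),
        infant_feature_count=n_inf, mother_feature_count=n_mom,
        shared_fraction_infant=len(shared) / n_inf if n_inf else 0.0,
        shared_fraction_mother=len(shared) / n_mom if n_mom else 0.0,
        feature_kind=feature_kind,
    )


def compute_sharing(table: AbundanceTable, pairing: pd.DataFrame) -> pd.DataFrame:
    """Sharing records for every paired (mother, infant) sample.

    Returns one row per pair with counts and fractions plus the shared
    feature set (as a frozenset column).
    """
    rows = []
    for row in pairing.itertuples(index=False):
        rec = shared_features(
            table.values[row.mother_sample], table.values[row.infant_sample],
            dyad_id=row.dyad_id, mother_sample=row.mother_sample,
            infant_sample=row.infant_sample, feature_kind=table.feature_kind,
        )
        rows.append(rec.__dict__)
    return pd.DataFrame(rows, columns=[
        "dyad_id", "infant_sample", "mother_sample", "shared_feature_set",
        "n_shared", "infant_feature_count", "mother_feature_count",
        "shared_fraction_infant", "shared_fraction_mother", "feature_kind"])


def dyad_shared_features(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-sample sharing to the dyad level (shared at >= 1 infant
    timepoint).  Returns long-form (dyad_id, feature_id) rows."""
    rows = []
    for dyad, grp in records.groupby("dyad_id", sort=True):
        feats = frozenset().union(*grp["shared_feature_set"])
        rows.extend({"dyad_id": dyad, "feature_id": f} for f in sorted(feats))
    return pd.DataFrame(rows, columns=["dyad_id", "feature_id"])


def related_vs_unrelated_similarity(table: AbundanceTable, pairing: pd.DataFrame,
                                    alternative: str = "two-sided"):
    """Bray-Curtis of each infant sample vs its own mother (related) and vs
    every other dyad's windowed mother (unrelated), with a rank-sum
    comparison of the two distributions."""
    mothers = pairing.drop_duplicates("dyad_id").set_index("dyad_id")["mother_sample"]
    if len(mothers) < 2:
        raise ValueError("need >= 2 dyads")
    related, unrelated = [], []
    for row in pairing.itertuples(index=False):
        inf = table.values[row.infant_sample].values
        for dyad, msample in mothers.items():
            d = bray_curtis(table.values[msample].values, inf)
            (related if dyad == row.dyad_id else unrelated).append(d)
    stat, p = stats.mannwhitneyu(related, unrelated, alternative=alternative)
    return np.asarray(related), np.asarray(unrelated), float(stat), float(p)


def core_shared_set(records: pd.DataFrame, metadata: pd.DataFrame,
                    min_dyads_per_study: int = 1) -> dict:
    """Features shared in >= ``min_dyads_per_study`` dyads within EVERY study.

    Returns the core feature list, the feature x study dyad-count matrix, and
    each feature's prevalence across all dyads (fraction of dyads sharing it).
    """
    dyad_study = metadata.drop_duplicates("dyad_id").set_index("dyad_id")["study_id"]
    long = dyad_shared_features(records)
    if long.empty:
        return {"core_features": [], "per_study_dyad_counts": pd.DataFrame(),
                "prevalence_across_dyads": pd.Series(dtype=float)}
    long["study_id"] = long["dyad_id"].map(dyad_study)
    counts = (
        long.groupby(["feature_id", "study_id"])["dyad_id"].nunique()
        .unstack(fill_value=0)
    )
    studies = sorted(metadata.loc[metadata["dyad_id"].isin(records["dyad_id"]),
                                  "study_id"].unique())
    counts = counts.reindex(columns=studies, fill_value=0)
    core = counts.index[(counts >= min_dyads_per_study).all(axis=1)]
    n_dyads = records["dyad_id"].nunique()
    prevalence = long.groupby("feature_id")["dyad_id"].nunique() / n_dyads
    return {"core_features": sorted(core), "per_study_dyad_counts": counts,
            "prevalence_across_dyads": prevalence.sort_values(ascending=False)}


def shared_fraction_dynamics(records_by_kind: dict[str, pd.DataFrame],
                             metadata: pd.DataFrame, scheme=None,
                             denominator: str = "infant",
                             quadratic_fit: bool = False) -> pd.DataFrame:
    """Mean shared fraction per infant time bin per feature kind, with a
    normal-approximation 95% CI (1.96 * SE); optional quadratic fit in age.
    """
    scheme = scheme or DEFAULT_SCHEME
    md = assign_time_bins(metadata, scheme).set_index("sample_id")
    col = f"shared_fraction_{denominator}"
    out = []
    for kind, records in records_by_kind.items():
        rec = records.copy()
        rec["time_bin"] = md.loc[rec["infant_sample"], "time_bin"].values
        rec["day"] = md.loc[rec["infant_sample"], "day"].values
        rec = rec[rec["time_bin"] != "unbinned"]
        for time_bin, grp in rec.groupby("time_bin"):
            vals = grp[col].values
            se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            out.append({
                "feature_kind": kind, "time_bin": time_bin, "n": len(vals),
                "mean_fraction": float(vals.mean()),
                "ci_low": float(vals.mean() - 1.96 * se),
                "ci_high": float(vals.mean() + 1.96 * se),
            })
        if quadratic_fit and rec["day"].nunique() > 2:
            coefs = np.polyfit(rec["day"].values, rec[col].values, deg=2)
            logger.info("quadratic fit (%s): %s", kind, coefs)
    order = {b: i for i, b in enumerate(scheme.infant_bin_order)}
    df = pd.DataFrame(out, columns=["feature_kind", "time_bin", "n",
                                    "mean_fraction", "ci_low", "ci_high"])
    return df.sort_values(["feature_kind", "time_bin"],
                          key=lambda s: s.map(lambda v: order.get(v, v))
                          if s.name == "time_bin" else s).reset_index(drop=True)


def shared_species_count_vs_age(records: pd.DataFrame, metadata: pd.DataFrame):
    """Per-infant-sample (age_days, n_shared) scatter plus an OLS fit.

    Returns (points DataFrame, fit dict or None when < 3 points).
    """
    md = metadata.set_index("sample_id")
    points = records[["infant_sample", "n_shared"]].copy()
    points["age_days"] = md.loc[points["infant_sample"], "day"].values
    fit = None
    if len(points) >= 3 and points["age_days"].nunique() > 1:
        res = stats.linregress(points["age_days"], points["n_shared"])
        fit = {"slope": float(res.slope), "intercept": float(res.intercept),
               "p_value": float(res.pvalue), "stderr": float(res.stderr)}
    return points[["infant_sample", "age_days", "n_shared"]], fit
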