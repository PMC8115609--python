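"""Readers/writers for the standard profile-table formats plus time-bin assignment.

The pipeline consumes three tabular dialects: MetaPhlAn2 merged taxon tables
(rows are pipe-delimited taxonomy strings ``k__...|p__...|...|s__...``, values
are percent relative abundances), HUMAnN2 joined pathway tables (rows are
pathway IDs with an optional ``|g__...s__...`` stratification suffix), and a
plain per-sample metadata TSV.  Everything is held in-memory as pandas
DataFrames wrapped in :class:`AbundanceTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dyadshare")

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species", "strain")

#: Per-sample metadata columns every dyad-aware computation joins on.
METADATA_COLUMNS = [
    "sample_id", "subject_id", "dyad_id", "role", "study_id", "day", "day_scale",
    "delivery_mode", "feeding", "infant_antibiotics", "gestational_age",
    "maternal_age_class", "maternal_abx_before_delivery", "maternal_intrapartum_abx",
    "birth_weight_class", "csection_type", "maternal_bmi_class", "sex",
    "sequencing_depth",
]

#: The twelve clinical covariates screened for variance contribution.
COVARIATES = [
    "delivery_mode", "study_id", "feeding", "infant_antibiotics", "gestational_age",
    "maternal_age_class", "maternal_abx_before_delivery", "maternal_intrapartum_abx",
    "birth_weight_class", "csection_type", "maternal_bmi_class", "sex",
]


class ParseError(ValueError):
    """Raised when an input table violates its dialect."""


@dataclass
class AbundanceTable:
    """A features x samples matrix of relative abundances (percent scale).

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by feature id, columns by sample id.
    feature_kind : str
        ``"taxon"`` or ``"pathway"``.
    taxon_level : pandas.Series, optional
        Rank name per feature when ``feature_kind == "taxon"``.
    """

    values: pd.DataFrame
    feature_kind: str = "taxon"
    taxon_level: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.feature_kind not in ("taxon", "pathway"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate feature id {dup!r}")
        if (self.values.values < 0).any():
            raise ValueError("negative abundance")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict_level(self, level: str) -> "AbundanceTable":
        """Return the sub-table of taxa at a single rank (e.g. ``"species"``)."""
        if self.taxon_level is None:
            raise ValueError("table has no taxonomy annotation")
        keep = self.taxon_level[self.taxon_level == level].index
        return AbundanceTable(self.values.loc[keep], "taxon", self.taxon_level.loc[keep])

    def subset_samples(self, samples) -> "AbundanceTable":
        return AbundanceTable(self.values[list(samples)], self.feature_kind, self.taxon_level)


def taxon_display_name(clade: str) -> str:
    """Strip the rank prefix of the terminal clade and map underscores to spaces.

    ``k__Bacteria|...|s__Bifidobacterium_longum`` -> ``Bifidobacterium longum``.
    """
    last = clade.split("|")[-1]
    for pre in RANK_PREFIXES:
        if last.startswith(pre):
            last = last[len(pre):]
            break
    return last.replace("_", " ")


def _clade_level(clade: str) -> str:
    parts = clade.split("|")
    for part in parts:
        if not any(part.startswith(p) for p in RANK_PREFIXES):
            raise ParseError(f"malformed clade string {clade!r} (component {part!r})")
    return RANK_NAMES[len(parts) - 1]


def parse_metaphlan_table(path) -> AbundanceTable:
    """Parse a MetaPhlAn2 merged abundance table (all taxonomic levels)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    levels = pd.Series([_clade_level(c) for c in df.index], index=df.index)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric abundance cell in {path}: {exc}") from exc
    return AbundanceTable(values, "taxon", levels)


def write_metaphlan_table(table: AbundanceTable, path) -> None:
    out = table.values.copy()
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t", float_format="%.17g")


def parse_humann_pathways(
    path,
    drop_stratified: bool = True,
    drop_unmapped: bool = True,
    renormalize: bool = False,
) -> AbundanceTable:
    """Parse a HUMAnN2 joined pathway-abundance table.

    Stratified rows carry a ``|g__X.s__Y`` suffix; ``drop_stratified`` keeps
    only community-level rows.  ``drop_unmapped`` removes the UNMAPPED /
    UNINTEGRATED accounting rows before optional per-sample renormalization
    to percent.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate pathway id {dup!r}")
    values = df.astype(float)
    if drop_stratified:
        values = values.loc[["|" not in i for i in values.index]]
    if drop_unmapped:
        base = [i.split("|")[0] for i in values.index]
        keep = [b not in ("UNMAPPED", "UNINTEGRATED") for b in base]
        values = values.loc[keep]
    if renormalize:
        sums = values.sum(axis=0)
        sums = sums.replace(0.0, np.nan)
        values = values.div(sums, axis=1).fillna(0.0) * 100.0
    return AbundanceTable(values, "pathway")


def write_humann_pathways(table: AbundanceTable, path) -> None:
    out = table.values.copy()
    out.index.name = "# Pathway"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str,
                                            "dyad_id": str, "study_id": str})
    missing = set(["sample_id", "subject_id", "dyad_id", "role", "study_id",
                   "day", "day_scale"]) - set(md.columns)
    if missing:
        raise ParseError(f"metadata missing columns {sorted(missing)}")
    return md


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Time bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeBinScheme:
    """Closed integer day ranges discretizing sampling times, per role.

    The default scheme bins mothers into pregnancy (gestational days 189-224),
    delivery (postnatal 0-7) and postpartum (postnatal 8-480), and infants into
    birth (0-1), 1 wk. (2-7), 1 mo. (8-30), 3 mo. (31-90), 6 mo. (91-180) and
    12 mo. (181-480 postnatal days).
    """

    mother_bins: tuple = (
        ("pregnancy", "gestational", 189, 224),
        ("delivery", "postnatal", 0, 7),
        ("postpartum", "postnatal", 8, 480),
    )
    infant_bins: tuple = (
        ("birth", "postnatal", 0, 1),
        ("1 wk.", "postnatal", 2, 7),
        ("1 mo.", "postnatal", 8, 30),
        ("3 mo.", "postnatal", 31, 90),
        ("6 mo.", "postnatal", 91, 180),
        ("12 mo.", "postnatal", 181, 480),
    )

    #: display order of infant bins, used by the dynamics reports
    @property
    def infant_bin_order(self) -> list[str]:
        return [b[0] for b in self.infant_bins]

    def assign(self, role: str, day: float, day_scale: str) -> str:
        if role == "infant" and day_scale == "gestational":
            raise ValueError("infant samples must be on the postnatal day scale")
        bins = self.mother_bins if role == "mother" else self.infant_bins
        for label, scale, lo, hi in bins:
            if day_scale == scale and lo <= day <= hi:
                return label
        return "unbinned"


DEFAULT_SCHEME = TimeBinScheme()


def assign_time_bins(metadata: pd.DataFrame, scheme: TimeBinScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Return a copy of ``metadata`` with a ``time_bin`` column filled in.

    Samples outside every range get the label ``unbinned`` and are excluded
    from bin-stratified analyses downstream.
    """
    md = metadata.copy()
    md["time_bin"] = [
        scheme.assign(r, d, s)
        for r, d, s in zip(md["role"], md["day"], md["day_scale"])
    ]
    return md


def filter_features(
    table: AbundanceTable,
    min_prevalence: float = 0.05,
    min_mean_abundance: float = 0.1,
    scope_samples=None,
) -> AbundanceTable:
    """Keep features with prevalence >= ``min_prevalence`` and mean abundance
    strictly greater than ``min_mean_abundance`` (percent) over the scope.

    Prevalence is the fraction of scope samples with abundance > 0.
    """
    if scope_samples is None:
        scope_samples = table.sample_ids
    scope_samples = list(scope_samples)
    if not scope_samples:
        raise ValueError("empty sample scope")
    unknown = set(scope_samples) - set(table.sample_ids)
    if unknown:
        raise ValueError(f"scope samples not in table: {sorted(unknown)[:3]}")
    sub = table.values[scope_samples]
    prevalence = (sub > 0).mean(axis=1)
    mean_ab = sub.mean(axis=1)
    keep = sub.index[(prevalence >= min_prevalence) & (mean_ab > min_mean_abundance)]
    lv = table.taxon_level.loc[keep] if table.taxon_level is not None else None
    return AbundanceTable(table.values.loc[keep], table.feature_kind, lv)
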