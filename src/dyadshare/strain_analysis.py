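"""Strain-level inference from marker-gene SNP haplotypes.

Each species contributes one aligned haplotype per sample (the dominant
strain).  Pairwise p-distances feed a neighbor-joining tree; the strain
distance between a mother and her infant is the patristic (branch-length
path) distance normalized to [0, 1], and vertical transmission is called when
that distance falls strictly below a conservative threshold (default 0.1).
"""

from __future__ import annotations

import io
import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .community_stats import bh_fdr, blocked_wilcoxon

logger = logging.getLogger("dyadshare")

#: encoding of the 4-letter alphabet plus gap
_ALPHABET = "ACGT-"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
GAP_CODE = _CODE["-"]

DEFAULT_THRESHOLD = 0.1


@dataclass
class HaplotypeAlignment:
    """Aligned dominant-strain SNP haplotypes for one species.

    ``records`` maps sample_id -> aligned sequence over A/C/G/T/- ; all
    sequences must share one length and each sample appears once (one dominant
    strain per species per sample).
    """

    species: str
    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"{self.species}: empty alignment")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.species}: unequal sequence lengths {sorted(lengths)}")
        bad = {c for s in self.records.values() for c in s} - set(_ALPHABET)
        if bad:
            raise ValueError(f"{self.species}: invalid characters {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    def encoded(self) -> np.ndarray:
        """Integer matrix (n_samples x n_sites), gap encoded as 4."""
        return np.array(
            [[_CODE[c] for c in self.records[s]] for s in self.records],
            dtype=np.uint8,
        )


def write_haplotype_fasta(alignment: HaplotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in alignment.records.items():
            fh.write(f">{sid}\n{seq}\n")


def parse_haplotype_fasta(path, species: str | None = None) -> HaplotypeAlignment:
    """Read one per-species alignment; record IDs are sample IDs."""
    if species is None:
        species = Path(path).name.split(".")[0]
    records: dict[str, str] = {}
    sid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if sid is not None:
                    records[sid] = "".join(chunks)
                sid, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if sid is not None:
        records[sid] = "".join(chunks)
    return HaplotypeAlignment(species, records)


def read_alignment_dir(directory) -> dict[str, HaplotypeAlignment]:
    """Read all ``<species>.aln.fasta`` files of a directory."""
    out = {}
    for path in sorted(Path(directory).glob("*.aln.fasta")):
        aln = parse_haplotype_fasta(path)
        out[aln.species] = aln
    return out


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def haplotype_similarity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical positions among comparable (both non-gap) ones.

    Returns NaN (with a warning) when no position is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    gap = ord("-")
    comparable = (a != gap) & (b != gap)
    n = int(comparable.sum())
    if n == 0:
        warnings.warn("no comparable (both non-gap) positions; similarity undefined")
        return float("nan")
    return float((a[comparable] == b[comparable]).sum() / n)


def _pairwise_identity(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise (matches, comparable) counts via one-hot matmuls."""
    nongap = (enc != GAP_CODE).astype(np.float64)
    comparable = nongap @ nongap.T
    matches = np.zeros_like(comparable)
    for code in range(4):
        ind = (enc == code).astype(np.float64)
        matches += ind @ ind.T
    return matches, comparable


def p_distance_matrix(alignment: HaplotypeAlignment) -> pd.DataFrame:
    """Symmetric matrix of p-distances (1 - similarity), zero diagonal.

    Pairs with no comparable positions get NaN.
    """
    ids = alignment.sample_ids
    matches, comparable = _pairwise_identity(alignment.encoded())
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(comparable > 0, matches / np.maximum(comparable, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class StrainTree:
    """A species tree with branch lengths; leaf names are sample IDs."""

    species: str
    tree: TreeNode = field(repr=False)

    @property
    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @classmethod
    def from_newick(cls, species: str, newick: str) -> "StrainTree":
        return cls(species, TreeNode.read(io.StringIO(newick)))


def nj_tree(distance_matrix: pd.DataFrame, species: str = "") -> StrainTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths produced by NJ are clamped to zero.  Fewer than
    three leaves yields the trivial tree (cherry or single leaf).
    """
    ids = list(distance_matrix.index)
    if len(ids) == 1:
        return StrainTree(species, TreeNode.read(io.StringIO(f"{ids[0]}:0;")))
    if len(ids) == 2:
        d = float(distance_matrix.iloc[0, 1])
        nwk = f"({ids[0]}:{d / 2},{ids[1]}:{d / 2});"
        return StrainTree(species, TreeNode.read(io.StringIO(nwk)))
    dm = DistanceMatrix(np.ascontiguousarray(distance_matrix.values, dtype=float), ids)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return StrainTree(species, tree)


def patristic_distance(tree: StrainTree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths along the unique path between two leaves."""
    if leaf_a == leaf_b:
        tree.tree.find(leaf_a)  # raises if unknown
        return 0.0
    return float(tree.tree.find(leaf_a).distance(tree.tree.find(leaf_b)))


def _patristic_matrix(tree: StrainTree) -> pd.DataFrame:
    dm = tree.tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def _normalizer(dist: pd.DataFrame, method: str) -> float:
    off = dist.values[np.triu_indices_from(dist.values, k=1)]
    off = off[~np.isnan(off)]
    if off.size == 0:
        return 0.0
    if method == "max_pair":
        return float(off.max())
    if method == "median_pair":
        return float(np.median(off))
    raise ValueError(f"unknown normalization {method!r}")


def normalized_strain_distance(tree: StrainTree, leaf_a: str, leaf_b: str,
                               normalization: str = "max_pair") -> float:
    """Patristic distance scaled by the tree-wide normalizer (default: the
    maximum leaf-pair patristic distance, so values live in [0, 1] and the
    maximally distant pair maps to 1)."""
    if normalization == "total_branch_length":
        norm = sum(n.length or 0.0 for n in tree.tree.traverse() if not n.is_root())
    else:
        norm = _normalizer(_patristic_matrix(tree), normalization)
    d = patristic_distance(tree, leaf_a, leaf_b)
    if norm == 0.0:
        return 0.0  # all strains identical
    return d / norm


# ---------------------------------------------------------------------------
# Transmission calling
# ---------------------------------------------------------------------------

def call_transmission(
    alignments: dict[str, HaplotypeAlignment],
    pairing: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    trees: dict[str, StrainTree] | None = None,
    normalization: str = "max_pair",
) -> pd.DataFrame:
    """Call mother-to-infant strain sharing per (dyad, species, infant sample).

    For every paired (mother_sample, infant_sample) where both carry the
    species, the normalized strain distance is computed on the species tree
    (NJ on p-distances unless a tree is supplied); species with fewer than
    three haplotypes fall back to the p-distance normalized by the species'
    maximum pairwise p-distance.  ``shared`` is strictly
    ``normalized_distance < threshold``; pairs where either member lacks the
    species yield no call.
    """
    rows = []
    for species in sorted(alignments):
        aln = alignments[species]
        have = set(aln.sample_ids)
        pairs = pairing[
            pairing["mother_sample"].isin(have) & pairing["infant_sample"].isin(have)
        ]
        if pairs.empty:
            continue
        if trees is not None and species in trees:
            dist = _patristic_matrix(trees[species])
            norm_method = normalization
        elif len(have) >= 3:
            tree = nj_tree(p_distance_matrix(aln), species)
            dist = _patristic_matrix(tree)
            norm_method = normalization
        else:
            dist = p_distance_matrix(aln)
            norm_method = "max_pair"
        if norm_method == "total_branch_length":
            # only reachable with an explicit tree or >=3 leaves
            tre = trees[species] if trees is not None and species in trees \
                else nj_tree(p_distance_matrix(aln), species)
            norm = sum(n.length or 0.0 for n in tre.tree.traverse() if not n.is_root())
        else:
            norm = _normalizer(dist, norm_method)
        for row in pairs.itertuples(index=False):
            d = float(dist.loc[row.mother_sample, row.infant_sample])
            nd = 0.0 if norm == 0.0 else d / norm
            rows.append({
                "dyad_id": row.dyad_id,
                "species": species,
                "mother_sample": row.mother_sample,
                "infant_sample": row.infant_sample,
                "normalized_distance": nd,
                "threshold": threshold,
                "shared": bool(nd < threshold),
            })
    return pd.DataFrame(
        rows,
        columns=["dyad_id", "species", "mother_sample", "infant_sample",
                 "normalized_distance", "threshold", "shared"],
    )


# ---------------------------------------------------------------------------
# Heterogeneity and dynamics
# ---------------------------------------------------------------------------

def intra_subject_heterogeneity(
    alignments: dict[str, HaplotypeAlignment],
    metadata: pd.DataFrame,
    min_comparisons: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-subject, cross-timepoint haplotype similarity, intra-mother vs
    intra-infant, per species.

    Species are retained only when both strata contribute at least
    ``min_comparisons`` pairwise comparisons; retained species get a Wilcoxon
    rank-sum comparison of the two similarity distributions, BH-corrected
    across species.  Returns (per-comparison long table, per-species tests).
    """
    md = metadata.set_index("sample_id")
    values = []
    for species in sorted(alignments):
        aln = alignments[species]
        ids = [s for s in aln.sample_ids if s in md.index]
        by_subject: dict[str, list[str]] = {}
        for s in ids:
            by_subject.setdefault(md.at[s, "subject_id"], []).append(s)
        for subject, samples in sorted(by_subject.items()):
            if len(samples) < 2:
                continue
            role = md.at[samples[0], "role"]
            for a, b in itertools.combinations(sorted(samples), 2):
                values.append({
                    "species": species, "subject_id": subject, "role": role,
                    "sample_a": a, "sample_b": b,
                    "similarity": haplotype_similarity(aln.records[a], aln.records[b]),
                })
    long = pd.DataFrame(values, columns=["species", "subject_id", "role",
                                         "sample_a", "sample_b", "similarity"])
    tests = []
    for species, grp in long.groupby("species"):
        mom = grp.loc[grp["role"] == "mother", "similarity"].dropna()
        inf = grp.loc[grp["role"] == "infant", "similarity"].dropna()
        if len(mom) < min_comparisons or len(inf) < min_comparisons:
            logger.info("heterogeneity: %s skipped (<%d comparisons in a stratum)",
                        species, min_comparisons)
            continue
        if mom.nunique() == 1 and inf.nunique() == 1 and mom.iloc[0] == inf.iloc[0]:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(inf, mom, alternative="two-sided")
        tests.append({
            "species": species, "n_infant": len(inf), "n_mother": len(mom),
            "mean_infant": inf.mean(), "mean_mother": mom.mean(),
            "statistic": float(stat), "p_value": float(p),
        })
    tests_df = pd.DataFrame(tests, columns=["species", "n_infant", "n_mother",
                                            "mean_infant", "mean_mother",
                                            "statistic", "p_value"])
    if len(tests_df):
        tests_df["q_value"] = bh_fdr(tests_df["p_value"].values)
    else:
        tests_df["q_value"] = []
    return long, tests_df


def shared_strain_dynamics(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    scheme=None,
    display_min_prevalence: float = 0.1,
) -> dict:
    """Per-bin shared-strain prevalence per species plus per-infant counts.

    Prevalence in a bin is the fraction of evaluable infant samples (those
    with a call for the species) whose call is shared; species shown must
    reach ``display_min_prevalence`` in at least one bin.  The per-infant
    shared-strain count is regressed on age (OLS).
    """
    from .profiles_io import DEFAULT_SCHEME, assign_time_bins
    scheme = scheme or DEFAULT_SCHEME
    md = assign_time_bins(metadata, scheme).set_index("sample_id")
    calls = calls.copy()
    calls["time_bin"] = md.loc[calls["infant_sample"], "time_bin"].values
    calls["day"] = md.loc[calls["infant_sample"], "day"].values
    binned = calls[calls["time_bin"] != "unbinned"]

    prev = (
        binned.groupby(["species", "time_bin"])["shared"]
        .agg(prevalence="mean", n_evaluable="size")
        .reset_index()
    )
    keep = prev.groupby("species")["prevalence"].max()
    prev_display = prev[prev["species"].map(keep) >= display_min_prevalence]

    per_infant = (
        calls.groupby("infant_sample")
        .agg(n_shared=("shared", "sum"), day=("day", "first"))
        .reset_index()
    )
    trend = None
    if len(per_infant) >= 3 and per_infant["day"].nunique() > 1:
        fit = stats.linregress(per_infant["day"], per_infant["n_shared"])
        trend = {"slope": fit.slope, "intercept": fit.intercept, "p_value": fit.pvalue}
    return {"prevalence": prev, "prevalence_display": prev_display,
            "per_infant_counts": per_infant, "age_trend": trend}


def shared_vs_nonshared_function_contrast(
    calls: pd.DataFrame,
    stratified_pathways,
    metadata: pd.DataFrame,
    species_token_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Compare per-infant pathway abundance attributed to shared vs non-shared
    species, per pathway, with a study-blocked Wilcoxon test.

    ``stratified_pathways`` is an AbundanceTable whose rows carry the
    ``|g__X.s__Y`` species suffix; ``species_token_map`` maps the ``s__``
    token (e.g. ``Escherichia_coli``) to the species key used in ``calls``.
    """
    strat = stratified_pathways.values
    rows = [i for i in strat.index if "|" in i]
    if not rows:
        logger.warning("no stratified pathway rows; contrast skipped")
        return pd.DataFrame(columns=["pathway", "statistic", "p_value", "q_value",
                                     "mean_shared", "mean_nonshared"])
    md = metadata.set_index("sample_id")
    # shared status per (infant_sample, species): any shared call
    status = calls.groupby(["infant_sample", "species"])["shared"].any()

    def token_of(row_id: str) -> str:
        suffix = row_id.split("|", 1)[1]
        return suffix.split("s__")[-1]

    records = []
    for row_id in rows:
        pwy = row_id.split("|", 1)[0]
        token = token_of(row_id)
        species = (species_token_map or {}).get(token, token)
        for sample in strat.columns:
            key = (sample, species)
            if key not in status.index:
                continue
            records.append({
                "pathway": pwy, "infant_sample": sample,
                "group": "shared" if status[key] else "nonshared",
                "abundance": float(strat.at[row_id, sample]),
            })
    long = pd.DataFrame(records)
    out = []
    for pwy, grp in long.groupby("pathway"):
        if grp["group"].nunique() < 2:
            continue
        blocks = md.loc[grp["infant_sample"], "study_id"].values
        res = blocked_wilcoxon(grp["abundance"].values,
                               (grp["group"] == "shared").values, blocks)
        out.append({
            "pathway": pwy, "statistic": res.statistic, "p_value": res.p_value,
            "mean_shared": grp.loc[grp["group"] == "shared", "abundance"].mean(),
            "mean_nonshared": grp.loc[grp["group"] == "nonshared", "abundance"].mean(),
        })
    res_df = pd.DataFrame(out, columns=["pathway", "statistic", "p_value",
                                        "mean_shared", "mean_nonshared"])
    if len(res_df):
        res_df["q_value"] = bh_fdr(res_df["p_value"].values)
    else:
        res_df["q_value"] = []
    return res_df
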