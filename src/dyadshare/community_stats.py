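"""Community-level statistics: diversity, Bray-Curtis, PCoA, stratified
(blocked) rank tests, BH FDR, differential abundance and PERMANOVA.

The blocked two-group test is the van Elteren form of the Wilcoxon rank-sum
test: within each block (study) the rank-sum of group 1 is centered and its
tie-corrected permutation variance accumulated, and the block sums are
combined into one standardized statistic.  The k-group version is the
stratified Kruskal-Wallis chi-square built from the same within-block rank
moments.  PERMANOVA follows the adonis partition of a distance matrix with
an unrestricted label-permutation null and the (1 + exceedances)/(1 + n_perm)
convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("dyadshare")


@dataclass
class TestResult:
    feature_id: str
    statistic: float
    p_value: float
    q_value: float | None = None
    direction: str | None = None  # group whose mean is higher


@dataclass
class PermanovaResult:
    covariate: str
    time_bin: str | None
    r_squared: float
    pseudo_f: float
    p_value: float
    q_value: float | None
    n_samples: int


# ---------------------------------------------------------------------------
# Diversity and dissimilarity
# ---------------------------------------------------------------------------

def alpha_diversity(profile, metric: str = "shannon") -> float:
    """Alpha diversity of one abundance vector.

    richness = count of features > 0; shannon = -sum p ln p (natural log);
    simpson = Gini-Simpson 1 - sum p^2.  All-zero profiles have richness 0
    and diversity 0 by convention.
    """
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    if metric == "richness":
        return float((x > 0).sum())
    total = x.sum()
    if total == 0:
        return 0.0
    p = x[x > 0] / total
    if metric == "shannon":
        return float(-(p * np.log(p)).sum())
    if metric == "simpson":
        return float(1.0 - (p ** 2).sum())
    raise ValueError(f"unknown metric {metric!r}")


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity sum|p-q| / sum(p+q), in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("unequal lengths")
    if p.sum() == 0 and q.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(braycurtis(p, q))


def bray_curtis_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis between the columns (samples) of a table."""
    x = values.values.T
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
    den = (x[:, None, :] + x[None, :, :]).sum(-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den == 0, 1, den), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def pcoa(distance_matrix: pd.DataFrame, k: int | None = None):
    """Classical MDS (PCoA) of a symmetric zero-diagonal distance matrix.

    Returns (coordinates DataFrame, eigenvalue Series).  All eigenvalues are
    reported; axes with negative eigenvalues are dropped from the
    coordinates.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    ids = list(distance_matrix.index) if isinstance(distance_matrix, pd.DataFrame) \
        else [str(i) for i in range(d.shape[0])]
    res = _skbio_pcoa(d, number_of_dimensions=0)
    eigvals = pd.Series(res.eigvals.values, name="eigenvalue")
    pos = np.flatnonzero(eigvals.values > 1e-12)
    coords = pd.DataFrame(res.samples.values, index=ids, columns=res.samples.columns)
    coords = coords.iloc[:, pos]
    if k is not None:
        coords = coords.iloc[:, :k]
    return coords, eigvals


# ---------------------------------------------------------------------------
# Blocked rank tests (van Elteren / stratified Kruskal-Wallis)
# ---------------------------------------------------------------------------

def _block_rank_moments(values, groups, blocks, group_levels):
    """Per-block mid-rank sums per group plus permutation moments.

    For block b with N_b samples and mid-rank variance
    S2_b = sum (r_i - rbar)^2 / (N_b - 1), simple random sampling gives
    E[R_g] = n_g rbar, Var(R_g) = n_g (N_b - n_g)/N_b S2_b and
    Cov(R_g, R_h) = -n_g n_h / N_b S2_b.
    """
    k = len(group_levels)
    S = np.zeros(k)
    cov = np.zeros((k, k))
    for b in np.unique(blocks):
        m = blocks == b
        v, g = values[m], groups[m]
        n_b = len(v)
        present = [lvl for lvl in group_levels if (g == lvl).any()]
        if n_b < 2 or len(present) < 2:
            continue  # single-group blocks carry no information
        r = stats.rankdata(v)
        rbar = r.mean()
        s2 = ((r - rbar) ** 2).sum() / (n_b - 1)
        for gi, lvl in enumerate(group_levels):
            n_g = int((g == lvl).sum())
            if n_g == 0:
                continue
            S[gi] += r[g == lvl].sum() - n_g * rbar
            cov[gi, gi] += n_g * (n_b - n_g) / n_b * s2
            for hj, lvl2 in enumerate(group_levels):
                if hj != gi and (g == lvl2).any():
                    n_h = int((g == lvl2).sum())
                    cov[gi, hj] += -n_g * n_h / n_b * s2
    return S, cov


def _multiset_permutations(items):
    """Distinct orderings of a label multiset."""
    items = sorted(items)
    if len(items) <= 1:
        yield tuple(items)
        return
    seen = set()
    for i, it in enumerate(items):
        if it in seen:
            continue
        seen.add(it)
        rest = items[:i] + items[i + 1:]
        for tail in _multiset_permutations(rest):
            yield (it,) + tail


def _exact_enumeration(values, groups, blocks, group_levels, stat_fn, max_outcomes=2_000_000):
    """Exhaustive within-block permutation distribution of ``stat_fn``."""
    block_ids = np.unique(blocks)
    per_block = []
    total = 1
    for b in block_ids:
        m = np.where(blocks == b)[0]
        perms = list(_multiset_permutations(list(groups[m])))
        per_block.append((m, perms))
        total *= len(perms)
        if total > max_outcomes:
            raise ValueError(f"exact enumeration too large (> {max_outcomes} outcomes)")
    obs = stat_fn(groups)
    count = 0
    n = 0
    g_work = groups.copy()
    for combo in itertools.product(*[p for _, p in per_block]):
        for (m, _), assignment in zip(per_block, combo):
            g_work[m] = assignment
        t = stat_fn(g_work)
        if t >= obs - 1e-12:
            count += 1
        n += 1
    return count / n


def blocked_wilcoxon(values, group_labels, block_labels, exact: bool = False) -> TestResult:
    """Two-group van Elteren (study-blocked Wilcoxon) test.

    With a single block this reduces to the standard tie-corrected two-sided
    Wilcoxon rank-sum normal approximation.  ``exact=True`` replaces the
    normal p by the exhaustive within-block permutation p of |Z|.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    blocks = np.asarray(block_labels)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    for lvl in levels:
        if not (groups == lvl).any():
            raise ValueError(f"group {lvl!r} empty")
    S, cov = _block_rank_moments(values, groups, blocks, levels)
    var = cov[0, 0]
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = S[0] / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    if exact:
        def stat_fn(g):
            s, c = _block_rank_moments(values, g, blocks, levels)
            return abs(s[0])

        p = _exact_enumeration(values, groups.copy(), blocks, levels, stat_fn)
    means = [values[groups == lvl].mean() for lvl in levels]
    direction = str(levels[int(np.argmax(means))])
    return TestResult("", float(z), float(min(p, 1.0)), None, direction)


def blocked_kruskal_wallis(values, group_labels, block_labels, exact: bool = False) -> TestResult:
    """Stratified Kruskal-Wallis chi-square test for >= 2 groups.

    With two groups the chi-square statistic is the square of the blocked
    Wilcoxon Z, so the p-values coincide.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    blocks = np.asarray(block_labels)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    S, cov = _block_rank_moments(values, groups, blocks, levels)

    def chi2_stat(g):
        s, c = _block_rank_moments(values, g, blocks, levels)
        cinv = np.linalg.pinv(c)
        return float(s @ cinv @ s)

    if not np.any(np.abs(cov) > 0):
        stat, p = 0.0, 1.0
    else:
        stat = float(S @ np.linalg.pinv(cov) @ S)
        df = len(levels) - 1
        p = float(stats.chi2.sf(stat, df))
        if stat < 1e-12:
            p = 1.0
    if exact:
        p = _exact_enumeration(values, groups.copy(), blocks, levels, chi2_stat)
    means = [values[groups == lvl].mean() for lvl in levels]
    direction = str(levels[int(np.argmax(means))])
    return TestResult("", stat, min(p, 1.0), None, direction)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

def differential_abundance(
    table,
    metadata: pd.DataFrame,
    grouping: str = "role",
    block: str = "study_id",
    report_min_prevalence: float | None = None,
    report_min_mean_abundance: float | None = None,
) -> pd.DataFrame:
    """Per-feature blocked Wilcoxon tests between two groups, BH across all
    tested features.

    All features are tested; the prevalence/abundance filters, when given,
    flag rows for reporting only (``reportable`` column) after the FDR is
    computed over the full tested set.
    """
    md = metadata.set_index("sample_id")
    samples = [s for s in table.sample_ids if s in md.index]
    groups = md.loc[samples, grouping].values
    blocks = md.loc[samples, block].values
    if len(np.unique(groups)) != 2:
        raise ValueError("grouping must have exactly 2 levels")
    sub = table.values[samples]
    rows = []
    for feat in sub.index:
        v = sub.loc[feat].values.astype(float)
        res = blocked_wilcoxon(v, groups, blocks)
        g1, g2 = np.unique(groups)
        rows.append({
            "feature_id": feat, "statistic": res.statistic, "p_value": res.p_value,
            "direction": res.direction,
            f"mean_{g1}": v[groups == g1].mean(), f"mean_{g2}": v[groups == g2].mean(),
        })
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].values)
    if report_min_prevalence is not None or report_min_mean_abundance is not None:
        prev = (sub > 0).mean(axis=1)
        mean_ab = sub.mean(axis=1)
        ok = pd.Series(True, index=sub.index)
        if report_min_prevalence is not None:
            ok &= prev >= report_min_prevalence
        if report_min_mean_abundance is not None:
            ok &= mean_ab > report_min_mean_abundance
        out["reportable"] = ok.loc[out["feature_id"]].values
    return out


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    distance_matrix: pd.DataFrame,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
    covariate: str = "",
    time_bin: str | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix (adonis-style partition).

    pseudo-F = (SS_between/df_b) / (SS_within/df_w); R^2 = SS_between/SS_total;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under unrestricted label
    permutation.
    """
    d = np.asarray(distance_matrix, dtype=float)
    labels = pd.Series(list(labels))
    codes, levels = pd.factorize(labels)
    k = len(levels)
    n = len(labels)
    if k < 2:
        raise ValueError("labels must form >= 2 groups")
    if d.shape != (n, n):
        raise ValueError("distance matrix / labels size mismatch")
    d2 = d ** 2
    ss_total, ss_within = _permanova_ss(d2, codes, k)
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    if df_w <= 0 or ss_within <= 0:
        f_obs = np.inf if ss_between > 0 else 0.0
    else:
        f_obs = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        sst, ssw = _permanova_ss(d2, perm, k)
        ssb = sst - ssw
        f_perm = (ssb / df_b) / (ssw / df_w) if ssw > 0 else np.inf
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(covariate, time_bin, float(r2), float(f_obs), float(p),
                           None, n)


def covariate_variance_scan(
    shared_species_table,
    metadata: pd.DataFrame,
    scheme=None,
    covariates=None,
    roles=("infant",),
    n_perm: int = 1000,
    seed: int | None = None,
    min_bin_samples: int = 6,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Univariate PERMANOVA (Bray-Curtis of the shared-species subtable) per
    time bin x covariate, BH-corrected across the scan.

    Samples missing the covariate are dropped per test; a covariate with any
    group smaller than ``min_group_size`` is excluded in that bin; bins with
    fewer than ``min_bin_samples`` samples are skipped with a warning.
    """
    from .profiles_io import COVARIATES, DEFAULT_SCHEME, assign_time_bins
    scheme = scheme or DEFAULT_SCHEME
    covariates = list(covariates) if covariates is not None else list(COVARIATES)
    md = assign_time_bins(metadata, scheme)
    md = md[md["role"].isin(roles) & (md["time_bin"] != "unbinned")]
    md = md[md["sample_id"].isin(shared_species_table.sample_ids)]
    results = []
    for time_bin, bin_md in md.groupby("time_bin", sort=False):
        if len(bin_md) < min_bin_samples:
            logger.warning("variance scan: bin %s skipped (%d samples)", time_bin, len(bin_md))
            continue
        samples = list(bin_md["sample_id"])
        dm = bray_curtis_matrix(shared_species_table.values[samples])
        for cov in covariates:
            lab = bin_md.set_index("sample_id")[cov].replace("", np.nan)
            ok = lab.notna()
            lab = lab[ok]
            counts = lab.value_counts()
            if len(counts) < 2:
                continue
            if (counts < min_group_size).any():
                logger.info("variance scan: %s excluded in %s (group < %d)",
                            cov, time_bin, min_group_size)
                continue
            keep = list(lab.index)
            res = permanova(dm.loc[keep, keep], lab.values, n_perm=n_perm,
                            seed=seed, covariate=cov, time_bin=time_bin)
            results.append(res)
    out = pd.DataFrame([{
        "covariate": r.covariate, "time_bin": r.time_bin, "r_squared": r.r_squared,
        "pseudo_f": r.pseudo_f, "p_value": r.p_value, "n_samples": r.n_samples,
    } for r in results])
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].values)
    return out
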