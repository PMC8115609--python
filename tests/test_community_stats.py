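import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dyadshare as ds
from dyadshare.community_stats import (alpha_diversity, bh_fdr,
                                       blocked_kruskal_wallis, blocked_wilcoxon,
                                       bray_curtis, bray_curtis_matrix,
                                       differential_abundance, pcoa, permanova)


@pytest.mark.parametrize("profile,metric,expected", [
    ((0.5, 0.5), "shannon", np.log(2)),
    ((0.25,) * 4, "simpson", 0.75),
    ((0.6, 0.3, 0.1), "shannon",
     -(0.6 * np.log(0.6) + 0.3 * np.log(0.3) + 0.1 * np.log(0.1))),
    ((1.0, 2.0, 0.0, 3.0), "richness", 3),
    ((0.0, 0.0), "shannon", 0.0),
    ((0.0, 0.0), "richness", 0),
])
def test_alpha_diversity(profile, metric, expected):
    assert alpha_diversity(profile, metric) == pytest.approx(expected)


def test_bray_curtis_examples_and_properties():
    assert bray_curtis([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)
    assert bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)
    assert bray_curtis([0.6, 0.4, 0], [0.2, 0.3, 0.5]) == pytest.approx(0.5)
    rng = np.random.default_rng(0)
    for _ in range(50):
        p, q = rng.random(8), rng.random(8)
        d = bray_curtis(p, q)
        assert 0 <= d <= 1
        assert d == pytest.approx(bray_curtis(q, p))
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [0, 0])


def test_bray_curtis_matrix_matches_scalar():
    rng = np.random.default_rng(1)
    vals = pd.DataFrame(rng.random((5, 6)), columns=list("abcdef"))
    m = bray_curtis_matrix(vals)
    for i, j in itertools.combinations(vals.columns, 2):
        assert m.loc[i, j] == pytest.approx(bray_curtis(vals[i], vals[j]))


def test_pcoa_preserves_euclidean_distances():
    rng = np.random.default_rng(2)
    pts = rng.random((7, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    coords, eig = pcoa(pd.DataFrame(d))
    rec = np.sqrt(((coords.values[:, None] - coords.values[None]) ** 2).sum(-1))
    np.testing.assert_allclose(rec, d, atol=1e-9)


def test_pcoa_small_cases():
    coords, eig = pcoa(pd.DataFrame([[0.0, 2.0], [2.0, 0.0]]))
    np.testing.assert_allclose(np.sort(coords.values.ravel()), [-1.0, 1.0], atol=1e-9)
    _, eig3 = pcoa(pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)))
    top2 = np.sort(eig3.values)[-2:]
    assert top2[0] == pytest.approx(top2[1])
    assert (top2 > 0).all()
    with pytest.raises(ValueError):
        pcoa(pd.DataFrame([[0.0, 1.0], [2.0, 0.0]]))


def test_blocked_wilcoxon_single_block_matches_rank_sum():
    rng = np.random.default_rng(3)
    v = rng.random(24)
    v[5] = v[6]  # ties exercise the mid-rank correction
    g = np.array([0] * 12 + [1] * 12)
    res = blocked_wilcoxon(v, g, np.zeros(24))
    ref = stats.mannwhitneyu(v[g == 0], v[g == 1], alternative="two-sided",
                             use_continuity=False, method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_blocked_wilcoxon_identical_groups():
    # exactly mirrored group values within each block
    v = np.array([1, 2, 3, 1, 2, 3, 4, 5, 4, 5], float)
    g = np.array([0, 0, 0, 1, 1, 1, 0, 1, 1, 0])
    b = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1])
    res = blocked_wilcoxon(v, g, b)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def _van_elteren_numerator(v, g, b, level):
    t = 0.0
    for blk in np.unique(b):
        m = b == blk
        r = stats.rankdata(v[m])
        n1 = (g[m] == level).sum()
        t += r[g[m] == level].sum() - n1 * r.mean()
    return t


def test_blocked_wilcoxon_exact_matches_enumeration_oracle():
    """Exact option reproduces the exhaustive within-block permutation p."""
    rng = np.random.default_rng(4)
    v = np.round(rng.random(16), 3)
    g = np.array(([0] * 4 + [1] * 4) * 2)
    b = np.repeat([0, 1], 8)
    p = blocked_wilcoxon(v, g, b, exact=True).p_value
    obs = abs(_van_elteren_numerator(v, g, b, 0))
    count = total = 0
    for c1 in itertools.combinations(range(8), 4):
        for c2 in itertools.combinations(range(8), 4):
            gp = np.ones(16, int)
            gp[list(c1)] = 0
            gp[[8 + i for i in c2]] = 0
            total += 1
            if abs(_van_elteren_numerator(v, gp, b, 0)) >= obs - 1e-12:
                count += 1
    assert p == pytest.approx(count / total, abs=1e-9)


def test_blocked_kruskal_two_groups_equals_wilcoxon():
    rng = np.random.default_rng(5)
    v = rng.random(20)
    g = rng.integers(0, 2, 20)
    b = np.zeros(20)
    pw = blocked_wilcoxon(v, g, b).p_value
    pk = blocked_kruskal_wallis(v, g, b).p_value
    assert pk == pytest.approx(pw, abs=1e-9)


def test_blocked_kruskal_three_groups_exact_oracle():
    rng = np.random.default_rng(6)
    v = rng.random(9)
    g = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
    b = np.zeros(9)
    p_exact = blocked_kruskal_wallis(v, g, b, exact=True).p_value
    # oracle: permutation distribution of the standard KW H statistic
    obs = stats.kruskal(v[g == 0], v[g == 1], v[g == 2]).statistic
    count = total = 0
    for perm in set(itertools.permutations(g)):
        gp = np.array(perm)
        h = stats.kruskal(v[gp == 0], v[gp == 1], v[gp == 2]).statistic
        total += 1
        if h >= obs - 1e-12:
            count += 1
    assert p_exact == pytest.approx(count / total, abs=1e-9)


def test_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(7)
    v = rng.random(30)
    g = rng.integers(0, 2, 30)
    b = rng.integers(0, 3, 30)
    p1 = blocked_wilcoxon(v, g, b).p_value
    p2 = blocked_wilcoxon(np.exp(5 * v), g, b).p_value
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_bh_fdr_examples():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    np.testing.assert_allclose(bh_fdr([0.37]), [0.37])
    q = bh_fdr([0.5, 0.001, 0.04, 0.9])
    assert (q >= [0.5, 0.001, 0.04, 0.9]).all()


def test_differential_abundance_constructed_effect(cohort):
    """A feature 10x higher in infants in every study comes out significant
    with infant direction."""
    table = cohort.species_table
    md = cohort.metadata
    vals = table.values.copy()
    boost = md.set_index("sample_id")["role"] == "infant"
    vals.iloc[0] = np.where(boost[vals.columns], 10.0, 1.0)
    res = differential_abundance(ds.AbundanceTable(vals, "taxon"), md)
    row = res[res["feature_id"] == vals.index[0]].iloc[0]
    assert row["q_value"] < 0.05
    assert row["direction"] == "infant"


def test_permanova_separated_clusters():
    rng = np.random.default_rng(8)
    pts = np.vstack([rng.normal(0, 0.05, (12, 3)), rng.normal(5, 0.05, (12, 3))])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = ["a"] * 12 + ["b"] * 12
    res = permanova(pd.DataFrame(d), labels, n_perm=1000, seed=1)
    assert res.p_value == pytest.approx(1 / 1001)
    assert res.r_squared > 0.9


def test_permanova_duplicated_groups_null():
    rng = np.random.default_rng(9)
    pts = rng.random((10, 3))
    pts = np.vstack([pts, pts])  # group b duplicates group a exactly
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = ["a"] * 10 + ["b"] * 10
    res = permanova(pd.DataFrame(d), labels, n_perm=500, seed=2)
    assert res.r_squared < 0.05
    assert res.p_value > 0.5


def test_permanova_pseudo_f_matches_skbio():
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as sk_permanova
    rng = np.random.default_rng(10)
    pts = np.vstack([rng.normal(0, 1, (9, 3)), rng.normal(1, 1, (11, 3))])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = ["a"] * 9 + ["b"] * 11
    mine = permanova(pd.DataFrame(d), labels, n_perm=99, seed=0)
    theirs = sk_permanova(DistanceMatrix(d), labels, permutations=99)
    assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)
    assert 0 <= mine.r_squared <= 1


def test_permanova_single_group_raises():
    d = pd.DataFrame(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        permanova(d, ["a"] * 4)


def test_variance_scan_excludes_small_groups(cohort):
    md = cohort.metadata.copy()
    # force a covariate level with only two samples
    md["rare_cov"] = "common"
    md.loc[md.index[:2], "rare_cov"] = "rare"
    scan = ds.covariate_variance_scan(cohort.species_table, md,
                                      covariates=["rare_cov"], n_perm=20, seed=0)
    assert scan.empty
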