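import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import dyadshare as ds
from dyadshare.strain_analysis import (HaplotypeAlignment, StrainTree,
                                       _patristic_matrix, call_transmission,
                                       haplotype_similarity,
                                       intra_subject_heterogeneity, nj_tree,
                                       normalized_strain_distance,
                                       p_distance_matrix, patristic_distance,
                                       shared_strain_dynamics)
from dyadshare.synthetic_cohort import (CohortConfig, default_pathway_map,
                                        default_species_pool)


def test_haplotype_similarity_examples():
    assert haplotype_similarity("A" * 100, "A" * 100) == 1.0
    assert haplotype_similarity("AAAT", "AAAA") == 0.75
    # 100 sites, 2 gap columns, 3 mismatches among the 98 comparable
    a = list("A" * 100)
    b = list("A" * 100)
    a[0] = "-"
    b[1] = "-"
    for i in (10, 20, 30):
        b[i] = "C"
    assert haplotype_similarity("".join(a), "".join(b)) == pytest.approx(95 / 98)


def test_haplotype_similarity_no_comparable_positions():
    with pytest.warns(UserWarning):
        assert np.isnan(haplotype_similarity("--", "AA".replace("A", "-")))


def test_p_distance_matrix_matches_double_loop():
    rng = np.random.default_rng(0)
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT-"), 60)) for i in range(6)}
    aln = HaplotypeAlignment("x", seqs)
    m = p_distance_matrix(aln)
    for a, b in itertools.combinations(seqs, 2):
        expected = 1 - haplotype_similarity(seqs[a], seqs[b])
        assert m.loc[a, b] == pytest.approx(expected, abs=1e-12)
    assert (np.diag(m.values) == 0).all()
    assert m.loc["s0", "s1"] == m.loc["s1", "s0"]


def test_nj_recovers_additive_four_taxon_matrix():
    # tree ((A:1,B:2):1,(C:3,D:4):1)
    D = pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float)
    tree = nj_tree(D, "toy")
    for a, b in itertools.combinations("ABCD", 2):
        assert patristic_distance(tree, a, b) == pytest.approx(D.loc[a, b], abs=1e-9)


def test_nj_three_taxa_three_point_formula():
    D = pd.DataFrame([[0, 4, 6], [4, 0, 8], [6, 8, 0]],
                     index=list("ABC"), columns=list("ABC"), dtype=float)
    tree = nj_tree(D, "toy")
    for a, b in itertools.combinations("ABC", 2):
        assert patristic_distance(tree, a, b) == pytest.approx(D.loc[a, b], abs=1e-9)


def test_nj_two_taxa_cherry():
    D = pd.DataFrame([[0, 3.0], [3.0, 0]], index=["A", "B"], columns=["A", "B"])
    tree = nj_tree(D, "toy")
    assert patristic_distance(tree, "A", "B") == pytest.approx(3.0)


def test_patristic_examples():
    tree = StrainTree.from_newick("toy", "((A:1,B:2):1,C:3);")
    assert patristic_distance(tree, "A", "C") == pytest.approx(5.0)
    assert patristic_distance(tree, "A", "A") == 0.0
    with pytest.raises(Exception):
        patristic_distance(tree, "A", "nope")


def test_normalized_strain_distance():
    tree = StrainTree.from_newick("toy", "((A:1,B:2):1,C:3);")
    # pairwise distances 3, 5, 6 -> max normalizer 6
    assert normalized_strain_distance(tree, "A", "C") == pytest.approx(5 / 6)
    assert normalized_strain_distance(tree, "B", "C") == pytest.approx(1.0)
    zero = StrainTree.from_newick("toy", "((A:0,B:0):0,C:0);")
    assert normalized_strain_distance(zero, "A", "C") == 0.0


def test_call_boundary_is_strict_at_threshold():
    """A pair at a normalized distance of exactly the 0.1 threshold is NOT
    called shared."""
    tree = StrainTree.from_newick("sp", "(M:0.05,I:0.05,X:0.95);")
    dist = _patristic_matrix(tree)
    assert dist.loc["M", "I"] == pytest.approx(0.1)
    aln = HaplotypeAlignment("sp", {"M": "ACGT", "I": "ACGT", "X": "ACGT"})
    pairing = pd.DataFrame([{"dyad_id": "D1", "mother_sample": "M",
                             "infant_sample": "I"}])
    calls = call_transmission({"sp": aln}, pairing, trees={"sp": tree})
    assert len(calls) == 1
    assert calls.iloc[0]["normalized_distance"] == pytest.approx(0.1)
    assert not calls.iloc[0]["shared"]
    below = call_transmission({"sp": aln}, pairing, trees={"sp": tree},
                              threshold=0.1000001)
    assert below.iloc[0]["shared"]


def test_call_threshold_monotonicity(cohort, pairing):
    calls_lo = call_transmission(cohort.alignments, pairing, threshold=0.05)
    calls_hi = call_transmission(cohort.alignments, pairing, threshold=0.1)
    assert calls_lo["shared"].sum() <= calls_hi["shared"].sum()


def test_no_call_when_species_absent(cohort, pairing):
    calls = call_transmission(cohort.alignments, pairing)
    aln_samples = {sp: set(a.sample_ids) for sp, a in cohort.alignments.items()}
    for row in calls.itertuples(index=False):
        assert row.mother_sample in aln_samples[row.species]
        assert row.infant_sample in aln_samples[row.species]


def test_zero_transmission_low_false_positive_rate():
    pool = [replace(s, transmission_prob=0.0) for s in default_species_pool()]
    cfg = CohortConfig(n_studies=2, dyads_per_study=25, species_pool=tuple(pool),
                       pathway_map=default_pathway_map(pool), seed=13)
    cohort = ds.generate_cohort(cfg)
    pairing = ds.pair_dyads(cohort.metadata)
    calls = call_transmission(cohort.alignments, pairing)
    assert len(calls) > 50
    assert calls["shared"].mean() <= 0.05


def test_intra_subject_heterogeneity_constructed_effect():
    """Mothers with strain replacement show lower within-subject similarity
    than infants with none."""
    cfg = CohortConfig(n_studies=2, dyads_per_study=25,
                       species_pool=default_species_pool(),
                       pathway_map=default_pathway_map(default_species_pool()),
                       seed=21, mother_strain_replacement_prob=0.5,
                       infant_strain_replacement_prob=0.0)
    cohort = ds.generate_cohort(cfg)
    long, tests = intra_subject_heterogeneity(cohort.alignments, cohort.metadata)
    assert len(tests) > 0
    assert (tests["mean_infant"] >= tests["mean_mother"]).all()
    assert (tests["q_value"] < 0.05).any()
    # comparison counts match a brute-force recount for one species
    species = tests.iloc[0]["species"]
    aln = cohort.alignments[species]
    md = cohort.metadata.set_index("sample_id")
    n = 0
    subjects = {}
    for s in aln.sample_ids:
        subjects.setdefault(md.at[s, "subject_id"], []).append(s)
    for subj, samples in subjects.items():
        n += len(samples) * (len(samples) - 1) // 2
    assert len(long[long["species"] == species]) == n


def test_heterogeneity_identical_haplotypes_nonsignificant():
    pool = [replace(s, within_strain_mut_rate=0.0) for s in default_species_pool()]
    cfg = CohortConfig(n_studies=1, dyads_per_study=15, species_pool=tuple(pool),
                       pathway_map=default_pathway_map(pool), seed=3,
                       mother_strain_replacement_prob=0.0)
    cohort = ds.generate_cohort(cfg)
    long, tests = intra_subject_heterogeneity(cohort.alignments, cohort.metadata)
    assert (long["similarity"] == 1.0).all()
    if len(tests):
        assert (tests["p_value"] == 1.0).all()


def test_shared_strain_dynamics_recount(cohort, pairing):
    calls = call_transmission(cohort.alignments, pairing)
    dyn = shared_strain_dynamics(calls, cohort.metadata)
    md = ds.assign_time_bins(cohort.metadata).set_index("sample_id")
    calls = calls.copy()
    calls["time_bin"] = md.loc[calls["infant_sample"], "time_bin"].values
    for _, row in dyn["prevalence"].iterrows():
        grp = calls[(calls["species"] == row["species"]) &
                    (calls["time_bin"] == row["time_bin"])]
        assert row["n_evaluable"] == len(grp)
        assert row["prevalence"] == pytest.approx(grp["shared"].mean())
    assert dyn["age_trend"] is not None


def test_all_shared_config_prevalence_one():
    """With universal transmission every evaluable call is shared.

    Species whose alignment spans a single lineage are excluded: max-pair
    normalization needs between-strain diversity on the tree to give the
    fixed threshold an absolute scale (a documented limitation).
    """
    pool = [replace(s, transmission_prob=1.0, prevalence_infant_base=0.0)
            for s in default_species_pool()]
    cfg = CohortConfig(n_studies=2, dyads_per_study=20, species_pool=tuple(pool),
                       pathway_map=default_pathway_map(pool), seed=5)
    cohort = ds.generate_cohort(cfg)
    pairing = ds.pair_dyads(cohort.metadata)
    ident = cohort.ground_truth.strain_identity
    diverse = {sp for sp, aln in cohort.alignments.items()
               if len({ident[(s, sp)] for s in aln.sample_ids}) >= 2}
    calls = call_transmission(cohort.alignments, pairing)
    dyn = shared_strain_dynamics(calls[calls["species"].isin(diverse)],
                                 cohort.metadata)
    assert len(dyn["prevalence"]) > 0
    assert (dyn["prevalence"]["prevalence"] > 0.99).all()


def test_function_contrast_constructed_effect(cohort, pairing):
    calls = call_transmission(cohort.alignments, pairing)
    token_map = {sp.species_token: sp.name for sp in cohort.config.species_pool}
    res = ds.shared_vs_nonshared_function_contrast(
        calls, cohort.pathway_table, cohort.metadata, species_token_map=token_map)
    assert {"pathway", "p_value", "q_value"} <= set(res.columns)
    # category sums recount for one pathway row
    strat_rows = [i for i in cohort.pathway_table.values.index if "|" in i]
    assert strat_rows
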