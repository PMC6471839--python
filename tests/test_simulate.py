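"""Synthetic-data generator: taxonomy, digestion, PSM and 16S sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import metaproteo as mp
from metaproteo.simulate import (CommunitySpec, build_taxonomy, digest,
                                 default_community, make_pathway_table,
                                 sample_16s, sample_psms,
                                 synthesize_proteomes)
from metaproteo.pipeline import simulate_inputs


# ---------------------------------------------------------------- taxonomy

def test_minimal_taxonomy_has_one_node_per_rank():
    tree = build_taxonomy(1, 1, 1, seed=0)
    assert len(tree) == 1
    lin = tree[0]
    assert len({lin.family, lin.genus, lin.species, lin.strain}) == 4


def test_taxonomy_product_counts_and_unique_ancestry():
    tree = build_taxonomy(2, 2, 2, seed=1)
    assert len(tree) == 8
    assert len({t.species for t in tree}) == 4
    assert len({t.genus for t in tree}) == 2
    # every strain has exactly one ancestor per rank
    by_strain = {}
    for lin in tree:
        assert lin.strain not in by_strain
        by_strain[lin.strain] = lin


def test_taxonomy_deterministic():
    assert build_taxonomy(3, 2, 2, seed=7) == build_taxonomy(3, 2, 2, seed=7)


@pytest.mark.parametrize("args", [(0, 1, 1), (1, 0, 1), (1, 1, 0)])
def test_taxonomy_rejects_nonpositive_counts(args):
    with pytest.raises(ValueError):
        build_taxonomy(*args)


# ---------------------------------------------------------------- digestion

def _digest_oracle(seq, max_missed, min_len, max_len):
    """Brute force: enumerate cleavage points, then all site subsets."""
    cuts = [i + 1 for i in range(len(seq) - 1)
            if seq[i] in "KR" and seq[i + 1] != "P"]
    bounds = [0] + cuts + [len(seq)]
    frags = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
    out = set()
    for i in range(len(frags)):
        for j in range(i, min(i + max_missed + 1, len(frags))):
            pep = "".join(frags[i:j + 1])
            if min_len <= len(pep) <= max_len:
                out.add(pep)
    return out


def test_digest_two_cleavage_sites():
    ext = frozenset(set("ACDEFGHIKLMNPQRSTVWY") | {"B"})
    assert digest("AAKBBRCC", 0, 1, 10, alphabet=ext) == {"AAK", "BBR", "CC"}


def test_digest_no_cleavage_before_proline():
    ext = frozenset(set("ACDEFGHIKLMNPQRSTVWY") | {"B"})
    assert digest("AAKPBBR", 0, 1, 10, alphabet=ext) == {"AAKPBBR"}


def test_digest_missed_cleavage_matches_enumeration():
    ext = frozenset(set("ACDEFGHIKLMNPQRSTVWY") | {"B"})
    assert digest("AAKBBR", 1, 1, 10, alphabet=ext) == {"AAK", "BBR",
                                                        "AAKBBR"}


def test_digest_rejects_invalid_residues():
    with pytest.raises(ValueError, match="invalid residue"):
        digest("AAKZ1", 0, 1, 10)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(seq=st.text(alphabet="AKRPGLS", min_size=1, max_size=25),
       missed=st.integers(0, 3))
def test_digest_equals_bruteforce_enumeration(seq, missed):
    assert digest(seq, missed, 1, 50) == _digest_oracle(seq, missed, 1, 50)


# ---------------------------------------------------------------- proteomes

def test_proteome_count_conservation():
    tree = build_taxonomy(5, 2, 1, seed=0)  # 10 strains
    recs = synthesize_proteomes(tree, proteins_per_strain=5,
                                homolog_family_count=8,
                                gene_annotation_rate=0.5, seed=0,
                                n_host_proteins=0, host_family_count=1)
    targets = [r for r in recs if not r.is_decoy]
    decoys = [r for r in recs if r.is_decoy]
    assert len(targets) == 50 and len(decoys) == 50
    for t in targets:
        twin = next(d for d in decoys
                    if d.accession == "DECOY_" + t.accession)
        assert twin.sequence == t.sequence[::-1]


@pytest.mark.parametrize("rate,expect_any", [(0.0, False), (1.0, True)])
def test_gene_annotation_rate_boundaries(rate, expect_any):
    tree = build_taxonomy(2, 2, 2, seed=3)
    recs = synthesize_proteomes(tree, 4, 6, rate, seed=3,
                                n_host_proteins=0, host_family_count=1)
    microbial = [r for r in recs if not r.is_decoy and not r.is_host]
    if expect_any:
        assert all(r.gene_name for r in microbial)
    else:
        assert not any(r.gene_name for r in microbial)


def test_family_members_share_gene_name_and_high_identity():
    tree = build_taxonomy(3, 2, 2, seed=5)
    recs = synthesize_proteomes(tree, 6, 5, 1.0, seed=5,
                                n_host_proteins=0, host_family_count=1)
    by_family = {}
    for r in recs:
        if not r.is_decoy:
            by_family.setdefault(r.uniref50_id, []).append(r)
    for members in by_family.values():
        assert len({m.gene_name for m in members}) == 1
        for a, b in itertools.combinations(members[:4], 2):
            ident = sum(x == y for x, y in zip(a.sequence, b.sequence))
            assert ident / len(a.sequence) >= 0.6  # both mutated <=20%


def test_empty_taxonomy_rejected():
    with pytest.raises(ValueError):
        synthesize_proteomes([], 5, 5, 0.5, seed=0)


# ------------------------------------------------------------ PSM sampling

def _tiny_spec(**overrides):
    defaults = dict(subjects=["A"], profiles={"A": {}}, depth=500,
                    decoy_hit_rate=0.0, homolog_family_count=5,
                    proteins_per_strain=5, n_host_proteins=4,
                    host_family_count=2, seed=11)
    defaults.update(overrides)
    return CommunitySpec(**defaults)


def _tiny_setup(host_fraction, n_strains=4, decoy_hit_rate=0.0, depth=500,
                seed=11):
    tree = build_taxonomy(2, 2, 1, seed=seed)[:n_strains]
    abund = {lin.strain: 1.0 / n_strains for lin in tree}
    spec = _tiny_spec(profiles={"A": abund},
                      host_spectrum_fraction=host_fraction,
                      decoy_hit_rate=decoy_hit_rate, depth=depth, seed=seed)
    recs = synthesize_proteomes(tree, spec.proteins_per_strain,
                                spec.homolog_family_count,
                                0.5, seed, n_host_proteins=4,
                                host_family_count=2)
    return spec, tree, recs


def test_no_host_fraction_means_no_host_matches():
    spec, tree, recs = _tiny_setup(host_fraction=0.0)
    psms, _ = sample_psms(spec, recs, tree)
    db = mp.ProteinDatabase(recs)
    for p in psms["A"]:
        assert not any(db[a].is_host for a in p.matched_accessions)


def test_single_strain_community_maps_within_strain():
    tree = build_taxonomy(1, 1, 1, seed=2)
    spec = _tiny_spec(profiles={"A": {tree[0].strain: 1.0}},
                      host_spectrum_fraction=0.0)
    recs = synthesize_proteomes(tree, 5, 3, 0.5, seed=2,
                                n_host_proteins=2, host_family_count=1)
    psms, _ = sample_psms(spec, recs, tree)
    db = mp.ProteinDatabase(recs)
    for p in psms["A"]:
        strains = {db[a].lineage.strain for a in p.matched_accessions
                   if not db[a].is_decoy}
        assert strains == {tree[0].strain}


def test_psm_rows_equal_depth_exactly():
    spec, tree, recs = _tiny_setup(host_fraction=0.2, decoy_hit_rate=0.02)
    psms, _ = sample_psms(spec, recs, tree)
    assert len(psms["A"]) == spec.depth_for("A")


def test_host_spectra_within_binomial_interval():
    """At depth 1000 and host fraction 0.18, the host spectrum count must
    fall inside the analytic 99% binomial interval around 180."""
    spec, tree, recs = _tiny_setup(host_fraction=0.18, depth=1000,
                                   decoy_hit_rate=0.0)
    psms, _ = sample_psms(spec, recs, tree)
    db = mp.ProteinDatabase(recs)
    n_host = sum(1 for p in psms["A"]
                 if any(db[a].is_host for a in p.matched_accessions))
    lo, hi = stats.binom.interval(0.99, 1000, 0.18)
    assert lo <= n_host <= hi


def test_decoy_hits_score_low_and_match_only_decoys():
    spec, tree, recs = _tiny_setup(host_fraction=0.1, decoy_hit_rate=0.05,
                                   depth=2000)
    psms, _ = sample_psms(spec, recs, tree)
    db = mp.ProteinDatabase(recs)
    decoy_scores = [p.score for p in psms["A"]
                    if all(db[a].is_decoy for a in p.matched_accessions)]
    target_scores = [p.score for p in psms["A"]
                     if not all(db[a].is_decoy
                                for a in p.matched_accessions)]
    assert decoy_scores and target_scores
    assert np.mean(decoy_scores) < np.mean(target_scores)


def test_depth_zero_rejected():
    with pytest.raises(ValueError):
        _tiny_spec(profiles={"A": {"x": 1.0}}, depth=0)


# ------------------------------------------------------- truth and rollups

def test_truth_rollups_sum_across_ranks(small_study):
    ab = small_study.truth.abundances
    by_strain = {lin.strain: lin for lin in small_study.taxonomy}
    for fine, coarse in [("strain", "species"), ("species", "genus"),
                         ("genus", "family")]:
        if fine == "strain":
            mapping = {s: by_strain[s].species for s in ab["strain"].index}
        else:
            lookup = {getattr(l, fine): getattr(l, coarse)
                      for l in small_study.taxonomy}
            mapping = {t: lookup[t] for t in ab[fine].index}
        rolled = ab[fine].groupby(mapping).sum().sort_index()
        pd.testing.assert_frame_equal(rolled, ab[coarse],
                                      check_exact=False, atol=1e-12)


# ---------------------------------------------------------------- 16S

def test_16s_noiseless_limit_recovers_true_fractions():
    # tie-free random abundances: with no noise and deep sampling, read
    # fractions must converge to the true genus fractions in rank and value
    tree = build_taxonomy(8, 1, 1, seed=6)
    gen = np.random.default_rng(6)
    abund = gen.dirichlet(np.ones(len(tree)))
    spec = _tiny_spec(profiles={"A": {t.strain: float(a)
                                      for t, a in zip(tree, abund)}},
                      host_spectrum_fraction=0.0, depth=50, seed=6)
    recs = synthesize_proteomes(tree, 2, 4, 0.5, seed=6,
                                n_host_proteins=1, host_family_count=1)
    _, truth = sample_psms(spec, recs, tree)
    reads = sample_16s(truth, read_depth=300000, noise_sd_16s=0.0, seed=3)
    frac = reads / reads.sum(axis=0)
    true = truth.genus_matrix
    rho = stats.spearmanr(frac.to_numpy().ravel(),
                          true.to_numpy().ravel()).statistic
    assert rho >= 0.99
    assert (frac - true).abs().max().max() < 0.01


def test_16s_single_genus_gets_all_reads():
    tree = build_taxonomy(1, 1, 2, seed=4)
    spec = _tiny_spec(profiles={"A": {t.strain: 0.5 for t in tree}},
                      host_spectrum_fraction=0.0)
    recs = synthesize_proteomes(tree, 3, 2, 0.5, seed=4,
                                n_host_proteins=1, host_family_count=1)
    _, truth = sample_psms(spec, recs, tree)
    reads = sample_16s(truth, 1000, 0.5, seed=4)
    assert reads.shape[0] == 1
    assert int(reads.iloc[0, 0]) == 1000


def test_16s_reproducible_with_fixed_seed(small_study):
    a = sample_16s(small_study.truth, 5000, 0.3, seed=9)
    b = sample_16s(small_study.truth, 5000, 0.3, seed=9)
    pd.testing.assert_frame_equal(a, b)


# ----------------------------------------------------------- determinism

def test_identical_spec_and_seed_give_byte_identical_outputs(tmp_path):
    spec, tax = default_community(seed=13, depth=150,
                                  proteins_per_strain=4,
                                  homolog_family_count=10,
                                  n_host_proteins=4, host_family_count=2)
    simulate_inputs(spec, tax, tmp_path / "a")
    simulate_inputs(spec, tax, tmp_path / "b")
    for name in ["database.fasta", "psms_all.tsv", "reads_16s.tsv",
                 "pathways.tsv", "truth.json", "config.yaml"]:
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes(), name


def test_pathway_table_covers_characterized_genes(small_study):
    table = make_pathway_table(small_study.proteomes, seed=7)
    genes = {r.gene_name for r in small_study.proteomes
             if not r.is_decoy and not r.is_host
             and mp.is_characterized(r.gene_name)}
    assert set(table["gene_name"]) == genes
    assert table["pathway_id"].nunique() == 3


def test_spec_validation_rejects_bad_fractions():
    with pytest.raises(ValueError):
        _tiny_spec(profiles={"A": {"x": 0.6}})  # does not sum to 1
    with pytest.raises(ValueError):
        _tiny_spec(profiles={"A": {"x": 1.0}}, host_spectrum_fraction=1.0)
    with pytest.raises(ValueError):
        _tiny_spec(profiles={"A": {"x": 1.0}}, decoy_hit_rate=0.2)
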