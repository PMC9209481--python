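"""Context-normalized dN/dS: site enumeration, statistics, tests, FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from somaclone import (
    GeneModel,
    SpectrumPrior,
    annotate_mutations,
    bh_fdr,
    binomial_selection_test,
    enumerate_sites,
    expected_ns_ratio,
    generate_panel,
    global_dnds,
    run_selection,
    selection_excess_fraction,
    simulate_mutations,
    SimulationConfig,
)
from somaclone.selection import SiteCounts, pool_sites
from somaclone.simulate import panel_site_table, simulate_catalogue
from somaclone.spectrum import estimate_prior
from somaclone.trinuc import CLASS_INDEX, N_CLASSES


# --- independent brute-force site enumerator ----------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_sites(gene: GeneModel):
    """Brute-force enumeration with Biopython translation and a hand-rolled
    pyrimidine normalization, independent of the package's code paths."""
    syn = np.zeros(N_CLASSES)
    mis = np.zeros(N_CLASSES)
    non = np.zeros(N_CLASSES)
    stoploss = np.zeros(N_CLASSES)
    padded = gene.flank5 + gene.cds + gene.flank3
    p0 = str(Seq(gene.cds).translate())
    for i, ref in enumerate(gene.cds):
        ctx = padded[i : i + 3]
        for alt in "ACGT":
            if alt == ref:
                continue
            if ref in "AG":
                label = (
                    _COMP[ctx[2]] + "[" + _COMP[ref] + ">" + _COMP[alt] + "]" + _COMP[ctx[0]]
                )
            else:
                label = ctx[0] + "[" + ref + ">" + alt + "]" + ctx[2]
            k = CLASS_INDEX[label]
            p1 = str(Seq(gene.cds[:i] + alt + gene.cds[i + 1 :]).translate())
            if p0 == p1:
                syn[k] += 1
            else:
                (j,) = [x for x in range(len(p0)) if p0[x] != p1[x]]
                if p1[j] == "*":
                    non[k] += 1
                elif p0[j] == "*":
                    stoploss[k] += 1
                else:
                    mis[k] += 1
    return syn, mis, non, stoploss


def test_toy_gene_sites_match_oracle(toy_gene):
    sc = enumerate_sites(toy_gene)
    syn, mis, non, stoploss = oracle_sites(toy_gene)
    assert sc.total_sites() == 27
    np.testing.assert_array_equal(sc.syn, syn)
    np.testing.assert_array_equal(sc.mis, mis)
    np.testing.assert_array_equal(sc.non, non)
    np.testing.assert_array_equal(sc.stoploss, stoploss)


def test_site_conservation(small_panel):
    for gene in small_panel.values():
        sc = enumerate_sites(gene)
        assert sc.total_sites() == 3 * len(gene.cds)


def test_synonymous_recoding_changes_site_counts(toy_gene):
    """A codon-synonymous recoding yields different S_i/N_i, exactly as the
    oracle dictates for both sequences."""
    recoded = GeneModel("g1b", "ATGGAGTAA", "driver")  # GAA -> GAG (both Glu)
    for gene in (toy_gene, recoded):
        sc = enumerate_sites(gene)
        syn, mis, non, stoploss = oracle_sites(gene)
        np.testing.assert_array_equal(sc.syn, syn)
        np.testing.assert_array_equal(sc.nonsyn, mis + non + stoploss)
    assert not np.array_equal(enumerate_sites(toy_gene).syn, enumerate_sites(recoded).syn)


# --- expected ratio -----------------------------------------------------------

def test_expected_ratio_degenerate_prior(toy_gene):
    sc = enumerate_sites(toy_gene)
    j = next(i for i in range(N_CLASSES) if sc.syn[i] > 0 and sc.nonsyn[i] > 0)
    p = np.zeros(N_CLASSES)
    p[j] = 1.0
    assert expected_ns_ratio(sc, SpectrumPrior(p)) == pytest.approx(
        sc.nonsyn[j] / sc.syn[j]
    )


def test_expected_ratio_uniform_matches_direct_sum(toy_gene):
    sc = enumerate_sites(toy_gene)
    prior = SpectrumPrior.uniform()
    direct = sc.nonsyn.sum() / sc.syn.sum()  # uniform weights cancel
    assert expected_ns_ratio(sc, prior) == pytest.approx(direct)


def test_expected_ratio_symmetric_counts_give_one():
    sc = SiteCounts(scope="x", syn=np.ones(N_CLASSES), mis=np.ones(N_CLASSES))
    assert expected_ns_ratio(sc, SpectrumPrior.uniform()) == pytest.approx(1.0)
    empty = SiteCounts(scope="y", mis=np.ones(N_CLASSES))
    with pytest.raises(ValueError):
        expected_ns_ratio(empty, SpectrumPrior.uniform())


# --- global statistic and excess fraction --------------------------------------

def test_global_dnds_worked_example():
    # observed/expected ratios 3.68 vs 2.12 give the headline 1.73
    assert global_dnds(368, 100, 2.12) == pytest.approx(1.73, abs=0.01)
    assert global_dnds(212, 100, 2.12) == pytest.approx(1.0)
    assert global_dnds(0, 10, 2.12) == 0.0
    with pytest.raises(ValueError):
        global_dnds(5, 0, 2.12)


def test_selection_excess_fraction():
    assert selection_excess_fraction(1.73) == pytest.approx(0.73 / 1.73, abs=1e-9)
    assert round(selection_excess_fraction(1.73), 2) == 0.42
    assert selection_excess_fraction(1.0) == 0.0
    assert selection_excess_fraction(0.5) == 0.0  # purifying clamps


# --- binomial test --------------------------------------------------------------

def _sites_with_pi(pi):
    """SiteCounts whose prior-weighted nonsyn probability is exactly pi."""
    sc = SiteCounts(scope="x")
    sc.mis[:] = pi
    sc.syn[:] = 1 - pi
    return sc


def _binom_tail(n, N, pi):
    return sum(math.comb(N, k) * pi**k * (1 - pi) ** (N - k) for k in range(n, N + 1))


def test_binomial_test_closed_forms():
    prior = SpectrumPrior.uniform()
    assert binomial_selection_test(10, 0, _sites_with_pi(0.5), prior) == pytest.approx(
        0.5**10
    )
    assert binomial_selection_test(0, 7, _sites_with_pi(0.5), prior) == pytest.approx(1.0)


def test_binomial_test_matches_tail_oracle():
    prior = SpectrumPrior.uniform()
    got = binomial_selection_test(7, 3, _sites_with_pi(0.7), prior)
    assert got == pytest.approx(_binom_tail(7, 10, 0.7), abs=1e-12)


# --- BH FDR ---------------------------------------------------------------------

def test_bh_single_and_stepup():
    q, called = bh_fdr([0.03])
    assert q[0] == pytest.approx(0.03) and called[0]
    q, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_monotone_in_sorted_p():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=40)
    q, _ = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    with pytest.raises(ValueError):
        bh_fdr([0.0, 0.5])


# --- run_selection ----------------------------------------------------------------

def test_all_synonymous_gives_zero_dnds(small_panel):
    sites = panel_site_table(small_panel)
    syn = sites[sites["consequence"] == "synonymous"].head(30)
    df = syn[["gene_id", "pos", "ref", "alt"]].copy()
    df.insert(0, "sample_id", "s1")
    df["vaf"] = 0.01
    df["phase_tag"] = None
    ann = annotate_mutations(df, small_panel)
    tab = run_selection(ann, small_panel, SpectrumPrior.uniform(), grouping="global")
    dnds = tab[tab["metric"] == "dN/dS"].iloc[0]
    assert dnds["statistic"] == 0.0
    assert not tab["called"].any()


@pytest.fixture(scope="module")
def driver_enriched():
    cfg = SimulationConfig(
        seed=17, n_driver=1, n_immune=6, n_housekeeping=5,
        min_codons=80, max_codons=150, n_samples=4, n_mutations_per_sample=150,
        selection_weight=3.0, impact_weight=0.0, dnv_rate=0.0,
    )
    panel = generate_panel(cfg)
    sites = panel_site_table(panel)
    muts = simulate_mutations(panel, cfg, sites=sites)
    ann = annotate_mutations(muts, panel)
    prior = estimate_prior(simulate_catalogue(cfg, size=50_000))
    return panel, ann, prior


def test_driver_enrichment_called_housekeeping_not(driver_enriched):
    panel, ann, prior = driver_enriched
    tab = run_selection(ann, panel, prior, grouping="gene_set")
    by_scope = tab[tab["metric"] == "dN/dS"].set_index("scope")
    assert by_scope.loc["driver", "q"] < 0.1
    assert not by_scope.loc["housekeeping", "called"]


def test_label_permutation_destroys_driver_signal(driver_enriched):
    panel, ann, prior = driver_enriched
    rng = np.random.default_rng(2)
    labels = [g.gene_set for g in panel.values()]
    null_calls = 0
    for _ in range(10):
        perm = rng.permutation(labels)
        permuted = {
            gid: GeneModel(gid, g.cds, perm[i], g.flank5, g.flank3, g.strand)
            for i, (gid, g) in enumerate(panel.items())
        }
        tab = run_selection(ann, permuted, prior, grouping="gene_set")
        row = tab[(tab["scope"] == "driver") & (tab["metric"] == "dN/dS")]
        if len(row) and row.iloc[0]["q"] >= 0.1:
            null_calls += 1
    assert null_calls >= 9
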