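"""Impact-score selection test: null sampling, rank-sum test, pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from somaclone import (
    GeneModel,
    SimulationConfig,
    SpectrumPrior,
    annotate_mutations,
    generate_panel,
    impact_test,
    run_impact_selection,
    sample_expected_scores,
    simulate_mutations,
    simulate_scores,
)
from somaclone.impact import scoreable_substitutions
from somaclone.simulate import panel_site_table, simulate_catalogue
from somaclone.spectrum import estimate_prior


def _score_table(gene, score_fn):
    rows = []
    for pos in range(1, len(gene.cds) + 1):
        ref = gene.cds[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            rows.append({"gene_id": gene.gene_id, "pos": pos, "alt": alt,
                         "score": score_fn(pos, alt)})
    return pd.DataFrame(rows)


def test_constant_scores_give_constant_null(toy_gene):
    scores = _score_table(toy_gene, lambda pos, alt: 0.9)
    draws = sample_expected_scores(toy_gene, SpectrumPrior.uniform(), scores,
                                   n_draws=500, seed=1)
    assert (draws == 0.9).all()


def test_null_sampling_is_deterministic_under_seed(toy_gene):
    scores = _score_table(toy_gene, lambda pos, alt: (pos * 7 + ord(alt)) % 10 / 10)
    a = sample_expected_scores(toy_gene, SpectrumPrior.uniform(), scores,
                               n_draws=1000, seed=42)
    b = sample_expected_scores(toy_gene, SpectrumPrior.uniform(), scores,
                               n_draws=1000, seed=42)
    np.testing.assert_array_equal(a, b)


def test_two_class_prior_weighting(toy_gene):
    """Prior mass 0.8/0.2 on two substitution classes with scores 1 and 0
    yields a null mean of 0.8."""
    from somaclone.trinuc import classify_96

    # find two distinct classes present in the toy gene
    subs = []
    for pos in range(1, len(toy_gene.cds) + 1):
        ref = toy_gene.cds[pos - 1]
        for alt in "ACGT":
            if alt != ref:
                subs.append((pos, ref, alt,
                             classify_96(toy_gene.context(pos), ref, alt).index))
    class_a = subs[0][3]
    class_b = next(s[3] for s in subs if s[3] != class_a)
    p = np.zeros(96)
    p[class_a], p[class_b] = 0.8, 0.2
    prior = SpectrumPrior(p)
    rows = [
        {"gene_id": "g1", "pos": pos, "alt": alt,
         "score": 1.0 if idx == class_a else 0.0}
        for pos, ref, alt, idx in subs
        if idx in (class_a, class_b)
    ]
    # make within-class counts equal so prior mass maps directly to draws
    df = pd.DataFrame(rows)
    n_a = (df["score"] == 1.0).sum()
    n_b = (df["score"] == 0.0).sum()
    vals, weights = scoreable_substitutions([toy_gene], prior, df)
    expected_mean = (0.8) / (0.8 + 0.2)  # scores 1/0, weights sum per class
    draws = sample_expected_scores(toy_gene, prior, df, n_draws=100_000, seed=3)
    # analytic mean: mass_a*(1) + mass_b*(0), with per-substitution weights
    mass_a = (0.8 / n_a) * n_a
    mass_b = (0.2 / n_b) * n_b
    analytic = mass_a / (mass_a + mass_b)
    assert draws.mean() == pytest.approx(analytic, abs=0.01)


# --- rank-sum test ---------------------------------------------------------------

def _ranksum_oracle(obs, exp):
    """Exhaustive permutation p-value for the one-sided rank-sum test."""
    pooled = list(obs) + list(exp)
    n = len(obs)

    def u_stat(group):
        return sum(1 for o in group for e in set(pooled) - set(group) if o > e)

    u_obs = sum(1 for o in obs for e in exp if o > e)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        group = [pooled[i] for i in combo]
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for o in group for e in rest if o > e)
        total += 1
        if u >= u_obs:
            count += 1
    return count / total


def test_impact_test_null_and_separation():
    null = impact_test([0.1, 0.2, 0.3], [0.15, 0.25, 0.35])
    assert abs(null.delta) < 0.11
    assert 0.2 < null.p
    sep = impact_test([1.0] * 5, [0.0] * 5)
    assert sep.delta == 1.0
    assert sep.p < 0.01  # tied samples use the tie-corrected approximation


def test_impact_test_matches_enumeration_oracle():
    obs, exp = [0.9, 0.8], [0.1, 0.2, 0.3]
    res = impact_test(obs, exp)
    assert res.p == pytest.approx(_ranksum_oracle(obs, exp), abs=1e-12)
    assert res.delta == pytest.approx(np.median(obs) - np.median(exp))


def test_impact_test_empty_observed_errors():
    with pytest.raises(ValueError):
        impact_test([], [0.1])


def test_delta_invariant_to_scoreless_substitutions(toy_gene):
    """Adding unscored substitutions to the table leaves the null unchanged."""
    scores = _score_table(toy_gene, lambda pos, alt: (pos % 5) / 5)
    prior = SpectrumPrior.uniform()
    base = sample_expected_scores(toy_gene, prior, scores, n_draws=2000, seed=9)
    # drop half the rows: the remaining substitutions keep their scores
    subset = scores.iloc[::2].reset_index(drop=True)
    # adding rows for another gene must not affect this gene's null
    other = _score_table(GeneModel("g2", "ATGCCCTAA", "driver"), lambda p, a: 0.99)
    combined = pd.concat([scores, other], ignore_index=True)
    again = sample_expected_scores(toy_gene, prior, combined, n_draws=2000, seed=9)
    np.testing.assert_array_equal(base, again)


def test_null_median_stable_under_more_draws(small_panel):
    cfg = SimulationConfig(seed=5, n_driver=1, n_immune=1, n_housekeeping=1)
    gene = next(iter(small_panel.values()))
    scores = _score_table(gene, lambda pos, alt: ((pos * 13 + ord(alt)) % 97) / 97)
    prior = SpectrumPrior.uniform()
    m1 = np.median(sample_expected_scores(gene, prior, scores, n_draws=20_000, seed=1))
    m2 = np.median(sample_expected_scores(gene, prior, scores, n_draws=40_000, seed=2))
    assert abs(m1 - m2) < 0.01


# --- pipeline-level -----------------------------------------------------------------

@pytest.fixture(scope="module")
def impact_study():
    cfg = SimulationConfig(
        seed=31, n_driver=3, n_immune=2, n_housekeeping=2,
        min_codons=80, max_codons=150, n_samples=4, n_mutations_per_sample=100,
        selection_weight=2.0, driver_min_score=0.8, dnv_rate=0.0,
    )
    panel = generate_panel(cfg)
    sites = panel_site_table(panel)
    scores = simulate_scores(panel, cfg, sites=sites)
    muts = simulate_mutations(panel, cfg, sites=sites, scores=scores)
    ann = annotate_mutations(muts, panel)
    prior = estimate_prior(simulate_catalogue(cfg, size=50_000))
    return panel, ann, prior, scores


def test_high_impact_driver_mutations_called(impact_study):
    panel, ann, prior, scores = impact_study
    tab, coverage = run_impact_selection(ann, panel, prior, scores,
                                         grouping="gene", n_draws=20_000, seed=1)
    drivers = tab[tab["scope"].str.startswith("DR")]
    assert len(drivers) >= 2
    assert drivers["called"].all()
    assert coverage["n_scored"] > 0


def test_gene_without_scored_mutations_is_omitted(impact_study):
    panel, ann, prior, scores = impact_study
    quiet = ann[ann["gene_id"] == "__none__"]  # empty table: every scope omitted
    tab, coverage = run_impact_selection(quiet, panel, prior, scores,
                                         grouping="gene", n_draws=100, seed=1)
    assert len(tab) == 0
    assert set(coverage["omitted_scopes"]) == set(panel)


def test_neutral_housekeeping_rarely_called():
    """Under neutral generation, housekeeping genes are not called in >= 90%
    of replicates."""
    cfg = SimulationConfig(
        seed=77, n_driver=2, n_immune=2, n_housekeeping=2,
        min_codons=60, max_codons=100, n_samples=2, n_mutations_per_sample=60,
        selection_weight=1.0, impact_weight=0.0, dnv_rate=0.0,
    )
    panel = generate_panel(cfg)
    sites = panel_site_table(panel)
    scores = simulate_scores(panel, cfg, sites=sites)
    prior = estimate_prior(simulate_catalogue(cfg, size=30_000))
    rng = np.random.default_rng(8)
    clean = 0
    for _ in range(20):
        muts = simulate_mutations(panel, cfg, rng=rng, sites=sites, scores=scores)
        ann = annotate_mutations(muts, panel)
        tab, _ = run_impact_selection(ann, panel, prior, scores,
                                      grouping="gene_set", n_draws=5_000, seed=3)
        row = tab[tab["scope"] == "housekeeping"]
        if len(row) == 0 or not row.iloc[0]["called"]:
            clean += 1
    assert clean >= 18
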