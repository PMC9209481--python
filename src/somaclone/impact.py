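"""Impact-score selection test (PolyPhen-2-style).

Functional impact scores in [0, 1] are supplied per substitution (gene,
position, alternate base). For each gene or gene set, observed scores of
called nonsynonymous mutations are compared against an expected-score null
obtained by sampling random point mutations in the same gene(s) with
probabilities given by the substitution-class prior. A one-sided Wilcoxon
rank-sum test asks whether the observed scores are stochastically larger; the
headline effect size is the difference between the observed and expected
median score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BASES, GeneModel
from .selection import bh_fdr
from .spectrum import SpectrumPrior
from .trinuc import classify_96

SCORE_COLUMNS = ["gene_id", "pos", "alt", "score"]


@dataclass
class ImpactResult:
    """Observed-vs-expected impact score comparison for one scope."""

    scope: str
    n_observed: int
    median_observed: float
    median_expected: float
    p: float

    @property
    def delta(self) -> float:
        return self.median_observed - self.median_expected


def read_scores(path) -> pd.DataFrame:
    """Read an impact-score table TSV (gene_id, pos, alt, score in [0,1])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "alt": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    df["score"] = df["score"].astype(float)
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    return df[SCORE_COLUMNS]


def scoreable_substitutions(genes: list[GeneModel], prior: SpectrumPrior,
                            scores: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Scores and prior weights of every scored substitution in the genes.

    Each scored (gene, pos, alt) key that references a valid panel position
    contributes its score with weight P_i of its substitution class; keys that
    do not match the gene's CDS are rejected.
    """
    by_gene = {g.gene_id: g for g in genes}
    sub = scores[scores["gene_id"].isin(by_gene)]
    vals, weights = [], []
    for row in sub.itertuples(index=False):
        gene = by_gene[row.gene_id]
        if not 1 <= row.pos <= len(gene.cds):
            raise ValueError(f"score key {row.gene_id}:{row.pos} outside CDS")
        ref = gene.cds[row.pos - 1]
        if row.alt == ref:
            raise ValueError(f"score key {row.gene_id}:{row.pos} alt equals ref")
        idx = classify_96(gene.context(row.pos), ref, row.alt).index
        vals.append(row.score)
        weights.append(prior.p[idx])
    return np.asarray(vals, dtype=float), np.asarray(weights, dtype=float)


def sample_expected_scores(genes, prior: SpectrumPrior, scores: pd.DataFrame,
                           n_draws: int = 100_000,
                           rng: np.random.Generator | None = None,
                           seed: int | None = None) -> np.ndarray:
    """Null distribution of impact scores under neutral mutagenesis.

    Random point mutations are sampled among the gene's scored substitutions
    with probability proportional to the prior of their substitution class;
    the scores of the draws form the expected-score sample.
    """
    if isinstance(genes, GeneModel):
        genes = [genes]
    if rng is None:
        rng = np.random.default_rng(seed)
    vals, weights = scoreable_substitutions(list(genes), prior, scores)
    if len(vals) == 0:
        raise ValueError("no scoreable substitutions in scope")
    total = weights.sum()
    if total == 0:
        raise ValueError("prior assigns zero mass to every scored substitution")
    return rng.choice(vals, size=n_draws, p=weights / total)


def impact_test(observed_scores, expected_scores) -> ImpactResult:
    """One-sided Wilcoxon rank-sum test of observed vs expected scores.

    Exact enumeration is used for small tie-free samples (both sides <= 50);
    otherwise the tie-corrected normal approximation. The alternative is that
    observed scores are stochastically larger.
    """
    obs = np.asarray(observed_scores, dtype=float)
    exp = np.asarray(expected_scores, dtype=float)
    if len(obs) == 0:
        raise ValueError("no observed scores")
    if len(exp) == 0:
        raise ValueError("no expected scores")
    combined = np.concatenate([obs, exp])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (max(len(obs), len(exp)) <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(obs, exp, alternative="greater", method=method)
    return ImpactResult(
        scope="",
        n_observed=len(obs),
        median_observed=float(np.median(obs)),
        median_expected=float(np.median(exp)),
        p=float(res.pvalue),
    )


def run_impact_selection(mutations: pd.DataFrame, panel: dict[str, GeneModel],
                         prior: SpectrumPrior, scores: pd.DataFrame,
                         grouping: str = "gene", n_draws: int = 100_000,
                         seed: int | None = None, fdr: float = 0.1,
                         ) -> tuple[pd.DataFrame, dict]:
    """Impact-score selection tests for one grouping family.

    Observed scores are the scores of nonsynonymous SNVs present in the score
    table; unscored mutations are excluded and tallied in the coverage report.
    Scopes with no scored observed mutation are omitted (with a reason).
    Returns (results table with BH q and calls, coverage report).
    """
    if grouping not in ("global", "gene_set", "gene"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rng = np.random.default_rng(seed)
    snvs = mutations[mutations["consequence"].notna()]
    nonsyn = snvs[snvs["consequence"].isin(["missense", "nonsense", "stoploss"])]
    merged = nonsyn.merge(scores, on=["gene_id", "pos", "alt"], how="left")

    coverage = {
        "n_nonsynonymous": int(len(nonsyn)),
        "n_scored": int(merged["score"].notna().sum()),
        "n_unscored": int(merged["score"].isna().sum()),
        "omitted_scopes": {},
    }

    if grouping == "global":
        scopes = {"global": set(panel)}
    elif grouping == "gene_set":
        scopes = {}
        for gid, gene in panel.items():
            scopes.setdefault(gene.gene_set, set()).add(gid)
    else:
        scopes = {gid: {gid} for gid in panel}

    rows = []
    for scope, gene_ids in sorted(scopes.items()):
        obs = merged[merged["gene_id"].isin(gene_ids)]["score"].dropna().to_numpy()
        if len(obs) == 0:
            coverage["omitted_scopes"][scope] = "no scored nonsynonymous mutations"
            continue
        genes = [panel[g] for g in sorted(gene_ids)]
        try:
            exp = sample_expected_scores(genes, prior, scores, n_draws=n_draws, rng=rng)
        except ValueError as why:
            coverage["omitted_scopes"][scope] = str(why)
            continue
        res = impact_test(obs, exp)
        rows.append(
            {
                "scope": scope,
                "n_observed": res.n_observed,
                "median_observed": res.median_observed,
                "median_expected": res.median_expected,
                "delta": res.delta,
                "p": res.p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["scope", "n_observed", "median_observed", "median_expected",
                 "delta", "p"],
    )
    if len(result):
        q, called = bh_fdr(result["p"], threshold=fdr)
        result["q"] = q
        result["called"] = called
    else:
        result["q"] = np.nan
        result["called"] = False
    return result, coverage
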