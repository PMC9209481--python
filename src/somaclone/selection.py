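"""Context-normalized dN/dS selection statistics.

The statistic compares the observed ratio of nonsynonymous to synonymous
mutations (n/s) to the ratio expected under neutral mutagenesis,

    dN/dS = (n/s) / (sum_i N_i P_i / sum_i S_i P_i),

where N_i and S_i count the nonsynonymous and synonymous sites of
trinucleotide substitution class i in the analysed coding sequence and P_i is
the class prior (estimated from a reference tumour catalogue). dMiss/dS and
dNons/dS restrict the numerator to missense or nonsense substitutions.
Positive selection is tested with a one-sided binomial test and calls are made
at a Benjamini-Hochberg FDR of 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import BASES, GeneModel, annotate_consequence
from .spectrum import SpectrumPrior
from .trinuc import N_CLASSES, classify_96

METRICS = ("dN/dS", "dMiss/dS", "dNons/dS")

# numerator site array per metric
_NUMERATOR = {"dN/dS": "nonsyn", "dMiss/dS": "missense", "dNons/dS": "nonsense"}


@dataclass
class SiteCounts:
    """Per-class counts of possible substitutions in a coding scope.

    For every position of the CDS each of the three possible single-base
    changes is assigned a class and a consequence; ``syn``/``mis``/``non``/
    ``stoploss`` hold the per-class totals. Stop-loss changes count as
    nonsynonymous but belong to neither the missense nor the nonsense
    submetric.
    """

    scope: str
    syn: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    mis: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    non: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    stoploss: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))

    @property
    def nonsyn(self) -> np.ndarray:
        return self.mis + self.non + self.stoploss

    @property
    def missense(self) -> np.ndarray:
        return self.mis

    @property
    def nonsense(self) -> np.ndarray:
        return self.non

    def total_sites(self) -> float:
        return float((self.syn + self.nonsyn).sum())

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(
            scope=f"{self.scope}+{other.scope}",
            syn=self.syn + other.syn,
            mis=self.mis + other.mis,
            non=self.non + other.non,
            stoploss=self.stoploss + other.stoploss,
        )


def enumerate_sites(gene: GeneModel) -> SiteCounts:
    """Classify all 3L possible SNVs of a gene into per-class site counts."""
    sc = SiteCounts(scope=gene.gene_id)
    arrays = {
        "synonymous": sc.syn,
        "missense": sc.mis,
        "nonsense": sc.non,
        "stoploss": sc.stoploss,
    }
    padded = gene.padded
    for pos in range(1, len(gene.cds) + 1):
        ref = gene.cds[pos - 1]
        context = padded[pos - 1 : pos + 2]
        for alt in BASES:
            if alt == ref:
                continue
            idx = classify_96(context, ref, alt).index
            cons = annotate_consequence(gene, pos, ref, alt)
            arrays[cons][idx] += 1
    return sc


def pool_sites(panel: dict[str, GeneModel], gene_ids=None, scope: str = "pooled",
               cache: dict | None = None) -> SiteCounts:
    """Sum site counts over a set of panel genes (optionally cached)."""
    total = SiteCounts(scope=scope)
    for gid, gene in panel.items():
        if gene_ids is not None and gid not in gene_ids:
            continue
        if cache is not None:
            if gid not in cache:
                cache[gid] = enumerate_sites(gene)
            counts = cache[gid]
        else:
            counts = enumerate_sites(gene)
        total.syn += counts.syn
        total.mis += counts.mis
        total.non += counts.non
        total.stoploss += counts.stoploss
    total.scope = scope
    return total


def expected_ns_ratio(sites: SiteCounts, prior: SpectrumPrior,
                      numerator: str = "nonsyn") -> float:
    """Prior-weighted expected numerator/synonymous site ratio.

    ``numerator`` is one of ``nonsyn``, ``missense``, ``nonsense``.
    """
    num = float(np.dot(getattr(sites, numerator), prior.p))
    den = float(np.dot(sites.syn, prior.p))
    if den == 0:
        raise ValueError("zero prior-weighted synonymous site mass")
    return num / den


def global_dnds(n: int, s: int, expected_ratio: float) -> float:
    """Observed-over-expected nonsynonymous/synonymous ratio, (n/s)/expected."""
    if s == 0:
        raise ValueError("no synonymous mutations: dN/dS undefined")
    if expected_ratio <= 0:
        raise ValueError("expected ratio must be positive")
    return (n / s) / expected_ratio


def selection_excess_fraction(dnds: float) -> float:
    """Fraction of nonsynonymous mutations attributable to positive selection.

    For dN/dS > 1 the excess over the neutral expectation is (dN/dS - 1) /
    (dN/dS); purifying or neutral values clamp to 0.
    """
    if dnds <= 0:
        raise ValueError("dN/dS must be positive")
    return max(0.0, (dnds - 1.0) / dnds)


def binomial_selection_test(n: int, s: int, sites: SiteCounts, prior: SpectrumPrior,
                            numerator: str = "nonsyn") -> float:
    """One-sided binomial p-value that the numerator count exceeds neutrality.

    Under the null each observed mutation is an independent draw that is a
    numerator-category substitution with probability
    pi = sum_i X_i P_i / (sum_i X_i P_i + sum_i S_i P_i); the p-value is
    P[X >= n] for X ~ Binomial(n + s, pi).
    """
    if n + s == 0:
        raise ValueError("no observed mutations to test")
    num_mass = float(np.dot(getattr(sites, numerator), prior.p))
    syn_mass = float(np.dot(sites.syn, prior.p))
    if num_mass + syn_mass == 0:
        raise ValueError("undefined null probability (zero site mass)")
    pi = num_mass / (num_mass + syn_mass)
    return float(stats.binom.sf(n - 1, n + s, pi))


def bh_fdr(pvalues, threshold: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjusted p-values and calls at the given FDR."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < threshold


def _observed_counts(mutations: pd.DataFrame) -> dict[str, int]:
    cons = mutations["consequence"].dropna()
    return {
        "syn": int((cons == "synonymous").sum()),
        "nonsyn": int(cons.isin(["missense", "nonsense", "stoploss"]).sum()),
        "missense": int((cons == "missense").sum()),
        "nonsense": int((cons == "nonsense").sum()),
    }


def run_selection(mutations: pd.DataFrame, panel: dict[str, GeneModel],
                  prior: SpectrumPrior, grouping: str = "gene_set",
                  metrics=METRICS, fdr: float = 0.1,
                  site_cache: dict | None = None) -> pd.DataFrame:
    """Selection tests for one grouping family.

    ``grouping`` is ``"global"`` (all genes pooled), ``"gene_set"`` (driver /
    immune / housekeeping pooled separately) or ``"gene"``. Only annotated
    SNVs enter the counts; BH adjustment is applied per metric within the
    family. Returns a table with columns scope, metric, n, s, expected_ratio,
    statistic, p, q, called.
    """
    if grouping not in ("global", "gene_set", "gene"):
        raise ValueError(f"unknown grouping {grouping!r}")
    snvs = mutations[mutations["consequence"].notna()]
    if site_cache is None:
        site_cache = {}

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
        sites = pool_sites(panel, gene_ids, scope=scope, cache=site_cache)
        sub = snvs[snvs["gene_id"].isin(gene_ids)]
        obs = _observed_counts(sub)
        s = obs["syn"]
        for metric in metrics:
            numerator = _NUMERATOR[metric]
            n = obs[numerator]
            if n + s == 0:
                continue
            expected = expected_ns_ratio(sites, prior, numerator)
            statistic = (n / s) / expected if s > 0 else np.nan
            p = binomial_selection_test(n, s, sites, prior, numerator)
            rows.append(
                {
                    "scope": scope,
                    "metric": metric,
                    "n": n,
                    "s": s,
                    "expected_ratio": expected,
                    "statistic": statistic,
                    "p": p,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=["scope", "metric", "n", "s", "expected_ratio", "statistic", "p"],
    )
    result["q"] = np.nan
    result["called"] = False
    for metric in metrics:
        mask = result["metric"] == metric
        if mask.any():
            q, called = bh_fdr(result.loc[mask, "p"], threshold=fdr)
            result.loc[mask, "q"] = q
            result.loc[mask, "called"] = called
    return result
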