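"""Study orchestration: run the full analysis and emit a report directory.

The analysis mirrors a four-step design: consume a somatic mutation table,
quantify positive selection (context-normalized dN/dS and impact-score tests),
infer clone sizes and occupancy from VAFs, and characterize the UV mutational
spectrum (96-class spectrum, dipyrimidine fraction, strand bias, CC>TT
dinucleotides, signature refitting). All outputs are headered TSVs; every
statistical table records the test used in comment lines for auditability.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonality, consensus, genome, impact, selection, spectrum

logger = logging.getLogger("somaclone")


@dataclass
class RunConfig:
    """Paths and parameters of one analysis run."""

    panel_fasta: Path
    panel_metadata: Path
    mutations: Path
    catalogue: Path
    outdir: Path
    samples: Path | None = None
    signatures: Path | None = None
    scores: Path | None = None
    tissue: str = "skin"
    fdr: float = 0.1
    seed: int = 0
    impact_draws: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("FDR threshold must be in (0, 1)")
        for name in ("panel_fasta", "panel_metadata", "mutations", "catalogue"):
            path = Path(getattr(self, name))
            setattr(self, name, path)
            if not path.exists():
                raise FileNotFoundError(f"{name}: {path}")
        for name in ("samples", "signatures", "scores"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def burden_summary(mutations: pd.DataFrame,
                   panel: dict[str, genome.GeneModel]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample, per-gene-set mutation counts and per-gene burden.

    The per-gene table reports mutations per sample (mps = total mutations in
    the gene / number of samples), ranked by mps.
    """
    n_samples = mutations["sample_id"].nunique()
    if n_samples == 0:
        raise ValueError("no samples in mutation table")
    gene_sets = {gid: g.gene_set for gid, g in panel.items()}
    df = mutations.copy()
    df["gene_set"] = df["gene_id"].map(gene_sets)
    per_sample = (
        df.groupby(["sample_id", "gene_set"]).size().unstack(fill_value=0).reset_index()
    )
    per_gene = df.groupby("gene_id").size().rename("n_mutations").reset_index()
    per_gene["mps"] = per_gene["n_mutations"] / n_samples
    absent = [g for g in panel if g not in set(per_gene["gene_id"])]
    if absent:
        per_gene = pd.concat(
            [per_gene, pd.DataFrame({"gene_id": absent, "n_mutations": 0, "mps": 0.0})],
            ignore_index=True,
        )
    per_gene["gene_set"] = per_gene["gene_id"].map(gene_sets)
    per_gene = per_gene.sort_values("mps", ascending=False).reset_index(drop=True)
    return per_sample, per_gene


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every analysis stage and write the study report directory.

    Stages with missing optional inputs (sample sheet, score table, signature
    matrix) are skipped with an explicit log entry; any hard failure aborts
    naming the stage. Outputs are deterministic given the config seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("seed=%d fdr=%.3f tissue=%s", config.seed, config.fdr, config.tissue)

        stage = "input"
        panel = genome.read_panel(config.panel_fasta, config.panel_metadata)
        mutations = genome.read_mutations(config.mutations)
        n_input = len(mutations)
        catalogue = pd.read_csv(config.catalogue, sep="\t")
        prior = spectrum.estimate_prior(catalogue, source_label=config.tissue)
        logger.info("%d genes, %d mutations, catalogue %d entries",
                    len(panel), n_input, len(catalogue))

        stage = "annotate"
        merged = genome.merge_phased(mutations)
        annotated = genome.annotate_mutations(merged, panel)
        n_dnv = int((annotated["var_class"] != "SNV").sum())
        logger.info("after phase merge: %d records (%d DNV/MNV)", len(annotated), n_dnv)
        _write(annotated, outdir / "mutations_annotated.tsv")
        written["mutations_annotated"] = outdir / "mutations_annotated.tsv"

        stage = "burden"
        per_sample, per_gene = burden_summary(annotated, panel)
        _write(per_sample, outdir / "burden_per_sample.tsv")
        _write(per_gene, outdir / "burden_per_gene.tsv")
        written["burden_per_sample"] = outdir / "burden_per_sample.tsv"
        written["burden_per_gene"] = outdir / "burden_per_gene.tsv"

        stage = "spectrum"
        spec = spectrum.compute_spectrum(annotated)
        _write(spec.to_series().rename_axis("class").reset_index(),
               outdir / "spectrum96.tsv")
        written["spectrum96"] = outdir / "spectrum96.tsv"
        uv_rows = []
        try:
            dipyr = spectrum.dipyrimidine_fraction(annotated)
            uv_rows.append({"statistic": "dipyrimidine_fraction_c_to_t",
                            "value": dipyr, "p": np.nan})
        except ValueError as why:
            logger.info("dipyrimidine fraction skipped: %s", why)
        sc = spectrum.strand_counts(annotated, subst_type="C>T")
        if sc.coding + sc.template > 0:
            bias = spectrum.strand_bias_test(sc)
            uv_rows.append({"statistic": "c_to_t_coding_strand_excess_percent",
                            "value": bias["excess_percent"], "p": bias["p"]})
        try:
            dnv = spectrum.dnv_strand_analysis(annotated)
            uv_rows.append({"statistic": "cc_tt_fraction_coding",
                            "value": dnv["fraction_coding"], "p": dnv["p"]})
        except ValueError as why:
            logger.info("CC>TT strand analysis skipped: %s", why)
        _write(pd.DataFrame(uv_rows), outdir / "uv_statistics.tsv",
               ["exact conditional binomial tests; two-sided for strand bias, "
                "one-sided (greater) for CC>TT"])
        written["uv_statistics"] = outdir / "uv_statistics.tsv"

        if config.signatures is not None and Path(config.signatures).exists():
            sigs = spectrum.read_signatures(config.signatures)
            exposures = spectrum.refit_signatures(spec, sigs)
            _write(exposures.rename_axis("signature").reset_index(),
                   outdir / "signature_exposures.tsv",
                   ["non-negative least squares refit, exposures normalized to 1"])
            written["signature_exposures"] = outdir / "signature_exposures.tsv"
        else:
            logger.info("signature stage skipped: no signature matrix supplied")

        stage = "selection_dnds"
        site_cache: dict = {}
        tables = []
        for grouping in ("global", "gene_set", "gene"):
            tab = selection.run_selection(
                annotated, panel, prior, grouping=grouping,
                fdr=config.fdr, site_cache=site_cache,
            )
            tab.insert(0, "grouping", grouping)
            tables.append(tab)
        dnds_table = pd.concat(tables, ignore_index=True)
        _write(dnds_table, outdir / "selection_dnds.tsv",
               ["one-sided binomial test against prior-weighted site ratio; "
                f"BH FDR per metric within grouping, threshold {config.fdr}"])
        written["selection_dnds"] = outdir / "selection_dnds.tsv"

        stage = "selection_impact"
        if config.scores is not None and Path(config.scores).exists():
            scores = impact.read_scores(config.scores)
            tables = []
            for grouping in ("gene_set", "gene"):
                tab, coverage = impact.run_impact_selection(
                    annotated, panel, prior, scores, grouping=grouping,
                    n_draws=config.impact_draws, seed=config.seed, fdr=config.fdr,
                )
                tab.insert(0, "grouping", grouping)
                tables.append(tab)
                logger.info("impact %s: %s", grouping, coverage)
            impact_table = pd.concat(tables, ignore_index=True)
            _write(impact_table, outdir / "selection_impact.tsv",
                   ["one-sided Wilcoxon rank-sum vs prior-weighted expected "
                    f"scores; BH FDR threshold {config.fdr}"])
            written["selection_impact"] = outdir / "selection_impact.tsv"
        else:
            logger.info("impact stage skipped: no score table supplied")

        stage = "clonality"
        if config.samples is not None and Path(config.samples).exists():
            samples = clonality.read_samples(config.samples)
            excluded = clonality.excluded_samples(samples)
            if excluded:
                logger.info("samples excluded from clone inference: %s", excluded)
            per_gene_calls = dnds_table[
                (dnds_table["grouping"] == "gene")
                & (dnds_table["metric"] == "dN/dS")
                & dnds_table["called"]
            ]["scope"].tolist()
            clones = clonality.clone_table(annotated, samples, per_gene_calls)
            _write(clones, outdir / "clone_report.tsv",
                   ["clone size = 2 x VAF x biopsy area; genes called at "
                    f"{config.fdr} FDR (dN/dS)"])
            written["clone_report"] = outdir / "clone_report.tsv"
        else:
            logger.info("clonality stage skipped: no sample sheet supplied")

        logger.info("run complete: %d tables", len(written))
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return written
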