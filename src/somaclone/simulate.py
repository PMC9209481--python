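"""Synthetic study generator.

Produces every input the pipeline consumes — gene panel, somatic mutation
table, reference catalogue for priors, impact-score table, sample sheet and
barcoded amplicon reads — with the statistical structure the downstream
analyses assume: a UV-like substitution spectrum (C>T at dipyrimidines with a
coding-strand excess and CC>TT dinucleotides), VAFs in a configurable
low-frequency range, positive selection on driver genes implemented as
acceptance reweighting of nonsynonymous draws (so the neutral limit w = 1 is
exact), and barcode families with configurable sizes and error rates.

Default parameter values reflect the study conditions this package models:
a 153-gene panel (101 driver, 32 immune, 20 housekeeping), 12 samples from
5 mm punch biopsies, ~76 mutations per sample with VAFs between 0.0023 and
0.11, a 24% coding-strand excess of C>T and predominantly coding-strand
CC>TT dinucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import HotspotDef, default_hotspots
from .genome import GeneModel, write_panel, write_mutations
from .spectrum import SpectrumPrior, uv_class_profile, default_signature_matrix, write_signatures
from .trinuc import BASES, CLASS_LABELS, N_CLASSES, PYRIMIDINES, classify_96, parse_label
from .genome import annotate_consequence

_STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in _STOP_CODONS
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study. ``seed`` is mandatory."""

    seed: int
    # panel
    n_driver: int = 101
    n_immune: int = 32
    n_housekeeping: int = 20
    min_codons: int = 150
    max_codons: int = 600
    # spectrum
    uv_weight: float = 0.5          # mix of UV-like profile vs uniform classes
    strand_bias: float = 1.24       # coding-strand weight for pyrimidine subs
    dnv_rate: float = 0.04          # CC>TT pairs per sampled mutation
    dnv_coding_fraction: float = 0.824
    # selection
    selection_weight: float = 2.0   # nonsynonymous acceptance weight, drivers
    nonsense_only: bool = False
    impact_weight: float = 4.0      # extra weight (1 + iw*score) on driver missense
    driver_min_score: float | None = None
    # sampling
    n_samples: int = 12
    n_mutations_per_sample: int = 76
    vaf_min: float = 0.0023
    vaf_max: float = 0.11
    # impact scores (Beta parameters per gene set)
    driver_score_beta: tuple = (0.5, 1.5)
    other_score_beta: tuple = (0.5, 1.5)
    # reference catalogue
    catalogue_size: int = 50_000
    tissue: str = "skin"
    # UMI / barcode families
    n_families: int = 5000
    family_size: int = 30
    family_size_sd: float = 0.0
    read_error_rate: float = 0.005
    error_mode: str = "per_read"    # or "per_base"
    true_hotspot_vaf: float = 0.01
    barcode_length: int = 12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.uv_weight <= 1:
            raise ValueError("uv_weight must be in [0, 1]")
        if self.strand_bias < 1:
            raise ValueError("strand_bias must be >= 1")
        if self.selection_weight < 1:
            raise ValueError("selection_weight must be >= 1")
        if not 0 < self.vaf_min <= self.vaf_max <= 1:
            raise ValueError("need 0 < vaf_min <= vaf_max <= 1")
        for name in ("dnv_rate", "dnv_coding_fraction", "read_error_rate",
                     "true_hotspot_vaf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.error_mode not in ("per_read", "per_base"):
            raise ValueError("error_mode must be per_read or per_base")
        if self.min_codons < 3 or self.max_codons < self.min_codons:
            raise ValueError("invalid codon length range")


def _rng_for(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    # independent, reproducible sub-streams per generator stage
    streams = ("panel", "mutations", "catalogue", "scores", "umi")
    children = np.random.SeedSequence(cfg.seed).spawn(len(streams))
    return np.random.default_rng(children[streams.index(stream)])


def class_probabilities(cfg: SimulationConfig) -> np.ndarray:
    """Configured per-class substitution probabilities (UV/uniform mixture)."""
    uniform = np.full(N_CLASSES, 1.0 / N_CLASSES)
    return cfg.uv_weight * uv_class_profile() + (1.0 - cfg.uv_weight) * uniform


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

def generate_panel(cfg: SimulationConfig,
                   rng: np.random.Generator | None = None) -> dict[str, GeneModel]:
    """Random gene panel: ATG start, no internal stops, terminal stop codon."""
    rng = rng or _rng_for(cfg, "panel")
    panel: dict[str, GeneModel] = {}
    specs = (
        [("driver", i) for i in range(cfg.n_driver)]
        + [("immune", i) for i in range(cfg.n_immune)]
        + [("housekeeping", i) for i in range(cfg.n_housekeeping)]
    )
    for gene_set, i in specs:
        n_codons = int(rng.integers(cfg.min_codons, cfg.max_codons + 1))
        internal = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
        cds = (
            "ATG"
            + "".join(_NONSTOP_CODONS[k] for k in internal)
            + _STOP_CODONS[rng.integers(0, 3)]
        )
        gene_id = f"{gene_set[:2].upper()}{i + 1:03d}"
        panel[gene_id] = GeneModel(
            gene_id=gene_id,
            cds=cds,
            gene_set=gene_set,
            flank5=BASES[rng.integers(0, 4)],
            flank3=BASES[rng.integers(0, 4)],
        )
    return panel


def panel_site_table(panel: dict[str, GeneModel]) -> pd.DataFrame:
    """All possible SNVs of the panel with class index and consequence.

    This table is the shared substrate of the mutation generator and the
    score generator; computing it once per panel keeps replicated simulations
    cheap.
    """
    gene_ids, gene_sets, positions, refs, alts, contexts, class_idx, cons = (
        [], [], [], [], [], [], [], [])
    for gene in panel.values():
        padded = gene.padded
        for pos in range(1, len(gene.cds) + 1):
            ref = gene.cds[pos - 1]
            ctx = padded[pos - 1 : pos + 2]
            for alt in BASES:
                if alt == ref:
                    continue
                gene_ids.append(gene.gene_id)
                gene_sets.append(gene.gene_set)
                positions.append(pos)
                refs.append(ref)
                alts.append(alt)
                contexts.append(ctx)
                class_idx.append(classify_96(ctx, ref, alt).index)
                cons.append(annotate_consequence(gene, pos, ref, alt))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_set": gene_sets,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "context": contexts,
            "class_idx": np.asarray(class_idx),
            "consequence": cons,
        }
    )


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def _substitution_weights(sites: pd.DataFrame, cfg: SimulationConfig,
                          scores: pd.DataFrame | None) -> np.ndarray:
    """Per-substitution sampling weights.

    A substitution class is drawn with the configured class probability and a
    site uniformly within the class; selection then reweights driver-gene
    nonsynonymous draws by the acceptance factor w (optionally nonsense-only
    and impact-score-weighted).
    """
    q = class_probabilities(cfg)
    class_counts = np.bincount(sites["class_idx"], minlength=N_CLASSES)
    per_site = np.where(class_counts > 0, q / np.maximum(class_counts, 1), 0.0)
    w = per_site[sites["class_idx"].to_numpy()]

    if cfg.strand_bias != 1.0:
        pyr_coding = sites["ref"].isin(list(PYRIMIDINES)).to_numpy()
        w = w * np.where(pyr_coding, cfg.strand_bias, 1.0)

    driver = (sites["gene_set"] == "driver").to_numpy()
    cons = sites["consequence"].to_numpy()
    if cfg.nonsense_only:
        selected = driver & (cons == "nonsense")
    else:
        selected = driver & np.isin(cons, ("missense", "nonsense", "stoploss"))
    w = w * np.where(selected, cfg.selection_weight, 1.0)

    if scores is not None and (cfg.impact_weight > 0 or cfg.driver_min_score is not None):
        merged = sites.merge(scores, on=["gene_id", "pos", "alt"], how="left")
        score = merged["score"].to_numpy()
        missense_driver = driver & (cons == "missense")
        if cfg.impact_weight > 0:
            # tilt driver missense mass toward damaging substitutions without
            # changing its total, so w alone sets the nonsynonymous excess
            tilt = np.where(
                missense_driver & ~np.isnan(score),
                1.0 + cfg.impact_weight * np.nan_to_num(score),
                1.0,
            )
            before = w[missense_driver].sum()
            after = (w * tilt)[missense_driver].sum()
            if after > 0:
                tilt = np.where(missense_driver, tilt * before / after, 1.0)
            w = w * tilt
        if cfg.driver_min_score is not None:
            low = missense_driver & (np.nan_to_num(score) < cfg.driver_min_score)
            w = w * np.where(low, 0.0, 1.0)

    total = w.sum()
    if total == 0:
        raise ValueError("all substitution weights are zero")
    return w / total


def _draw_vafs(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = np.log(cfg.vaf_min), np.log(cfg.vaf_max)
    return np.exp(rng.uniform(lo, hi, size=n))


def _dnv_candidates(panel: dict[str, GeneModel]) -> tuple[list, list]:
    coding, template = [], []
    for gene in panel.values():
        for pos in range(1, len(gene.cds)):
            pair = gene.cds[pos - 1 : pos + 1]
            if pair == "CC":
                coding.append((gene.gene_id, pos))
            elif pair == "GG":
                template.append((gene.gene_id, pos))
    return coding, template


def simulate_mutations(panel: dict[str, GeneModel], cfg: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       sites: pd.DataFrame | None = None,
                       scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw a somatic mutation table for all samples of the synthetic study.

    Each SNV is drawn by sampling a substitution class from the configured
    spectrum and a site uniformly within the class, with driver-gene
    nonsynonymous substitutions accepted with relative weight w. VAFs are
    log-uniform over the configured range. Phased CC>TT dinucleotide pairs
    are injected at the configured rate with shared phase tags, placing the
    dipyrimidine on the coding strand with the configured probability.
    """
    if not panel:
        raise ValueError("empty panel")
    rng = rng or _rng_for(cfg, "mutations")
    if sites is None:
        sites = panel_site_table(panel)
    weights = _substitution_weights(sites, cfg, scores)
    dnv_coding, dnv_template = _dnv_candidates(panel)

    rows = []
    for k in range(cfg.n_samples):
        sample_id = f"S{k + 1:02d}"
        n = cfg.n_mutations_per_sample
        idx = rng.choice(len(sites), size=n, replace=False, p=weights)
        chosen = sites.iloc[idx]
        vafs = _draw_vafs(rng, n, cfg)
        used_pos: set = set()
        for (row, vaf) in zip(chosen.itertuples(index=False), vafs):
            used_pos.add((row.gene_id, row.pos))
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene_id": row.gene_id,
                    "pos": row.pos,
                    "ref": row.ref,
                    "alt": row.alt,
                    "vaf": float(vaf),
                    "phase_tag": None,
                }
            )
        n_dnv = rng.binomial(n, cfg.dnv_rate)
        for d in range(n_dnv):
            on_coding = rng.uniform() < cfg.dnv_coding_fraction
            pool = dnv_coding if on_coding else dnv_template
            if not pool:
                continue
            gene_id, pos = pool[rng.integers(0, len(pool))]
            # injected pairs own both positions; skip collisions so phase
            # groups stay consistent
            if (gene_id, pos) in used_pos or (gene_id, pos + 1) in used_pos:
                continue
            used_pos.update({(gene_id, pos), (gene_id, pos + 1)})
            ref, alt = ("C", "T") if on_coding else ("G", "A")
            vaf = float(_draw_vafs(rng, 1, cfg)[0])
            tag = f"{sample_id}_dnv{d}"
            for offset in (0, 1):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "gene_id": gene_id,
                        "pos": pos + offset,
                        "ref": ref,
                        "alt": alt,
                        "vaf": vaf,
                        "phase_tag": tag,
                    }
                )
    return pd.DataFrame(rows)


def simulate_catalogue(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       size: int | None = None) -> pd.DataFrame:
    """Reference mutation catalogue (SKCM/HNSC stand-in) for prior estimation.

    Classes are drawn from the configured spectrum with an independent random
    stream, decoupling prior estimation from the study mutations, and each
    draw is written as its pyrimidine-centred context representation.
    """
    rng = rng or _rng_for(cfg, "catalogue")
    size = size or cfg.catalogue_size
    if size <= 0:
        raise ValueError("catalogue size must be positive")
    q = class_probabilities(cfg)
    idx = rng.choice(N_CLASSES, size=size, p=q)
    contexts, refs, alts = [], [], []
    for i in idx:
        ctx, ref, alt = parse_label(CLASS_LABELS[i])
        contexts.append(ctx)
        refs.append(ref)
        alts.append(alt)
    return pd.DataFrame({"context": contexts, "ref": refs, "alt": alts})


def simulate_scores(panel: dict[str, GeneModel], cfg: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Impact scores for every missense-producing substitution of the panel.

    Scores follow Beta distributions configurable per gene set (driver vs
    other), standing in for an external predictor such as PolyPhen-2.
    """
    rng = rng or _rng_for(cfg, "scores")
    if sites is None:
        sites = panel_site_table(panel)
    missense = sites[sites["consequence"] == "missense"].copy()
    driver = (missense["gene_set"] == "driver").to_numpy()
    a_d, b_d = cfg.driver_score_beta
    a_o, b_o = cfg.other_score_beta
    scores = np.where(
        driver,
        rng.beta(a_d, b_d, size=len(missense)),
        rng.beta(a_o, b_o, size=len(missense)),
    )
    missense["score"] = scores
    return missense[["gene_id", "pos", "alt", "score"]].reset_index(drop=True)


def generate_sample_sheet(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: circular punch biopsies of 5 mm diameter."""
    return pd.DataFrame(
        {
            "sample_id": [f"S{k + 1:02d}" for k in range(cfg.n_samples)],
            "tissue": cfg.tissue,
            "diameter_mm": 5.0,
            "area_mm2": np.nan,
        }
    )


# ---------------------------------------------------------------------------
# Barcoded amplicon reads
# ---------------------------------------------------------------------------

def _int_to_barcode(i: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(BASES[i % 4])
        i //= 4
    return "".join(out)


def simulate_umi_reads(hotspot: HotspotDef, cfg: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       true_vaf: float | None = None) -> list[tuple[str, str]]:
    """Barcoded reads over one hotspot amplicon.

    Each family derives from a mutant or wild-type template (mutant with the
    true hotspot VAF, carrying the alternate base at the first mutant
    position); reads then acquire errors independently. In ``per_read`` mode a
    read is wrong with probability ``read_error_rate`` (one random substituted
    base); ``per_base`` applies that rate independently per position. Family
    mutant status uses one uniform draw per family, so estimates are monotone
    in the true VAF under a shared seed.
    """
    rng = rng or _rng_for(cfg, "umi")
    if true_vaf is None:
        true_vaf = cfg.true_hotspot_vaf
    ref = hotspot.reference
    mut_pos = hotspot.mutant_positions[0]
    mutant_template = ref[:mut_pos] + hotspot.alt_base + ref[mut_pos + 1 :]

    mutant_u = rng.uniform(size=cfg.n_families)
    reads: list[tuple[str, str]] = []
    for fam in range(cfg.n_families):
        barcode = _int_to_barcode(fam, cfg.barcode_length)
        if cfg.family_size_sd > 0:
            size = max(1, int(round(rng.normal(cfg.family_size, cfg.family_size_sd))))
        else:
            size = cfg.family_size
        template = mutant_template if mutant_u[fam] < true_vaf else ref
        for _ in range(size):
            read = template
            if cfg.error_mode == "per_read":
                if rng.uniform() < cfg.read_error_rate:
                    p = int(rng.integers(0, len(read)))
                    others = [b for b in BASES if b != read[p]]
                    read = read[:p] + others[rng.integers(0, 3)] + read[p + 1 :]
            else:
                hits = np.nonzero(rng.uniform(size=len(read)) < cfg.read_error_rate)[0]
                if len(hits):
                    chars = list(read)
                    for p in hits:
                        others = [b for b in BASES if b != chars[p]]
                        chars[p] = others[rng.integers(0, 3)]
                    read = "".join(chars)
            reads.append((barcode, read))
    return reads


def write_barcoded_fastq(reads: list[tuple[str, str]], path,
                         prefix_barcode: bool = True) -> None:
    """Write (barcode, sequence) pairs as FASTQ.

    With ``prefix_barcode`` the barcode is prepended to the read sequence;
    otherwise it is recorded as a ``UMI:<barcode>`` description token.
    """
    with open(path, "w") as fh:
        for i, (barcode, seq) in enumerate(reads):
            if prefix_barcode:
                full = barcode + seq
                fh.write(f"@read_{i}\n{full}\n+\n{'I' * len(full)}\n")
            else:
                fh.write(f"@read_{i} UMI:{barcode}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Whole-study emission
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimulationConfig, outdir) -> dict[str, Path]:
    """Write a complete synthetic study directory and return the file map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel_fasta": out / "panel.fasta",
        "panel_metadata": out / "panel_metadata.tsv",
        "mutations": out / "mutations.tsv",
        "catalogue": out / "catalogue.tsv",
        "scores": out / "scores.tsv",
        "samples": out / "samples.tsv",
        "signatures": out / "signatures.tsv",
        "umi_fastq": out / "umi_reads.fastq",
        "config": out / "config.yaml",
    }
    panel = generate_panel(cfg)
    write_panel(panel, paths["panel_fasta"], paths["panel_metadata"])
    sites = panel_site_table(panel)
    scores = simulate_scores(panel, cfg, sites=sites)
    scores.to_csv(paths["scores"], sep="\t", index=False)
    mutations = simulate_mutations(panel, cfg, sites=sites, scores=scores)
    write_mutations(mutations, paths["mutations"])
    simulate_catalogue(cfg).to_csv(paths["catalogue"], sep="\t", index=False)
    generate_sample_sheet(cfg).to_csv(paths["samples"], sep="\t", index=False)
    write_signatures(default_signature_matrix(), paths["signatures"])
    hotspot = default_hotspots()[0]
    write_barcoded_fastq(simulate_umi_reads(hotspot, cfg), paths["umi_fastq"])
    import yaml

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    return paths
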