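"""Clone-size inference from variant allele frequencies.

Assuming diploid cells heterozygous for a somatic mutation, the surface area
of the clone carrying it is

    clone size (mm^2) = 2 x VAF x biopsy surface area (mm^2),

so a VAF of 0.5 corresponds to a clone filling the whole biopsy. Clone
frequency is reported per cm^2 of sampled tissue and clonal occupancy as the
percentage of the sampled surface carrying mutations in a gene. Each called
mutation in a positively selected gene is treated as one clone; overlapping
or nested clones are not resolved, so occupancies are reported unclamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "tissue", "diameter_mm", "area_mm2"]


def biopsy_area(diameter_mm: float) -> float:
    """Surface area of a circular punch biopsy, pi * (d/2)^2."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * (diameter_mm / 2.0) ** 2


def clone_size(vaf: float, area_mm2: float) -> float:
    """Clone surface area implied by a VAF in a biopsy of known area."""
    if not 0 < vaf <= 1:
        raise ValueError(f"VAF {vaf} outside (0, 1]")
    if area_mm2 <= 0:
        raise ValueError("biopsy area must be positive")
    return 2.0 * vaf * area_mm2


def read_samples(path) -> pd.DataFrame:
    """Read a sample sheet TSV (sample_id, tissue, diameter_mm, area_mm2).

    Area is taken verbatim when given, derived from the diameter otherwise;
    samples with neither are kept but flagged ``area_known=False`` and are
    excluded from clone-size inference (mirroring biopsies of unknown size).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    missing = {"sample_id", "tissue"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    for col in ("diameter_mm", "area_mm2"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = df[col].astype(float)
    derived = df["area_mm2"].isna() & df["diameter_mm"].notna()
    df.loc[derived, "area_mm2"] = df.loc[derived, "diameter_mm"].map(biopsy_area)
    df["area_known"] = df["area_mm2"].notna()
    return df


def _scoped(mutations: pd.DataFrame, samples: pd.DataFrame, genes=None):
    known = samples[samples["area_known"]]
    muts = mutations[mutations["sample_id"].isin(known["sample_id"])]
    if genes is not None:
        muts = muts[muts["gene_id"].isin(set(genes))]
    total_area = float(known["area_mm2"].sum())
    return muts, known, total_area


def clone_estimates(mutations: pd.DataFrame, samples: pd.DataFrame,
                    genes=None) -> pd.DataFrame:
    """Per-mutation clone sizes over samples with known area."""
    muts, known, _ = _scoped(mutations, samples, genes)
    area = known.set_index("sample_id")["area_mm2"]
    out = muts.copy()
    out["size_mm2"] = [
        clone_size(v, area[s]) for v, s in zip(out["vaf"], out["sample_id"])
    ]
    return out


def clones_per_cm2(mutations: pd.DataFrame, samples: pd.DataFrame,
                   genes=None) -> float:
    """Clone frequency: clones per cm^2 of sampled tissue with known area."""
    muts, _, total_area = _scoped(mutations, samples, genes)
    if total_area == 0:
        raise ValueError("no sampled area with known size")
    return len(muts) / total_area * 100.0


def occupancy_percent(mutations: pd.DataFrame, samples: pd.DataFrame,
                      gene: str) -> float:
    """Percent of sampled surface occupied by clones of one gene.

    Equals 100 x (sum of clone sizes) / (total sampled area), i.e. the
    area-weighted mean of 2 x VAF. May exceed 100% for pathological inputs
    (overlapping clones); such values are reported with a warning.
    """
    est = clone_estimates(mutations, samples, genes=[gene])
    _, _, total_area = _scoped(mutations, samples)
    if total_area == 0:
        raise ValueError("no sampled area with known size")
    pct = 100.0 * est["size_mm2"].sum() / total_area
    if pct > 100.0:
        warnings.warn(
            f"occupancy for {gene} exceeds 100% ({pct:.1f}%): clones overlap",
            stacklevel=2,
        )
    return float(pct)


def clone_table(mutations: pd.DataFrame, samples: pd.DataFrame,
                selected_genes) -> pd.DataFrame:
    """Per-gene clone summaries restricted to positively selected genes.

    One row per selected gene: number of clones (= mutations in samples of
    known area), clone frequency per cm^2, median clone size in mm^2 and
    percent occupancy. Samples lacking a known area are excluded throughout.
    """
    selected = sorted(set(selected_genes))
    rows = []
    for gene in selected:
        est = clone_estimates(mutations, samples, genes=[gene])
        n = len(est)
        rows.append(
            {
                "gene": gene,
                "n_clones": n,
                "clones_per_cm2": clones_per_cm2(mutations, samples, genes=[gene]),
                "median_size_mm2": float(est["size_mm2"].median()) if n else 0.0,
                "occupancy_percent": occupancy_percent(mutations, samples, gene),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "n_clones", "clones_per_cm2", "median_size_mm2",
                 "occupancy_percent"],
    )


def excluded_samples(samples: pd.DataFrame) -> list[str]:
    """Sample ids excluded from clone inference for lack of a known area."""
    return samples.loc[~samples["area_known"], "sample_id"].tolist()
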