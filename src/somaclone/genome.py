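"""Gene panel and mutation-table data model.

A panel is a set of coding sequences (one per gene) with single-base flanking
context at the CDS edges and a gene-set label (driver / immune / housekeeping).
Mutations live in a pandas DataFrame keyed by sample, gene and 1-based CDS
position. This module owns the file formats, codon-table consequence
annotation, and the proximity-flag / phase-merge rules used to recover
dinucleotide and multinucleotide variants from phased SNV calls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trinuc import BASES, classify_96

GENE_SETS = ("driver", "immune", "housekeeping")

CONSEQUENCES = ("synonymous", "missense", "nonsense", "stoploss")

# Standard genetic code, in the canonical TCAG codon order.
_CODON_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    "".join(codon): aa
    for codon, aa in zip(itertools.product(_CODON_BASES, repeat=3), _AMINO)
}

MUTATION_COLUMNS = ["sample_id", "gene_id", "pos", "ref", "alt", "vaf", "phase_tag"]


@dataclass(frozen=True)
class GeneModel:
    """One coding sequence with edge context and a gene-set label.

    ``cds`` includes the terminal stop codon; ``flank5``/``flank3`` are the
    single reference bases immediately 5' and 3' of the CDS on the coding
    strand, needed to assign trinucleotide context to the first and last
    positions. ``strand`` records the gene's orientation on the reference the
    context was read from.
    """

    gene_id: str
    cds: str
    gene_set: str
    flank5: str = "A"
    flank3: str = "A"
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.cds) < 6 or len(self.cds) % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {len(self.cds)} must be >= 6 "
                "and divisible by 3"
            )
        if any(b not in BASES for b in self.cds):
            raise ValueError(f"gene {self.gene_id}: CDS contains non-ACGT bases")
        for name, b in (("flank5", self.flank5), ("flank3", self.flank3)):
            if len(b) != 1 or b not in BASES:
                raise ValueError(f"gene {self.gene_id}: {name} must be one of ACGT")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.gene_set not in GENE_SETS:
            raise ValueError(
                f"gene {self.gene_id}: gene_set {self.gene_set!r} not in {GENE_SETS}"
            )

    def __len__(self) -> int:
        return len(self.cds)

    @property
    def padded(self) -> str:
        """CDS with single-base flanks attached."""
        return self.flank5 + self.cds + self.flank3

    def context(self, pos: int) -> str:
        """Coding-strand trinucleotide context at a 1-based CDS position."""
        if not 1 <= pos <= len(self.cds):
            raise ValueError(f"gene {self.gene_id}: position {pos} outside CDS")
        return self.padded[pos - 1 : pos + 2]


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code ('*' for stop)."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def annotate_consequence(gene: GeneModel, pos: int, ref: str, alt: str) -> str:
    """Codon-table consequence of a single-base substitution.

    Returns one of ``synonymous`` (amino acid, incl. stop, unchanged),
    ``nonsense`` (non-stop codon becomes stop), ``stoploss`` (stop codon
    becomes non-stop) or ``missense``.
    """
    if not 1 <= pos <= len(gene.cds):
        raise ValueError(f"gene {gene.gene_id}: position {pos} outside CDS")
    if gene.cds[pos - 1] != ref:
        raise ValueError(
            f"gene {gene.gene_id}: ref {ref} does not match CDS base "
            f"{gene.cds[pos - 1]} at position {pos}"
        )
    if alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    i = (pos - 1) // 3
    offset = (pos - 1) % 3
    codon = gene.cds[3 * i : 3 * i + 3]
    mutated = codon[:offset] + alt + codon[offset + 1 :]
    aa0, aa1 = CODON_TABLE[codon], CODON_TABLE[mutated]
    if aa0 == aa1:
        return "synonymous"
    if aa1 == "*":
        return "nonsense"
    if aa0 == "*":
        return "stoploss"
    return "missense"


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------

def _parse_description_tokens(description: str) -> dict[str, str]:
    tokens = {}
    for word in description.split()[1:]:
        if "=" in word:
            key, _, value = word.partition("=")
            tokens[key] = value
    return tokens


def read_panel(fasta_path, metadata_path) -> dict[str, GeneModel]:
    """Read a gene panel from a CDS FASTA plus a gene metadata table.

    The FASTA holds one record per gene (ID = gene_id); optional
    ``flank5=``/``flank3=``/``strand=`` tokens in the record description carry
    edge context (defaulting to A/A/+). The metadata TSV maps gene_id to
    gene_set and may override flanks/strand via optional columns. Every FASTA
    record must have a metadata row and vice versa.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "gene_id" not in meta.columns or "gene_set" not in meta.columns:
        raise ValueError("metadata table needs gene_id and gene_set columns")
    meta = meta.set_index("gene_id")
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate metadata rows for genes: {dupes}")

    panel: dict[str, GeneModel] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = record.id
        if gene_id not in meta.index:
            raise ValueError(f"gene {gene_id}: no metadata row")
        tokens = _parse_description_tokens(record.description)
        row = meta.loc[gene_id]
        for key in ("flank5", "flank3", "strand"):
            if key in meta.columns and pd.notna(row.get(key)):
                tokens[key] = str(row[key])
        panel[gene_id] = GeneModel(
            gene_id=gene_id,
            cds=str(record.seq).upper(),
            gene_set=str(row["gene_set"]),
            flank5=tokens.get("flank5", "A"),
            flank3=tokens.get("flank3", "A"),
            strand=tokens.get("strand", "+"),
        )
    missing = set(meta.index) - set(panel)
    if missing:
        raise ValueError(f"metadata rows without FASTA record: {sorted(missing)}")
    if not panel:
        raise ValueError("empty panel")
    return panel


def write_panel(panel: dict[str, GeneModel], fasta_path, metadata_path) -> None:
    """Write a panel as CDS FASTA + metadata TSV (inverse of read_panel)."""
    records = [
        SeqRecord(
            Seq(g.cds),
            id=g.gene_id,
            description=f"flank5={g.flank5} flank3={g.flank3} strand={g.strand}",
        )
        for g in panel.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in panel.values()],
            "gene_set": [g.gene_set for g in panel.values()],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutation-table I/O and annotation
# ---------------------------------------------------------------------------

def read_mutations(path) -> pd.DataFrame:
    """Read a mutation table TSV (sample_id gene_id pos ref alt vaf [phase_tag])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str,
                                            "ref": str, "alt": str,
                                            "phase_tag": str},
                     comment="#")
    required = {"sample_id", "gene_id", "pos", "ref", "alt", "vaf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    if "phase_tag" not in df.columns:
        df["phase_tag"] = pd.NA
    df["pos"] = df["pos"].astype(int)
    df["vaf"] = df["vaf"].astype(float)
    bad = df[(df["vaf"] <= 0) | (df["vaf"] > 1)]
    if len(bad):
        raise ValueError(f"VAF outside (0, 1] in {len(bad)} rows")
    return df[MUTATION_COLUMNS + [c for c in df.columns if c not in MUTATION_COLUMNS]]


def write_mutations(mutations: pd.DataFrame, path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> pd.DataFrame:
    """Minimal VCF reader: CHROM = gene_id, POS = CDS position, INFO VAF=.

    Sample identity is taken from the INFO ``SAMPLE=`` key if present,
    otherwise from the single VCF sample column.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    rows = []
    vcf_samples = list(vcf.header.samples)
    for rec in vcf:
        for alt in rec.alts or ():
            if "SAMPLE" in rec.info:
                sample = rec.info["SAMPLE"]
            else:
                sample = vcf_samples[0] if vcf_samples else "sample1"
            if "VAF" not in rec.info:
                raise ValueError(f"VCF record {rec.chrom}:{rec.pos} lacks INFO VAF")
            vaf = rec.info["VAF"]
            if isinstance(vaf, tuple):
                vaf = vaf[0]
            rows.append(
                {
                    "sample_id": str(sample),
                    "gene_id": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "vaf": float(vaf),
                    "phase_tag": rec.info["PHASE"] if "PHASE" in rec.info else None,
                }
            )
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    df["phase_tag"] = df["phase_tag"].astype("object")
    return df


def annotate_mutations(mutations: pd.DataFrame, panel: dict[str, GeneModel]) -> pd.DataFrame:
    """Attach var_class, coding-strand context, consequence and class label.

    SNVs get a trinucleotide context, codon-table consequence and 96-class
    label; DNV/MNV rows (multi-base ref/alt) get var_class only. Reference
    mismatches against the panel CDS are rejected naming the offending gene.
    """
    df = mutations.copy()
    var_class, contexts, consequences, labels = [], [], [], []
    for row in df.itertuples(index=False):
        gene = panel.get(row.gene_id)
        if gene is None:
            raise ValueError(f"mutation in unknown gene {row.gene_id}")
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != len(alt):
            raise ValueError(
                f"gene {row.gene_id} pos {row.pos}: ref/alt length mismatch"
            )
        if gene.cds[row.pos - 1 : row.pos - 1 + len(ref)] != ref:
            raise ValueError(
                f"gene {row.gene_id}: ref {ref} does not match CDS at pos {row.pos}"
            )
        if len(ref) == 1:
            var_class.append("SNV")
            contexts.append(gene.context(row.pos))
            consequences.append(annotate_consequence(gene, row.pos, ref, alt))
            labels.append(classify_96(contexts[-1], ref, alt).label)
        else:
            var_class.append("DNV" if len(ref) == 2 else "MNV")
            contexts.append(None)
            consequences.append(None)
            labels.append(None)
    df["var_class"] = var_class
    df["context"] = contexts
    df["consequence"] = consequences
    df["class_label"] = labels
    return df


# ---------------------------------------------------------------------------
# Proximity flagging and phase merging
# ---------------------------------------------------------------------------

def flag_proximal(mutations: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Pairs of mutations in the same sample and gene within ``window`` bp.

    Returns a DataFrame with columns sample_id, gene_id, pos_a, pos_b
    (pos_a < pos_b, distance inclusive of exactly ``window``).
    """
    pairs = []
    for (sample, gene), grp in mutations.groupby(["sample_id", "gene_id"], sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if pos[j] - pos[i] > window:
                    break
                pairs.append((sample, gene, int(pos[i]), int(pos[j])))
    return pd.DataFrame(pairs, columns=["sample_id", "gene_id", "pos_a", "pos_b"])


def merge_phased(mutations: pd.DataFrame) -> pd.DataFrame:
    """Collapse runs of adjacent, same-phase-tag SNVs into DNV/MNV records.

    Mutations sharing a phase tag were observed on the same reads; runs of
    consecutive CDS positions among them are merged into one record whose
    ref/alt are the concatenated bases and whose VAF is the arithmetic mean of
    the members. Untagged or non-adjacent mutations pass through unchanged.
    """
    df = mutations.copy()
    tagged = df[df["phase_tag"].notna()]
    key = tagged[["sample_id", "gene_id", "pos"]]
    if key.duplicated().any():
        raise ValueError("same position appears in more than one phased record")

    merged_rows = []
    drop_idx: list = []
    for (sample, gene, tag), grp in tagged.groupby(
        ["sample_id", "gene_id", "phase_tag"], sort=False
    ):
        grp = grp.sort_values("pos")
        run: list = []
        def flush(run):
            if len(run) >= 2:
                merged_rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": gene,
                        "pos": run[0].pos,
                        "ref": "".join(str(r.ref) for r in run),
                        "alt": "".join(str(r.alt) for r in run),
                        "vaf": float(np.mean([r.vaf for r in run])),
                        "phase_tag": tag,
                    }
                )
                drop_idx.extend(r.Index for r in run)
        for row in grp.itertuples():
            if len(str(row.ref)) != 1:
                flush(run)
                run = []
                continue
            if run and row.pos == run[-1].pos + 1:
                run.append(row)
            else:
                flush(run)
                run = [row]
        flush(run)

    kept = df.drop(index=drop_idx)
    if merged_rows:
        extra = pd.DataFrame(merged_rows, columns=MUTATION_COLUMNS)
        extra = extra.reindex(columns=kept.columns)
        out = pd.concat([kept.astype(object), extra.astype(object)],
                        ignore_index=True)
        out["pos"] = out["pos"].astype(int)
        out["vaf"] = out["vaf"].astype(float)
    else:
        out = kept
    return out.sort_values(["sample_id", "gene_id", "pos"]).reset_index(drop=True)
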