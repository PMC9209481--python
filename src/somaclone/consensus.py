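"""Barcode-family consensus calling and hotspot VAF quantification.

Reads sharing a unique molecular barcode derive from one original DNA
molecule; grouping them into barcode families and requiring within-family
agreement suppresses sequencing and PCR errors, enabling mutation detection
well below the raw error rate. The consensus rules implemented here are:

* families with fewer than 10 reads are rejected;
* families with 10-20 reads must be unanimous (all reads identical);
* families with more than 20 reads accept the plurality read sequence if it
  accounts for at least 90% of the family.

Hotspot VAFs are the fraction of accepted consensus reads carrying the
alternate base at each hotspot position, e.g. the C>T UV hotspots in the
CTTCCGG ETS motifs of the RPL13A and DPH3 promoters.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

MIN_FAMILY_SIZE = 10
UNANIMITY_MAX_SIZE = 20
PLURALITY_FRACTION = 0.9


@dataclass
class BarcodeFamily:
    """Reads sharing one molecular barcode."""

    barcode: str
    reads: list[str]

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class HotspotDef:
    """A UV hotspot: an amplicon with motif-anchored mutant positions."""

    amplicon_id: str
    reference: str
    motif: str
    motif_offset: int
    mutant_positions: list[int]
    ref_base: str = "C"
    alt_base: str = "T"

    def __post_init__(self) -> None:
        end = self.motif_offset + len(self.motif)
        if self.reference[self.motif_offset : end] != self.motif:
            raise ValueError(
                f"{self.amplicon_id}: motif {self.motif} not at offset "
                f"{self.motif_offset}"
            )
        for pos in self.mutant_positions:
            if self.reference[pos] != self.ref_base:
                raise ValueError(
                    f"{self.amplicon_id}: reference base at {pos} is "
                    f"{self.reference[pos]}, expected {self.ref_base}"
                )


def group_families(reads) -> list[BarcodeFamily]:
    """Group (barcode, sequence) pairs into families, preserving read order."""
    families: "OrderedDict[str, list[str]]" = OrderedDict()
    for barcode, seq in reads:
        if not barcode:
            raise ValueError("read without barcode tag")
        families.setdefault(barcode, []).append(seq)
    return [BarcodeFamily(bc, rds) for bc, rds in families.items()]


def call_consensus(family: BarcodeFamily,
                   per_base: bool = False) -> str | None:
    """Consensus sequence of a barcode family, or None if rejected.

    Default mode applies whole-read identity rules (see module docstring).
    ``per_base=True`` instead takes a per-position majority vote with the same
    size thresholds and a >=90% per-base agreement requirement, offered as an
    alternative; ties reject in both modes.
    """
    if family.size == 0:
        raise ValueError("empty barcode family")
    if family.size < MIN_FAMILY_SIZE:
        return None
    if per_base:
        return _per_base_consensus(family)
    counts = Counter(family.reads)
    top_seq, top_n = counts.most_common(1)[0]
    if family.size <= UNANIMITY_MAX_SIZE:
        return top_seq if top_n == family.size else None
    # ties for the plurality read cannot reach 90%, so they reject naturally
    if top_n / family.size >= PLURALITY_FRACTION:
        return top_seq
    return None


def _per_base_consensus(family: BarcodeFamily) -> str | None:
    length = len(family.reads[0])
    threshold = 1.0 if family.size <= UNANIMITY_MAX_SIZE else PLURALITY_FRACTION
    out = []
    for i in range(length):
        counts = Counter(read[i] for read in family.reads)
        base, n = counts.most_common(1)[0]
        if n / family.size < threshold:
            return None
        out.append(base)
    return "".join(out)


def consensus_reads(families, per_base: bool = False) -> list[str]:
    """Accepted consensus sequences of a family collection."""
    out = []
    for fam in families:
        cons = call_consensus(fam, per_base=per_base)
        if cons is not None:
            out.append(cons)
    return out


def hotspot_vaf(consensus: list[str], hotspot: HotspotDef) -> pd.DataFrame:
    """Per-position VAF of the hotspot substitution among consensus reads.

    Each row is one mutant position: amplicon, position (0-based), ref, alt,
    number of mutant families, total families, VAF.
    """
    if len(consensus) == 0:
        raise ValueError("no accepted consensus reads")
    rows = []
    for pos in hotspot.mutant_positions:
        n_mut = sum(1 for seq in consensus if seq[pos] == hotspot.alt_base)
        rows.append(
            {
                "amplicon": hotspot.amplicon_id,
                "position": pos,
                "ref": hotspot.ref_base,
                "alt": hotspot.alt_base,
                "n_mut_families": n_mut,
                "n_families": len(consensus),
                "vaf": n_mut / len(consensus),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_barcoded_fastq(path, barcode_length: int | None = None):
    """Yield (barcode, sequence) pairs from a barcoded FASTQ.

    With ``barcode_length`` the barcode is a fixed-length read prefix and is
    stripped from the returned sequence; otherwise it is parsed from a
    ``UMI:<barcode>`` token in the read description.
    """
    pairs = []
    for record in SeqIO.parse(str(path), "fastq"):
        seq = str(record.seq)
        if barcode_length is not None:
            if len(seq) <= barcode_length:
                raise ValueError(f"read {record.id} shorter than barcode")
            pairs.append((seq[:barcode_length], seq[barcode_length:]))
        else:
            barcode = None
            for token in record.description.split():
                if token.startswith("UMI:"):
                    barcode = token[4:]
            if not barcode:
                raise ValueError(f"read {record.id} lacks a UMI: header token")
            pairs.append((barcode, seq))
    return pairs


def write_consensus_fasta(consensus: list[str], path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(consensus):
            fh.write(f">consensus_{i}\n{seq}\n")


def default_hotspots() -> list[HotspotDef]:
    """Synthetic stand-ins for the RPL13A and DPH3 promoter UV hotspots.

    Amplicon names carry the genomic windows of the real assays; the reference
    sequences are synthetic (no genome download) but contain the CTTCCGG ETS
    motif, with the motif's CC dinucleotide as the mutant C>T positions.
    """
    motif = "CTTCCGG"

    def build(amplicon_id: str, length: int, offset: int) -> HotspotDef:
        # deterministic filler pattern around the motif; synthetic sequence
        filler = ("ACGGATTCGAGTCAGGTACCTAGATCGGTAAC" * 8)
        ref = filler[:offset] + motif + filler[offset : length - len(motif)]
        ref = ref[:length]
        return HotspotDef(
            amplicon_id=amplicon_id,
            reference=ref,
            motif=motif,
            motif_offset=offset,
            mutant_positions=[offset + 3, offset + 4],
        )

    return [
        build("RPL13A_chr19:49487384-49487466", 83, 30),
        build("DPH3_chr3:16264961-16265030", 70, 25),
    ]
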