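"""Mutational spectra, substitution-class priors, UV diagnostics, signatures.

Covers the 96-class spectrum of a mutation set, estimation of class priors
from a reference catalogue (the stand-in for TCGA SKCM/HNSC frequencies),
dipyrimidine-context and transcriptional strand-bias statistics that
characterize UV mutagenesis, CC>TT dinucleotide strand analysis, and
refitting of known mutational signatures by non-negative least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trinuc import (
    CLASS_INDEX,
    CLASS_LABELS,
    N_CLASSES,
    PYRIMIDINES,
    classify_96,
    is_c_to_t,
    is_dipyrimidine,
    revcomp,
)


@dataclass
class Spectrum96:
    """Counts over the 96 trinucleotide substitution classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES,):
            raise ValueError("spectrum must have 96 entries")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_snv(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.n_snv == 0:
            raise ValueError("empty spectrum has no frequencies")
        return self.counts / self.n_snv

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CLASS_LABELS), name="count")


@dataclass
class SpectrumPrior:
    """Per-class substitution probabilities P_i (96 entries summing to 1)."""

    p: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_CLASSES,):
            raise ValueError("prior must have 96 entries")
        if (self.p < 0).any():
            raise ValueError("negative probabilities")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError(f"prior sums to {self.p.sum()}, not 1")

    @classmethod
    def uniform(cls, source_label: str = "uniform") -> "SpectrumPrior":
        return cls(np.full(N_CLASSES, 1.0 / N_CLASSES), source_label)

    def to_series(self) -> pd.Series:
        return pd.Series(self.p, index=list(CLASS_LABELS), name="p")


@dataclass
class StrandCounts:
    """Substitution counts by the strand carrying the mutated pyrimidine."""

    coding: int
    template: int

    def __post_init__(self) -> None:
        if self.coding < 0 or self.template < 0:
            raise ValueError("strand counts must be non-negative")


def compute_spectrum(mutations: pd.DataFrame) -> Spectrum96:
    """96-class spectrum of the SNVs in an annotated mutation table.

    DNV/MNV records are excluded; rows must carry a ``class_label`` column
    (see :func:`somaclone.genome.annotate_mutations`).
    """
    counts = np.zeros(N_CLASSES, dtype=int)
    snvs = mutations[mutations["class_label"].notna()]
    for label in snvs["class_label"]:
        counts[CLASS_INDEX[label]] += 1
    return Spectrum96(counts)


def estimate_prior(catalogue: pd.DataFrame, source_label: str = "") -> SpectrumPrior:
    """Class priors from a reference mutation catalogue.

    The catalogue is a MAF-like table with ``context``, ``ref`` and ``alt``
    columns; priors are the raw class frequencies (zero-count classes get
    probability 0, no pseudo-count).
    """
    if len(catalogue) == 0:
        raise ValueError("empty catalogue")
    counts = np.zeros(N_CLASSES, dtype=float)
    for row in catalogue.itertuples(index=False):
        sc = classify_96(str(row.context), str(row.ref), str(row.alt))
        counts[sc.index] += 1
    return SpectrumPrior(counts / counts.sum(), source_label)


def dipyrimidine_fraction(mutations: pd.DataFrame) -> float:
    """Fraction of C>T SNVs whose context is a dipyrimidine.

    A substitution counts as dipyrimidine if, on the strand carrying the
    mutated pyrimidine, the 5' or 3' neighbour is also a pyrimidine (C or T).
    G>A calls are strand-normalized first. Raises on empty input.
    """
    snvs = mutations[mutations["class_label"].notna()]
    ct = snvs[snvs["class_label"].map(is_c_to_t)]
    if len(ct) == 0:
        raise ValueError("no C>T SNVs to evaluate")
    hits = ct["class_label"].map(is_dipyrimidine)
    return float(hits.mean())


def strand_counts(mutations: pd.DataFrame, subst_type: str | None = "C>T") -> StrandCounts:
    """Count SNVs by the strand carrying the mutated pyrimidine.

    The context/ref columns are reported on the coding strand, so a pyrimidine
    ref means the pyrimidine sits on the coding (untranscribed) strand and a
    purine ref puts it on the template strand. ``subst_type`` restricts to one
    pyrimidine-normalized substitution type (e.g. ``"C>T"``); None keeps all.
    """
    snvs = mutations[mutations["class_label"].notna()]
    if subst_type is not None:
        snvs = snvs[snvs["class_label"].str.slice(2, 5) == subst_type]
    on_coding = snvs["ref"].isin(list(PYRIMIDINES))
    return StrandCounts(int(on_coding.sum()), int((~on_coding).sum()))


def strand_bias_test(sc: StrandCounts, alternative: str = "two-sided") -> dict:
    """Exact test of equal mutation rates on the coding vs template strand.

    Two Poisson counts with equal exposure are compared conditionally, which
    reduces to an exact binomial test of the coding count out of the total
    with success probability 0.5. Returns the coding/template ratio, the
    percent excess on the coding strand, and the p-value.
    """
    total = sc.coding + sc.template
    if total == 0:
        raise ValueError("both strand counts are zero")
    ratio = sc.coding / sc.template if sc.template > 0 else math.inf
    excess = 100.0 * (ratio - 1.0) if math.isfinite(ratio) else math.inf
    p = stats.binomtest(sc.coding, total, 0.5, alternative=alternative).pvalue
    return {"ratio": ratio, "excess_percent": excess, "p": float(p)}


def dnv_strand_analysis(mutations: pd.DataFrame) -> dict:
    """Strand distribution of CC>TT dinucleotide variants.

    CC>TT on the coding strand appears as ref ``CC``; the same event with the
    dipyrimidine on the template strand appears as ``GG>AA``. Returns the
    coding-strand fraction and a one-sided exact binomial p-value against 0.5.
    """
    dnvs = mutations[(mutations["ref"].str.len() == 2)]
    coding = int(((dnvs["ref"] == "CC") & (dnvs["alt"] == "TT")).sum())
    template = int(((dnvs["ref"] == "GG") & (dnvs["alt"] == "AA")).sum())
    total = coding + template
    if total == 0:
        raise ValueError("no CC>TT dinucleotide variants")
    p = stats.binomtest(coding, total, 0.5, alternative="greater").pvalue
    return {
        "n_coding": coding,
        "n_template": template,
        "fraction_coding": coding / total,
        "p": float(p),
    }


def cosine_similarity(u, v) -> float:
    """Cosine similarity of two non-negative 96-vectors (1 = identical shape)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# Signature matrices and refitting
# ---------------------------------------------------------------------------

@dataclass
class SignatureMatrix:
    """Known mutational signatures: 96 class rows x named signature columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.index) != list(CLASS_LABELS):
            try:
                self.data = self.data.reindex(list(CLASS_LABELS))
            except Exception as exc:  # pragma: no cover
                raise ValueError("signature matrix rows must be the 96 classes") from exc
        if self.data.isna().any().any():
            raise ValueError("signature matrix has missing class rows")
        if self.data.shape[1] < 1:
            raise ValueError("signature matrix needs at least one column")
        if (self.data.values < 0).any():
            raise ValueError("negative signature probabilities")
        sums = self.data.sum(axis=0)
        if (np.abs(sums - 1.0) > 1e-6).any():
            bad = sums[np.abs(sums - 1.0) > 1e-6].index.tolist()
            raise ValueError(f"signature columns do not sum to 1: {bad}")

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_signatures(path) -> SignatureMatrix:
    """Read a signature matrix TSV (first column = class label)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(df)


def write_signatures(sigs: SignatureMatrix, path) -> None:
    sigs.data.rename_axis("class").to_csv(path, sep="\t")


def refit_signatures(spectrum: Spectrum96, sigs: SignatureMatrix) -> pd.Series:
    """Estimate per-signature exposure proportions for one spectrum.

    Non-negative least squares fits the spectrum's class frequencies as a
    mixture of the signature columns; exposures are renormalized to
    proportions summing to 1.
    """
    if spectrum.n_snv == 0:
        raise ValueError("cannot refit an empty spectrum")
    matrix = sigs.values()
    if (matrix.sum(axis=0) == 0).any():
        raise ValueError("signature matrix has a zero column")
    freq = spectrum.frequencies()
    exposures, _ = optimize.nnls(matrix, freq)
    total = exposures.sum()
    if total == 0:
        raise ValueError("all-zero exposure fit")
    return pd.Series(exposures / total, index=sigs.names, name="exposure")


def default_signature_matrix() -> SignatureMatrix:
    """A small synthetic signature set for offline analyses and tests.

    Four columns: a UV-like signature (C>T at dipyrimidines, 5'-pyrimidine
    weighted, qualitatively mirroring the dominant SBS7 peaks), a flat
    background, a C>A-heavy (smoking-like) and a T>C-heavy (clock-like)
    signature. Real catalogues (e.g. COSMIC) can be supplied as TSV instead.
    """
    cols = {}
    uv = np.zeros(N_CLASSES)
    for i, lab in enumerate(CLASS_LABELS):
        if is_c_to_t(lab) and lab[0] in PYRIMIDINES:
            uv[i] = 2.0 if lab[0] == "T" else 1.0
    cols["UV"] = uv / uv.sum()
    cols["Flat"] = np.full(N_CLASSES, 1.0 / N_CLASSES)
    ca = np.array([1.0 if lab[2:5] == "C>A" else 0.0 for lab in CLASS_LABELS])
    cols["Smoking-like"] = ca / ca.sum()
    tc = np.array([1.0 if lab[2:5] == "T>C" else 0.0 for lab in CLASS_LABELS])
    cols["Clock-like"] = tc / tc.sum()
    return SignatureMatrix(pd.DataFrame(cols, index=list(CLASS_LABELS)))


def uv_class_profile() -> np.ndarray:
    """The UV-like per-class probability profile used by the generator."""
    return default_signature_matrix().data["UV"].to_numpy()
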