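"""Pyrimidine-centred trinucleotide substitution classes.

Single-base substitutions are conventionally collapsed onto 96 classes of the
form ``X[P>Q]Y`` where ``P`` is the mutated pyrimidine (C or T), ``Q`` the
alternate base and ``X``/``Y`` the 5'/3' neighbours on the pyrimidine-bearing
strand. Purine-centred substitutions are mapped to their reverse complement,
so each class pools both strand orientations of the same chemical event.
"""

from __future__ import annotations

from dataclasses import dataclass

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def comp(base: str) -> str:
    """Complement of a single base (or base string, position-wise)."""
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SubstitutionClass:
    """One of the 96 pyrimidine-centred trinucleotide substitution classes."""

    index: int
    label: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _all_labels() -> tuple[str, ...]:
    labels = []
    for ref in "CT":
        for alt in BASES:
            if alt == ref:
                continue
            for five in BASES:
                for three in BASES:
                    labels.append(f"{five}[{ref}>{alt}]{three}")
    return tuple(sorted(labels))


#: All 96 class labels in lexicographic order; this is the canonical row order
#: used for spectra, priors and signature matrices throughout the package.
CLASS_LABELS: tuple[str, ...] = _all_labels()
CLASS_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CLASS_LABELS)}
N_CLASSES = len(CLASS_LABELS)


def class_label(context: str, ref: str, alt: str) -> str:
    """Pyrimidine-normalized class label for a substitution in context."""
    return classify_96(context, ref, alt).label


def classify_96(context: str, ref: str, alt: str) -> SubstitutionClass:
    """Map a substitution with its coding-strand context onto its class.

    Parameters
    ----------
    context : str
        3-mer centred on the mutated base, on the strand the mutation was
        reported on.
    ref, alt : str
        Reference and alternate single bases on that same strand.

    Purine-centred calls are reverse-complemented so the returned class is
    always pyrimidine-centred; the mapping is a strand involution.
    """
    if len(context) != 3:
        raise ValueError(f"context must be a 3-mer, got {context!r}")
    if any(b not in BASES for b in context + ref + alt):
        raise ValueError(f"non-ACGT character in {context!r} {ref!r}>{alt!r}")
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("classify_96 handles single-base substitutions only")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if context[1] != ref:
        raise ValueError(f"context {context!r} centre does not match ref {ref!r}")
    if ref in PURINES:
        context = revcomp(context)
        ref = comp(ref)
        alt = comp(alt)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return SubstitutionClass(CLASS_INDEX[label], label)


def parse_label(label: str) -> tuple[str, str, str]:
    """Split a class label into (context, ref, alt)."""
    if label not in CLASS_INDEX:
        raise ValueError(f"not a substitution class label: {label!r}")
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def is_c_to_t(label: str) -> bool:
    """True for C>T classes (the UV-photoproduct substitution type)."""
    return label[2:5] == "C>T"


def is_dipyrimidine(label: str) -> bool:
    """True if either neighbour of the mutated pyrimidine is a pyrimidine."""
    return label[0] in PYRIMIDINES or label[-1] in PYRIMIDINES
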