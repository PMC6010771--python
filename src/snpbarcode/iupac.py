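"""IUPAC nucleotide-ambiguity utilities.

RAD consensus sequences encode a diploid genotype per individual as a
single character: ``A`` means the A/A homozygote, ``R`` the A/G
heterozygote, and so on.  ``N`` and ``-`` are treated as missing data.
Three- and four-allele ambiguity codes (B, D, H, V, N) cannot represent
a diploid genotype and are handled explicitly by callers.
"""

from __future__ import annotations

CODE_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_SET.items()}

#: Characters accepted in locus alignments.
ALPHABET = frozenset(CODE_TO_SET) | {"-"}

#: Codes representing a valid diploid genotype (one or two alleles).
DIPLOID_CODES = frozenset(k for k, v in CODE_TO_SET.items() if len(v) <= 2)

#: Codes treated as missing data in genotype context.
MISSING_CODES = frozenset({"N", "-"})

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def genotype_from_code(code: str) -> tuple[str, str] | None:
    """Expand a single IUPAC character into an unordered diploid genotype.

    Returns ``None`` for missing data (``N``/``-``) and for 3+-allele
    ambiguity codes, which cannot be interpreted as one diploid call.
    Alleles are returned in lexical order.
    """
    code = code.upper()
    if code == "-":
        return None
    s = CODE_TO_SET.get(code)
    if s is None:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}")
    if code in MISSING_CODES or len(s) > 2:
        return None
    if len(s) == 1:
        (a,) = s
        return (a, a)
    a, b = sorted(s)
    return (a, b)


def code_from_genotype(a: str, b: str) -> str:
    """Collapse an unordered diploid genotype into one IUPAC character."""
    key = frozenset((a.upper(), b.upper()))
    try:
        return SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"not a diploid nucleotide genotype: {a}/{b}") from None


def minimal_cover(alleles) -> str:
    """Smallest IUPAC code whose allele set equals the observed set.

    Every non-empty subset of {A,C,G,T} has exactly one code, so the
    minimal cover is the exact-set lookup.
    """
    key = frozenset(a.upper() for a in alleles)
    if not key:
        raise ValueError("cannot cover an empty allele set")
    try:
        return SET_TO_CODE[key]
    except KeyError:
        bad = key - frozenset("ACGT")
        raise ValueError(f"non-nucleotide alleles: {sorted(bad)}") from None


def expand(code: str) -> frozenset[str]:
    """Set of concrete bases compatible with an IUPAC character."""
    try:
        return CODE_TO_SET[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def compatible(a: str, b: str) -> bool:
    """True when two IUPAC characters can denote the same base."""
    return bool(expand(a) & expand(b))


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence, mapping ambiguity codes correctly."""
    return seq.upper().translate(_COMPLEMENT)[::-1]
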