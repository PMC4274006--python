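"""Shared sequence alphabet helpers.

The pipeline works on upper-case DNA with the two-base IUPAC ambiguity
codes used for heterozygous positions (W, M, R, Y, S, K) plus N.  Bases
are compared either literally (genotype/ST identity, distances) or by
IUPAC compatibility (read-overlap matching), so both views live here.
"""

from __future__ import annotations

from Bio.Seq import Seq

PURE_BASES = "ACGT"

# two-base ambiguity codes <-> unordered allele pairs
IUPAC_HET: dict[frozenset[str], str] = {
    frozenset("AT"): "W",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("GT"): "K",
}
HET_ALLELES: dict[str, frozenset[str]] = {v: k for k, v in IUPAC_HET.items()}

# bitmask encoding: A=1 C=2 G=4 T=8; ambiguity codes are unions
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
BASE_MASK: dict[str, int] = dict(_BIT)
for code, pair in HET_ALLELES.items():
    BASE_MASK[code] = _BIT[min(pair)] | _BIT[max(pair)]
BASE_MASK["N"] = 15


def het_code(a: str, b: str) -> str:
    """IUPAC code for the unordered allele pair {a, b}."""
    return IUPAC_HET[frozenset((a, b))]


def is_ambiguous(base: str) -> bool:
    return base not in PURE_BASES


def compatible(a: str, b: str) -> bool:
    """True if the two symbols share at least one underlying base."""
    return bool(BASE_MASK.get(a, 0) & BASE_MASK.get(b, 0))


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return str(Seq(seq).reverse_complement())
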