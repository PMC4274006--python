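"""Bidirectional consensus assembly with IUPAC heterozygote calling.

One trimmed forward read and one trimmed reverse read per individual
are merged by the best ungapped offset alignment.  A pair is accepted
when the overlap spans at least 80% of the shorter read and at least
98% of the overlapping positions match (IUPAC-compatible symbols count
as matches).  At an overlap position a two-base IUPAC code is emitted
only when both strands show a secondary peak above the threshold (40%
of the primary peak by default) and agree on the allele pair —
bidirectional confirmation; a position covered by a single strand takes
that strand's call and can never be heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._seq import BASE_MASK, het_code, reverse_complement
from .errors import UsageError
from .traceqc import TrimmedRead

MIN_OVERLAP_FRAC = 0.80
MIN_MATCH = 0.98
HET_THRESHOLD = 0.40


@dataclass(frozen=True)
class BaseCall:
    call: str
    het: bool = False
    conflict: bool = False


@dataclass(frozen=True)
class LocusContig:
    """Assembled consensus for one sample x locus."""

    sample_id: str
    locus_id: str
    consensus: str
    het_positions: tuple[int, ...]  # 1-based on the consensus
    support: tuple[Literal["both_strands", "single_strand"], ...]
    conflicts: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.support) != len(self.consensus):
            raise UsageError("support track length != consensus length")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class AssemblyResult:
    sample_id: str
    locus_id: str
    accepted: bool
    contig: LocusContig | None
    offset: int  # start of the reverse-complemented read relative to the forward read
    overlap_len: int
    pct_match: float
    reason: str = ""


def call_heterozygote(
    fwd_frac: float,
    rev_frac: float,
    fwd_base: str,
    rev_base: str,
    second_base: str,
    threshold: float = HET_THRESHOLD,
    fwd_qv: int = 0,
    rev_qv: int = 0,
) -> BaseCall:
    """Resolve one bidirectionally covered position.

    A heterozygote (IUPAC two-base code) is called only when the
    secondary-peak fraction exceeds `threshold` on BOTH strands and the
    strands agree on the allele pair: each strand's primary base must
    belong to {fwd_base, second_base}.  Otherwise the primary base of
    the higher-QV strand is returned; a primary-base disagreement
    without heterozygote evidence is flagged as a conflict.
    """
    alleles = frozenset((fwd_base, second_base))
    if (
        fwd_frac > threshold
        and rev_frac > threshold
        and len(alleles) == 2
        and rev_base in alleles
        and alleles <= set("ACGT")
    ):
        return BaseCall(het_code(*sorted(alleles)), het=True)
    primary = fwd_base if fwd_qv >= rev_qv else rev_base
    if fwd_base != rev_base:
        return BaseCall(primary, conflict=True)
    return BaseCall(primary)


def _mask_array(bases: str) -> np.ndarray:
    return np.fromiter((BASE_MASK.get(b, 0) for b in bases), dtype=np.uint8, count=len(bases))


def _overlap_coords(offset: int, n_fwd: int, n_rev: int) -> tuple[int, int]:
    """[start, end) of the overlap in forward-read coordinates."""
    return max(0, offset), min(n_fwd, offset + n_rev)


def assemble_pair(
    fwd: TrimmedRead,
    rev: TrimmedRead,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
    min_match: float = MIN_MATCH,
    het_threshold: float = HET_THRESHOLD,
) -> AssemblyResult:
    """Assemble a trimmed forward/reverse read pair into a contig.

    The reverse read is reverse-complemented, all offsets giving an
    overlap of at least `min_overlap_frac` x the shorter read are
    scored, and the offset with the highest match fraction (ties: longer
    overlap, then smaller |offset|) is kept.  The pair is rejected when
    no offset reaches both thresholds.
    """
    sample_id, locus_id = fwd.read.sample_id, fwd.read.locus_id
    if fwd.empty or rev.empty or len(fwd) == 0 or len(rev) == 0:
        return AssemblyResult(sample_id, locus_id, False, None, 0, 0, 0.0, "empty read")

    f_bases = fwd.bases
    r_bases = reverse_complement(rev.bases)
    r_qv = fwd_aligned_rev_qv = tuple(reversed(rev.qv))
    r_sec = tuple(reversed(rev.secondary_fraction))
    nf, nr = len(f_bases), len(r_bases)
    required = min_overlap_frac * min(nf, nr)

    f_mask = _mask_array(f_bases)
    r_mask = _mask_array(r_bases)

    best: tuple[float, int, int] | None = None  # (pct_match, overlap, -|offset|)
    best_offset = 0
    for offset in range(-nr + 1, nf):
        lo, hi = _overlap_coords(offset, nf, nr)
        overlap = hi - lo
        if overlap < required or overlap <= 0:
            continue
        matches = int(np.count_nonzero(f_mask[lo:hi] & r_mask[lo - offset : hi - offset]))
        key = (matches / overlap, overlap, -abs(offset))
        if best is None or key > best:
            best = key
            best_offset = offset
    if best is None:
        return AssemblyResult(
            sample_id, locus_id, False, None, 0, 0, 0.0, "no offset with sufficient overlap"
        )
    pct_match, overlap, _ = best
    if pct_match < min_match:
        return AssemblyResult(
            sample_id,
            locus_id,
            False,
            None,
            best_offset,
            overlap,
            round(pct_match, 4),
            f"match {pct_match:.4f} < {min_match}",
        )

    # consensus over the union of covered positions
    offset = best_offset
    union_lo = min(0, offset)
    union_hi = max(nf, offset + nr)
    consensus: list[str] = []
    support: list[str] = []
    het_positions: list[int] = []
    conflicts: list[int] = []
    for u in range(union_lo, union_hi):
        on_f = 0 <= u < nf
        on_r = 0 <= u - offset < nr
        pos = u - union_lo + 1
        if on_f and on_r:
            j = u - offset
            call = call_heterozygote(
                fwd.secondary_fraction[u],
                r_sec[j],
                f_bases[u],
                r_bases[j],
                second_base=r_bases[j] if r_bases[j] != f_bases[u] else f_bases[u],
                threshold=het_threshold,
                fwd_qv=fwd.qv[u],
                rev_qv=fwd_aligned_rev_qv[j],
            )
            consensus.append(call.call)
            support.append("both_strands")
            if call.het:
                het_positions.append(pos)
            if call.conflict:
                conflicts.append(pos)
        elif on_f:
            consensus.append(f_bases[u])
            support.append("single_strand")
        else:
            consensus.append(r_bases[u - offset])
            support.append("single_strand")

    contig = LocusContig(
        sample_id=sample_id,
        locus_id=locus_id,
        consensus="".join(consensus),
        het_positions=tuple(het_positions),
        support=tuple(support),  # type: ignore[arg-type]
        conflicts=tuple(conflicts),
    )
    return AssemblyResult(
        sample_id, locus_id, True, contig, offset, overlap, round(pct_match, 4)
    )


def reconcile_individuals(
    contigs: Sequence[LocusContig],
) -> tuple[LocusContig | None, tuple[int, ...]]:
    """Merge independently assembled individuals of one sample x locus.

    Individuals must agree; the first contig is returned together with
    the 1-based positions where any later individual disagrees (the
    sample x locus is flagged by the caller when that tuple is
    non-empty).  Length mismatches flag position 0.
    """
    contigs = [c for c in contigs if c is not None]
    if not contigs:
        return None, ()
    first = contigs[0]
    disagreements: set[int] = set()
    for other in contigs[1:]:
        if len(other) != len(first):
            disagreements.add(0)
            continue
        disagreements.update(
            i + 1 for i, (a, b) in enumerate(zip(first.consensus, other.consensus)) if a != b
        )
    return first, tuple(sorted(disagreements))
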