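"""Reference-based SNP calling, ST assignment and locus-combination
discriminatory power.

SNPs are substitutions relative to a designated reference individual's
sequence; positions are 1-based reference coordinates.  IUPAC
heterozygote codes are treated as allele symbols in their own right
(A vs R is a difference), so a heterozygous site counts as one SNP site
and contributes to genotype identity.  The distinct allele vector a
sample carries over the SNP columns of a locus combination is its SNP
genotype (ST).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assemble import LocusContig
from .errors import UsageError
from .traceqc import round_half_up


@dataclass(frozen=True)
class SnpCall:
    position_1based: int
    ref_base: str
    sample_base: str


@dataclass(frozen=True)
class SnpColumn:
    locus_id: str
    position_1based: int
    ref_base: str
    observed_alleles: frozenset[str]


@dataclass(frozen=True)
class SnpProfile:
    sample_id: str
    combination: tuple[str, ...]
    alleles: tuple[str, ...]


@dataclass(frozen=True)
class StRegistry:
    """Bijection between distinct allele vectors and ST ids 1..K,
    numbered by first occurrence in input order."""

    combination: tuple[str, ...]
    st_of_vector: Mapping[tuple[str, ...], int]
    members: Mapping[int, tuple[str, ...]]
    st_of_sample: Mapping[str, int]

    @property
    def n_sts(self) -> int:
        return len(self.members)

    def partition(self) -> frozenset[frozenset[str]]:
        """Label-free partition of samples into STs."""
        return frozenset(frozenset(m) for m in self.members.values())


def call_snps(contig: LocusContig, reference: str) -> list[SnpCall]:
    """Variable sites between a consensus contig and the reference.

    The contig must align to the reference without internal gaps; a
    length mismatch beyond end effects is treated as unalignable.  With
    equal lengths the alignment is positional; a shorter contig is
    end-anchored at the offset with the fewest mismatches.
    """
    n_ref, n_c = len(reference), len(contig.consensus)
    if n_c > n_ref:
        raise UsageError(
            f"{contig.sample_id}.{contig.locus_id}: contig longer than reference "
            "(internal gaps required; locus flagged unalignable)"
        )
    seq = contig.consensus
    if n_c == n_ref:
        offset = 0
    else:
        best = None
        for off in range(n_ref - n_c + 1):
            mm = sum(a != b for a, b in zip(seq, reference[off : off + n_c]))
            if best is None or mm < best[0]:
                best = (mm, off)
        offset = best[1]
    return [
        SnpCall(offset + i + 1, reference[offset + i], seq[i])
        for i in range(n_c)
        if seq[i] != reference[offset + i]
    ]


def snp_columns(
    contigs: Mapping[str, LocusContig],
    reference: str,
    locus_id: str,
) -> list[SnpColumn]:
    """Union of variable sites over all samples of one locus."""
    per_pos: dict[int, set[str]] = {}
    ref_base: dict[int, str] = {}
    for contig in contigs.values():
        for call in call_snps(contig, reference):
            per_pos.setdefault(call.position_1based, set()).add(call.sample_base)
            ref_base[call.position_1based] = call.ref_base
    return [
        SnpColumn(locus_id, pos, ref_base[pos], frozenset(per_pos[pos]))
        for pos in sorted(per_pos)
    ]


def build_profiles(
    contigs_by_locus: Mapping[str, Mapping[str, LocusContig]],
    references: Mapping[str, str],
    combination: Sequence[str],
) -> tuple[list[SnpProfile], list[SnpColumn]]:
    """Per-sample allele vectors over the SNP columns of a combination.

    Column order is (locus order in the combination, then position
    ascending).  Samples missing any locus of the combination are
    excluded (they cannot be typed on it).
    """
    combination = tuple(combination)
    columns: list[SnpColumn] = []
    for locus in combination:
        columns.extend(snp_columns(contigs_by_locus[locus], references[locus], locus))
    samples = None
    for locus in combination:
        present = set(contigs_by_locus[locus])
        samples = present if samples is None else samples & present
    profiles = []
    for sample in sorted(samples or ()):
        # one gap-free alignment per locus: ref position -> sample base
        aligned: dict[str, dict[int, str]] = {}
        for locus in combination:
            calls = call_snps(contigs_by_locus[locus][sample], references[locus])
            aligned[locus] = {c.position_1based: c.sample_base for c in calls}
        alleles = tuple(
            aligned[col.locus_id].get(col.position_1based, col.ref_base) for col in columns
        )
        profiles.append(SnpProfile(sample, combination, alleles))
    return profiles, columns


def assign_sts(profiles: Iterable[SnpProfile]) -> StRegistry:
    """Assign ST numbers to distinct allele vectors (first-occurrence
    order)."""
    profiles = list(profiles)
    if not profiles:
        raise UsageError("assign_sts needs at least one profile")
    combos = {p.combination for p in profiles}
    if len(combos) != 1:
        raise UsageError(f"profiles mix combinations: {sorted(combos)}")
    st_of_vector: dict[tuple[str, ...], int] = {}
    members: dict[int, list[str]] = {}
    st_of_sample: dict[str, int] = {}
    for p in profiles:
        st = st_of_vector.setdefault(p.alleles, len(st_of_vector) + 1)
        members.setdefault(st, []).append(p.sample_id)
        st_of_sample[p.sample_id] = st
    return StRegistry(
        combination=profiles[0].combination,
        st_of_vector=st_of_vector,
        members={k: tuple(v) for k, v in members.items()},
        st_of_sample=st_of_sample,
    )


def resolution_percent(n_sts: int, n_samples: int) -> float:
    """Typing resolution: 100 x STs / samples, one decimal."""
    if n_samples <= 0:
        raise UsageError("n_samples must be positive")
    return round_half_up(100.0 * n_sts / n_samples, 1)


def evaluate_combinations(
    contigs_by_locus: Mapping[str, Mapping[str, LocusContig]],
    references: Mapping[str, str],
    combinations: Sequence[Sequence[str]],
    headline: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Discriminatory power per locus combination: SNP and ST counts.

    Returns a table with columns combination, n_regions, n_snps, n_sts,
    n_samples, complete (False when samples were dropped for a missing
    locus), and resolution_pct for the headline combination (default:
    the last one)."""
    all_samples = set()
    for per in contigs_by_locus.values():
        all_samples |= set(per)
    headline = tuple(headline) if headline is not None else tuple(combinations[-1])
    rows = []
    for combo in combinations:
        combo = tuple(combo)
        profiles, columns = build_profiles(contigs_by_locus, references, combo)
        registry = assign_sts(profiles) if profiles else None
        n_sts = registry.n_sts if registry else 0
        row = {
            "combination": " + ".join(combo),
            "n_regions": len(combo),
            "n_snps": len(columns),
            "n_sts": n_sts,
            "n_samples": len(profiles),
            "complete": len(profiles) == len(all_samples),
            "resolution_pct": (
                resolution_percent(n_sts, len(profiles))
                if combo == headline and profiles
                else np.nan
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def pearson_snp_st(report: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-tailed p, via the t transform with n-2 df)
    between SNP counts and ST counts across combinations."""
    if len(report) < 3:
        raise UsageError("need at least 3 combinations for a correlation")
    x = report["n_snps"].to_numpy(dtype=float)
    y = report["n_sts"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UsageError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def diagnostic_sites(
    profiles: Sequence[SnpProfile],
    columns: Sequence[SnpColumn],
    species_labels: Mapping[str, str],
) -> dict[str, list[SnpColumn]]:
    """Species-diagnostic SNP columns.

    A column is diagnostic for a one-vs-rest partition when the allele
    sets of the two sides are disjoint; it separates all species when
    the per-species allele sets are pairwise disjoint.  Keys: one per
    species ("<sp>_vs_rest") plus "all_species".
    """
    species = sorted(set(species_labels.values()))
    if len(species) < 2:
        raise UsageError("need at least two species")
    by_species_alleles: list[dict[str, set[str]]] = []
    for j, _col in enumerate(columns):
        d: dict[str, set[str]] = {sp: set() for sp in species}
        for p in profiles:
            d[species_labels[p.sample_id]].add(p.alleles[j])
        by_species_alleles.append(d)

    out: dict[str, list[SnpColumn]] = {f"{sp}_vs_rest": [] for sp in species}
    out["all_species"] = []
    for col, d in zip(columns, by_species_alleles):
        sets = [d[sp] for sp in species]
        for sp in species:
            rest = set().union(*(d[o] for o in species if o != sp))
            if d[sp] and rest and d[sp].isdisjoint(rest):
                out[f"{sp}_vs_rest"].append(col)
        if all(s for s in sets) and all(
            sets[i].isdisjoint(sets[j]) for i in range(len(sets)) for j in range(i + 1, len(sets))
        ):
            out["all_species"].append(col)
    return out


def profile_table(profiles: Sequence[SnpProfile], columns: Sequence[SnpColumn]) -> pd.DataFrame:
    """Samples x SNP-columns allele table (columns named
    `<locus>:<position>`)."""
    colnames = [f"{c.locus_id}:{c.position_1based}" for c in columns]
    data = {p.sample_id: list(p.alleles) for p in profiles}
    return pd.DataFrame.from_dict(data, orient="index", columns=colnames)
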