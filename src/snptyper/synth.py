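"""Synthetic three-species barcode panel generator.

Emulates the statistical structure of a landrace identification panel:
three congeneric species (labelled A, B, C), several barcode loci with
planted substitution SNPs, heterozygous sites visible as chromatogram
secondary peaks, and a locus whose mononucleotide repeat interrupts
Sanger sequencing.

Panel structure
---------------
Planted SNP columns are partitioned into roles:

* roughly half are fixed differences diagnostic for species C (the
  distant congener), up to five of which additionally carry a third
  allele in species B (so those columns separate all three species);
* the remaining columns are within-species variation, split between A
  and C in proportion to their sample counts.  Each species keeps a
  founder block of samples identical at the species' core profile; the
  other samples are single-SNP variants of the founder (one variant per
  variation column), which makes the founder the hub of the minimum
  spanning tree and yields two multi-ST groups under a <=2-SNP rule.

Species B is a near neighbour of A (it differs only at the three-allele
columns), mirroring a variety-level relationship; species C is distant.

Every generated object is a deterministic function of (configuration,
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from ._seq import PURE_BASES, het_code
from .errors import ConfigError
from .traceqc import QualityRead

Species = Literal["A", "B", "C"]


@dataclass(frozen=True)
class LocusSpec:
    """One barcode locus: name, length and optional sequencing-failure
    mode (a mononucleotide run that interrupts reads)."""

    locus_id: str
    length: int
    failure_mode: Literal["none", "mononucleotide_repeat"] = "none"
    repeat_run_length: int = 0
    repeat_start_1based: int = 120  # run placed near the 5' end

    def __post_init__(self):
        if not 300 <= self.length <= 1200:
            raise ConfigError(f"{self.locus_id}: length {self.length} outside [300, 1200]")
        if self.failure_mode == "mononucleotide_repeat":
            if self.repeat_run_length < 8:
                raise ConfigError(f"{self.locus_id}: repeat_run_length must be >= 8")
            if self.repeat_start_1based + self.repeat_run_length > self.length:
                raise ConfigError(f"{self.locus_id}: repeat run exceeds locus length")


@dataclass(frozen=True)
class TraceModel:
    """Parameters of the simulated chromatogram quality profile.

    QV profile: flat at `peak_qv` until `qv_decay_start`, then linear
    decay at `qv_decay_slope` per base, plus Gaussian noise of sd
    `qv_noise_sd`, clipped to [0, 60].  Heterozygous positions carry a
    secondary-peak fraction of `het_secondary_fraction` on both strands;
    homozygous positions carry |N(0, hom_secondary_noise)|.  On loci
    with a repeat failure mode, a read collapses (QV ~ `collapse_qv`)
    downstream of the run with probability `failure_fraction`.
    """

    peak_qv: int = 55
    qv_decay_start: int = 500
    qv_decay_slope: float = 0.05
    qv_noise_sd: float = 0.0
    het_secondary_fraction: float = 0.6
    hom_secondary_noise: float = 0.02
    error_rate: float = 0.0
    failure_fraction: float = 0.655
    collapse_qv: int = 8

    def __post_init__(self):
        if not 0 < self.het_secondary_fraction <= 1:
            raise ConfigError("het_secondary_fraction must lie in (0, 1]")
        if not 0 <= self.peak_qv <= 60:
            raise ConfigError("peak_qv must lie in [0, 60]")


@dataclass(frozen=True)
class PlantedSnp:
    locus_id: str
    position_1based: int
    ref_base: str
    alt_base: str  # may be an IUPAC code for a planted heterozygote
    carriers: frozenset[str]


@dataclass(frozen=True)
class PlantedHet:
    sample_id: str
    locus_id: str
    position_1based: int
    alleles: tuple[str, str]


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth of a generated panel."""

    locus_specs: tuple[LocusSpec, ...]
    references: Mapping[str, str]
    sample_genotypes: Mapping[str, Mapping[str, str]]
    species_labels: Mapping[str, Species]
    planted_snps: tuple[PlantedSnp, ...]
    planted_het_sites: tuple[PlantedHet, ...]
    reference_sample: str
    founders: Mapping[Species, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.sample_genotypes)

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(s.locus_id for s in self.locus_specs)

    def snp_columns(self, locus_id: str) -> tuple[int, ...]:
        """Distinct planted SNP positions of one locus, ascending."""
        return tuple(
            sorted({s.position_1based for s in self.planted_snps if s.locus_id == locus_id})
        )

    def n_snp_columns(self, loci: Sequence[str] | None = None) -> int:
        loci = tuple(loci) if loci is not None else self.locus_ids
        return sum(len(self.snp_columns(l)) for l in loci)

    def true_profile(self, sample_id: str, loci: Sequence[str] | None = None) -> tuple[str, ...]:
        """Planted allele vector of a sample over the SNP columns of
        `loci` (locus order, position ascending)."""
        loci = tuple(loci) if loci is not None else self.locus_ids
        out = []
        for locus in loci:
            g = self.sample_genotypes[sample_id][locus]
            out.extend(g[p - 1] for p in self.snp_columns(locus))
        return tuple(out)

    def true_partition(self, loci: Sequence[str] | None = None) -> dict[tuple[str, ...], tuple[str, ...]]:
        """Map planted profile -> samples sharing it."""
        groups: dict[tuple[str, ...], list[str]] = {}
        for s in self.sample_ids:
            groups.setdefault(self.true_profile(s, loci), []).append(s)
        return {k: tuple(v) for k, v in groups.items()}


def default_locus_specs() -> tuple[LocusSpec, ...]:
    """Five barcode loci with the trimmed-alignment lengths of the study
    system: ITS, LSU D1-D3, rbcL, matK, and a trnH-psbA-like locus whose
    mononucleotide run interrupts sequencing."""
    return (
        LocusSpec("ITS", 660),
        LocusSpec("LSU_D1-D3", 714),
        LocusSpec("rbcL", 568),
        LocusSpec("matK", 818),
        LocusSpec("trnH-psbA", 715, failure_mode="mononucleotide_repeat", repeat_run_length=12),
    )


def default_snp_counts() -> dict[str, int]:
    """Planted substitution SNP columns per locus (35 across the four
    informative loci; the failing plastid spacer contributes none)."""
    return {"ITS": 19, "LSU_D1-D3": 11, "rbcL": 4, "matK": 1, "trnH-psbA": 0}


DEFAULT_SAMPLES_PER_SPECIES = (21, 2, 6)
_MAX_THREE_ALLELE = 5  # columns where species B carries a third allele


def _sample_ids(n_per_species: Sequence[int]) -> dict[str, Species]:
    prefixes = {"A": "AV", "B": "AX", "C": "AL"}
    labels: dict[str, Species] = {}
    for species, n in zip("ABC", n_per_species):
        for i in range(n):
            labels[f"{prefixes[species]}{i + 1:02d}"] = species  # type: ignore[assignment]
    return labels


def make_panel(
    n_samples_per_species: Sequence[int] = DEFAULT_SAMPLES_PER_SPECIES,
    locus_specs: Sequence[LocusSpec] | None = None,
    n_snps_per_locus: Mapping[str, int] | None = None,
    seed: int = 0,
) -> PanelTruth:
    """Generate a deterministic three-species panel with planted SNPs.

    The first species-A sample whose profile equals the reference (AV03
    when present in the founder block, else the first founder) plays the
    role of the designated reference individual.
    """
    specs = tuple(locus_specs) if locus_specs is not None else default_locus_specs()
    n_snps = dict(n_snps_per_locus) if n_snps_per_locus is not None else default_snp_counts()
    for spec in specs:
        k = n_snps.get(spec.locus_id, 0)
        if k >= spec.length:
            raise ConfigError(f"{spec.locus_id}: {k} SNPs requested for {spec.length} bp")
    nA, nB, nC = (list(n_samples_per_species) + [0, 0, 0])[:3]
    if nA < 1:
        raise ConfigError("species A needs at least one sample (it hosts the reference)")

    rng = np.random.default_rng(seed)
    bases = np.array(list(PURE_BASES))

    # references: i.i.d. uniform composition, repeat runs overwritten
    references: dict[str, str] = {}
    for spec in specs:
        seq = rng.choice(bases, size=spec.length)
        if spec.failure_mode == "mononucleotide_repeat":
            lo = spec.repeat_start_1based - 1
            seq[lo : lo + spec.repeat_run_length] = "A"
        references[spec.locus_id] = "".join(seq)

    # SNP positions per locus (outside any repeat run)
    columns: list[tuple[str, int]] = []
    for spec in specs:
        k = n_snps.get(spec.locus_id, 0)
        allowed = np.arange(1, spec.length + 1)
        if spec.failure_mode == "mononucleotide_repeat":
            lo, hi = spec.repeat_start_1based, spec.repeat_start_1based + spec.repeat_run_length
            allowed = allowed[(allowed < lo) | (allowed >= hi)]
        if k > len(allowed):
            raise ConfigError(f"{spec.locus_id}: {k} SNPs exceed available positions")
        pos = np.sort(rng.choice(allowed, size=k, replace=False))
        columns.extend((spec.locus_id, int(p)) for p in pos)

    n_total = len(columns)
    order = rng.permutation(n_total)

    # role allocation
    n_diag_c = int(round(n_total * 0.5)) if (nC > 0 and n_total > 0) else 0
    n_diag_c = max(n_diag_c, 1) if (nC > 0 and n_total > 0) else 0
    n_all3 = min(_MAX_THREE_ALLELE, n_diag_c) if nB > 0 else 0
    n_var = n_total - n_diag_c
    wA, wC = max(nA - 1, 0), max(nC - 1, 0)
    if n_var > 0 and wA + wC == 0:
        raise ConfigError("variation columns requested but no species has >=2 samples")
    n_var_a = n_var * wA // (wA + wC) if n_var else 0
    if wC == 0:
        n_var_a = n_var
    n_var_c = n_var - n_var_a

    diag_c_idx = [order[i] for i in range(n_diag_c)]
    all3_idx = set(diag_c_idx[:n_all3])
    var_a_idx = [order[i] for i in range(n_diag_c, n_diag_c + n_var_a)]
    var_c_idx = [order[i] for i in range(n_diag_c + n_var_a, n_total)]

    def _alt(ref: str, forbid: set[str]) -> str:
        choices = [b for b in PURE_BASES if b != ref and b not in forbid]
        return str(rng.choice(choices))

    labels = _sample_ids((nA, nB, nC))
    by_species = {sp: [s for s, l in labels.items() if l == sp] for sp in "ABC"}
    genotypes = {
        s: {spec.locus_id: list(references[spec.locus_id]) for spec in specs} for s in labels
    }

    planted: list[PlantedSnp] = []
    het_sites: list[PlantedHet] = []

    def plant(col: tuple[str, int], allele: str, carriers: Sequence[str], ref: str):
        locus, pos = col
        for s in carriers:
            genotypes[s][locus][pos - 1] = allele
        planted.append(PlantedSnp(locus, pos, ref, allele, frozenset(carriers)))

    for i in diag_c_idx:
        locus, pos = columns[i]
        ref = references[locus][pos - 1]
        alt_c = _alt(ref, set())
        plant(columns[i], alt_c, by_species["C"], ref)
        if i in all3_idx and nB > 0:
            alt_b = _alt(ref, {alt_c})
            plant(columns[i], alt_b, by_species["B"], ref)

    def plant_variation(var_idx: list[int], members: list[str], species: Species):
        """Founder block + one single-SNP variant per variation column.
        Every third variant is heterozygous (ref/alt IUPAC code)."""
        if not var_idx:
            return
        n = len(members)
        n_founder = max(1, n - len(var_idx))
        variants = members[n_founder:]
        for j, sample in enumerate(variants):
            cols = [var_idx[j]]
            if sample == variants[-1]:  # last variant absorbs leftover columns
                cols.extend(var_idx[len(variants):])
            for ci in cols:
                locus, pos = columns[ci]
                ref = genotypes[sample][locus][pos - 1]
                alt = _alt(ref, set())
                if j % 3 == 2:
                    code = het_code(ref, alt)
                    plant(columns[ci], code, [sample], ref)
                    het_sites.append(
                        PlantedHet(sample, locus, pos, tuple(sorted((ref, alt))))  # type: ignore[arg-type]
                    )
                else:
                    plant(columns[ci], alt, [sample], ref)

    plant_variation(var_a_idx, by_species["A"], "A")
    plant_variation(var_c_idx, by_species["C"], "C")

    founders = {
        sp: by_species[sp][0] for sp in "ABC" if by_species[sp]
    }
    ref_sample = "AV03" if "AV03" in by_species["A"][: max(1, nA - n_var_a)] else by_species["A"][0]

    return PanelTruth(
        locus_specs=specs,
        references=references,
        sample_genotypes={s: {l: "".join(g) for l, g in d.items()} for s, d in genotypes.items()},
        species_labels=labels,
        planted_snps=tuple(planted),
        planted_het_sites=tuple(het_sites),
        reference_sample=ref_sample,
        founders=founders,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# read simulation


def _read_template(genotype: str, direction: str) -> str:
    from ._seq import reverse_complement

    return genotype if direction == "forward" else reverse_complement(genotype)


def simulate_reads(
    truth: PanelTruth,
    model: TraceModel | None = None,
    seed: int = 0,
    n_individuals: int = 2,
) -> list[QualityRead]:
    """Simulate bidirectional reads for every sample x locus x individual.

    Reads span the whole locus.  At a heterozygous genotype position the
    two strands basecall the two different alleles as their primary peak
    (forward: alphabetically first; reverse: the other, complemented in
    read orientation), each with the model's secondary-peak fraction, so
    the allele pair is recoverable by bidirectional confirmation.  On
    failure-mode loci an affected read's QV collapses over reference
    positions downstream of the repeat run, mapped into the read's own
    orientation.
    """
    from ._seq import HET_ALLELES, reverse_complement

    model = model or TraceModel()
    rng = np.random.default_rng(seed)
    reads: list[QualityRead] = []
    spec_by_id = {s.locus_id: s for s in truth.locus_specs}

    for sample in truth.sample_ids:
        for locus in truth.locus_ids:
            spec = spec_by_id[locus]
            genotype = truth.sample_genotypes[sample][locus]
            length = len(genotype)

            # genotype-orientation primary base per strand + secondary fraction
            primary_f, primary_r = [], []
            sec = np.abs(rng.normal(0.0, model.hom_secondary_noise, size=length))
            sec = np.clip(sec, 0.0, 1.0)
            for i, b in enumerate(genotype):
                if b in HET_ALLELES:
                    pair = sorted(HET_ALLELES[b])
                    primary_f.append(pair[0])
                    primary_r.append(pair[1])
                    sec[i] = model.het_secondary_fraction
                else:
                    primary_f.append(b)
                    primary_r.append(b)
            fwd_template = "".join(primary_f)
            rev_template = reverse_complement("".join(primary_r))

            for ind in range(1, n_individuals + 1):
                for direction in ("forward", "reverse"):
                    if direction == "forward":
                        read_bases = list(fwd_template)
                        read_sec = sec.copy()
                    else:
                        read_bases = list(rev_template)
                        read_sec = sec[::-1].copy()

                    # sequencing errors
                    if model.error_rate > 0:
                        errs = np.nonzero(rng.random(length) < model.error_rate)[0]
                        for i in errs:
                            read_bases[i] = _alt_base(rng, read_bases[i])

                    # quality profile
                    idx = np.arange(1, length + 1)
                    qv = model.peak_qv - model.qv_decay_slope * np.maximum(
                        0, idx - model.qv_decay_start
                    )
                    if model.qv_noise_sd > 0:
                        qv = qv + rng.normal(0.0, model.qv_noise_sd, size=length)

                    # repeat-run collapse
                    if (
                        spec.failure_mode == "mononucleotide_repeat"
                        and rng.random() < model.failure_fraction
                    ):
                        run_end = spec.repeat_start_1based + spec.repeat_run_length - 1
                        if direction == "forward":
                            bad = idx > run_end  # read coords == reference coords
                        else:
                            # read index i covers reference position length-i+1
                            bad = idx <= (length - run_end)
                        qv = np.where(
                            bad, model.collapse_qv + rng.normal(0, 2.0, size=length), qv
                        )
                        scramble = bad & (rng.random(length) < 0.5)
                        for i in np.nonzero(scramble)[0]:
                            read_bases[i] = str(rng.choice(list(PURE_BASES)))

                    qv = np.clip(np.rint(qv), 0, 60).astype(int)
                    tag = "F" if direction == "forward" else "R"
                    reads.append(
                        QualityRead(
                            read_id=f"{sample}.{locus}.i{ind}.{tag}",
                            sample_id=sample,
                            locus_id=locus,
                            direction=direction,  # type: ignore[arg-type]
                            bases="".join(read_bases),
                            qv=tuple(int(q) for q in qv),
                            secondary_fraction=tuple(float(x) for x in read_sec),
                        )
                    )
    return reads


def _alt_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in PURE_BASES if b != base]
    return str(rng.choice(choices))


# ---------------------------------------------------------------------------
# file output


def write_panel(truth: PanelTruth, outdir: str | Path) -> None:
    """Write per-locus genotype-truth FASTA plus the references."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus in truth.locus_ids:
        records = [
            SeqRecord(Seq(truth.references[locus]), id=f"REF.{locus}", description="reference")
        ]
        for sample in truth.sample_ids:
            records.append(
                SeqRecord(
                    Seq(truth.sample_genotypes[sample][locus]),
                    id=f"{sample}.{locus}",
                    description=f"species={truth.species_labels[sample]}",
                )
            )
        seqio_write(records, outdir / f"{locus}.truth.fasta", "fasta")


def write_reads(reads: Sequence[QualityRead], outdir: str | Path) -> None:
    """One FASTQ file per read plus a `<read_id>.sec.tsv` sidecar with
    per-position secondary-peak fractions (FASTQ has no channel for
    them)."""
    from .io import write_read_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for read in reads:
        write_read_fastq(read, outdir)
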