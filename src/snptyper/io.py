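"""File formats: FASTQ + secondary-peak sidecar, FASTA, flat config.

FASTQ carries bases and QVs; the per-read tab-separated sidecar
``<read_id>.sec.tsv`` (columns: position_1based, secondary_fraction)
carries the chromatogram secondary-peak fractions that FASTQ cannot.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError
from .traceqc import QualityRead


def write_read_fastq(read: QualityRead, outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    rec = SeqRecord(
        Seq(read.bases),
        id=read.read_id,
        description=f"sample={read.sample_id} locus={read.locus_id} direction={read.direction}",
    )
    rec.letter_annotations["phred_quality"] = list(read.qv)
    fq = outdir / f"{read.read_id}.fastq"
    SeqIO.write([rec], fq, "fastq")
    sidecar = outdir / f"{read.read_id}.sec.tsv"
    with open(sidecar, "w") as fh:
        fh.write("position_1based\tsecondary_fraction\n")
        for i, frac in enumerate(read.secondary_fraction, start=1):
            fh.write(f"{i}\t{frac:.4f}\n")
    return fq, sidecar


def _parse_description(desc: str) -> dict[str, str]:
    fields = {}
    for token in desc.split():
        if "=" in token:
            k, v = token.split("=", 1)
            fields[k] = v
    return fields


def read_read_fastq(fastq_path: str | Path) -> QualityRead:
    """Load one read from a FASTQ file and its adjacent sidecar; a
    missing sidecar yields all-zero secondary fractions."""
    fastq_path = Path(fastq_path)
    rec = next(SeqIO.parse(fastq_path, "fastq"))
    qv = tuple(int(q) for q in rec.letter_annotations["phred_quality"])
    n = len(rec.seq)
    sec = [0.0] * n
    sidecar = fastq_path.with_name(f"{rec.id}.sec.tsv")
    if sidecar.exists():
        with open(sidecar) as fh:
            next(fh)
            for line in fh:
                pos_s, frac_s = line.split("\t")
                sec[int(pos_s) - 1] = float(frac_s)
    meta = _parse_description(rec.description)
    parts = rec.id.split(".")
    return QualityRead(
        read_id=rec.id,
        sample_id=meta.get("sample", parts[0]),
        locus_id=meta.get("locus", parts[1] if len(parts) > 1 else ""),
        direction=meta.get("direction", "forward"),  # type: ignore[arg-type]
        bases=str(rec.seq).upper(),
        qv=qv,
        secondary_fraction=tuple(sec),
    )


def iter_reads(directory: str | Path) -> Iterator[QualityRead]:
    for fq in sorted(Path(directory).glob("*.fastq")):
        yield read_read_fastq(fq)


def write_consensus_fasta(contigs, path: str | Path) -> None:
    """Per-sample-x-locus consensus FASTA; the description line carries
    `het_positions=` as a comma list."""
    records = []
    for c in contigs:
        het = ",".join(str(p) for p in c.het_positions) or "-"
        records.append(
            SeqRecord(
                Seq(c.consensus),
                id=f"{c.sample_id}.{c.locus_id}",
                description=f"het_positions={het}",
            )
        )
    SeqIO.write(records, path, "fasta")


def read_locus_fasta(path: str | Path) -> dict[str, str]:
    """FASTA of one locus -> {record id: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def parse_flat_config(path: str | Path) -> dict[str, str]:
    """Flat key-value config: one `key = value` (or `key value`) per
    line; `#` starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, value = line.split("=", 1)
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ConfigError(f"{path}:{lineno}: cannot parse {raw!r}")
            key, value = parts
        out[key.strip()] = value.strip()
    return out
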