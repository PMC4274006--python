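"""End-to-end orchestration: synth -> qc -> assemble -> type -> trees/mst.

A single master seed deterministically derives one seed per stage (CRC32
of the stage name XOR the master seed), so any stage can be re-run in
isolation and two runs with the same config produce byte-identical
artifacts.  All tabular artifacts are TSV with a header; floats are
printed to 4 decimals, percentages to 1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import assemble as asm
from . import genotyping as gt
from . import mst as mstmod
from . import phylo
from . import synth
from . import traceqc as qc
from .errors import StageError

log = logging.getLogger("snptyper")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; QC/assembly/typing thresholds default to
    the study's printed values."""

    seed: int = 0
    n_samples_per_species: tuple[int, int, int] = synth.DEFAULT_SAMPLES_PER_SPECIES
    locus_specs: tuple[synth.LocusSpec, ...] = field(default_factory=synth.default_locus_specs)
    n_snps_per_locus: Mapping[str, int] = field(default_factory=synth.default_snp_counts)
    trace_model: synth.TraceModel = field(default_factory=synth.TraceModel)
    n_individuals: int = 2
    # QC
    ts_min: float = 35.0
    crl_min: int = 200
    trim_window: int = 25
    trim_qv: int = 25
    trim_max_bad: int = 3
    # assembly
    min_overlap_frac: float = 0.80
    min_match: float = 0.98
    het_threshold: float = 0.40
    # typing
    combinations: tuple[tuple[str, ...], ...] | None = None
    # trees
    bootstrap_reps: int = 100
    anneal: phylo.AnnealSchedule = field(default_factory=phylo.AnnealSchedule)
    bootstrap_anneal: phylo.AnnealSchedule = field(
        default_factory=lambda: phylo.AnnealSchedule(t0=1.0, cooling=0.9, proposals_per_temp=20)
    )
    # MST
    priority_weights: Mapping[int, int] = field(
        default_factory=lambda: dict(mstmod.DEFAULT_PRIORITY_WEIGHTS)
    )
    max_group_diff: int = 2
    min_group_size: int = 2


def stage_seed(master: int, stage: str) -> int:
    return (int(master) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class RunResult:
    config: RunConfig
    truth: synth.PanelTruth
    reads: list
    metrics: list
    contigs_by_locus: dict[str, dict[str, asm.LocusContig]]
    references: dict[str, str]
    typed_loci: tuple[str, ...]
    combination_report: pd.DataFrame
    pearson: tuple[float, float]
    profiles: list[gt.SnpProfile]
    columns: list[gt.SnpColumn]
    registry: gt.StRegistry
    upgma: phylo.Dendrogram
    mp: phylo.ParsimonyResult
    support: dict
    mst: mstmod.MstGraph
    outdir: Path | None = None
    manifest: dict | None = None


def default_combinations(informative: Sequence[str]) -> tuple[tuple[str, ...], ...]:
    """Singles, consecutive pairs of nuclear/plastid blocks and the
    headline concatenation over the typable loci."""
    informative = tuple(informative)
    combos: list[tuple[str, ...]] = [(l,) for l in informative]
    if len(informative) >= 2:
        combos.append(informative[:2])
        if len(informative) >= 4:
            combos.append(informative[2:4])
            combos.append((informative[0],) + informative[2:4])
            combos.append((informative[1],) + informative[2:4])
    combos.append(informative)
    # dedupe, keep order
    seen, out = set(), []
    for c in combos:
        if c not in seen and len(c) >= 1:
            seen.add(c)
            out.append(c)
    return tuple(out)


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Run the full pipeline; write artifacts when `outdir` is given."""
    written: list[Path] = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _write_tsv(name: str, df: pd.DataFrame):
        if out is None:
            return
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")
        written.append(path)

    def _write_text(name: str, text: str):
        if out is None:
            return
        path = out / name
        path.write_text(text)
        written.append(path)

    def _cleanup():
        for p in written:
            p.unlink(missing_ok=True)

    try:
        stage = "synth"
        log.info("[%s] generating panel", stage)
        truth = synth.make_panel(
            config.n_samples_per_species,
            config.locus_specs,
            config.n_snps_per_locus,
            seed=stage_seed(config.seed, "synth"),
        )
        reads = synth.simulate_reads(
            truth,
            config.trace_model,
            seed=stage_seed(config.seed, "reads"),
            n_individuals=config.n_individuals,
        )

        stage = "qc"
        log.info("[%s] scoring %d traces", stage, len(reads))
        metrics = [
            qc.trace_metrics(
                r, config.trim_window, config.trim_qv, config.trim_max_bad
            )
            for r in reads
        ]
        passing_ids = {
            m.read_id
            for m in metrics
            if m.trace_score >= config.ts_min and m.crl >= config.crl_min
        }
        _write_tsv("qc_report.tsv", qc.qc_report(metrics))

        stage = "assemble"
        by_pair: dict[tuple[str, str, int], dict[str, qc.QualityRead]] = {}
        for r in reads:
            ind = int(r.read_id.split(".i")[1].split(".")[0])
            by_pair.setdefault((r.sample_id, r.locus_id, ind), {})[r.direction] = r
        contigs_by_locus: dict[str, dict[str, asm.LocusContig]] = {
            l: {} for l in truth.locus_ids
        }
        log_rows = []
        per_sample_locus: dict[tuple[str, str], list[asm.LocusContig]] = {}
        for (sample, locus, ind), pair in sorted(by_pair.items()):
            fwd, rev = pair.get("forward"), pair.get("reverse")
            if fwd is None or rev is None:
                continue
            if fwd.read_id not in passing_ids or rev.read_id not in passing_ids:
                continue
            result = asm.assemble_pair(
                qc.trim_read(fwd, config.trim_window, config.trim_qv, config.trim_max_bad),
                qc.trim_read(rev, config.trim_window, config.trim_qv, config.trim_max_bad),
                config.min_overlap_frac,
                config.min_match,
                config.het_threshold,
            )
            log_rows.append(
                {
                    "sample": sample,
                    "locus": locus,
                    "individual": ind,
                    "offset": result.offset,
                    "overlap_len": result.overlap_len,
                    "pct_match": result.pct_match,
                    "accepted": result.accepted,
                    "reason": result.reason,
                }
            )
            if result.accepted:
                per_sample_locus.setdefault((sample, locus), []).append(result.contig)
        recovery_rows = []
        flagged = []
        for (sample, locus), contigs in sorted(per_sample_locus.items()):
            contig, disagreements = asm.reconcile_individuals(contigs)
            if disagreements:
                flagged.append((sample, locus, disagreements))
            contigs_by_locus[locus][sample] = contig
        n_samples = len(truth.sample_ids)
        for locus in truth.locus_ids:
            recovery_rows.append(
                {
                    "region": locus,
                    "n_recovered": len(contigs_by_locus[locus]),
                    "pct_recovery": qc.round_half_up(
                        100.0 * len(contigs_by_locus[locus]) / n_samples, 1
                    ),
                }
            )
        _write_tsv("assembly_log.tsv", pd.DataFrame(log_rows))
        _write_tsv("barcode_recovery.tsv", pd.DataFrame(recovery_rows))

        stage = "type"
        ref_sample = truth.reference_sample
        typed_loci = tuple(
            l for l in truth.locus_ids if ref_sample in contigs_by_locus[l]
            and len(contigs_by_locus[l]) == n_samples
        )
        log.info("[%s] typable loci: %s", stage, ", ".join(typed_loci))
        references = {
            l: contigs_by_locus[l][ref_sample].consensus for l in typed_loci
        }
        combos = config.combinations or default_combinations(typed_loci)
        combos = tuple(tuple(c) for c in combos if all(l in typed_loci for l in c))
        report = gt.evaluate_combinations(
            {l: contigs_by_locus[l] for l in typed_loci}, references, combos
        )
        pearson = gt.pearson_snp_st(report)
        headline = combos[-1]
        profiles, columns = gt.build_profiles(
            {l: contigs_by_locus[l] for l in typed_loci}, references, headline
        )
        registry = gt.assign_sts(profiles)
        _write_tsv("combination_report.tsv", report)
        _write_tsv(
            "st_assignments.tsv",
            pd.DataFrame(
                [(p.sample_id, registry.st_of_sample[p.sample_id]) for p in profiles],
                columns=["sample", "st"],
            ),
        )
        prof_table = gt.profile_table(profiles, columns)
        if out is not None:
            path = out / "snp_profiles.tsv"
            prof_table.to_csv(path, sep="\t", index_label="sample")
            written.append(path)
        diag = gt.diagnostic_sites(profiles, columns, truth.species_labels)
        _write_tsv(
            "diagnostic_sites.tsv",
            pd.DataFrame(
                [
                    {"partition": k, "locus": c.locus_id, "position": c.position_1based}
                    for k, cols in diag.items()
                    for c in cols
                ]
            ),
        )

        stage = "tree"
        D_samples = phylo.distance_matrix(profiles)
        dendro = phylo.upgma(D_samples)
        st_profiles = {
            f"ST{st}": vec for vec, st in registry.st_of_vector.items()
        }
        matrix = phylo.CharacterMatrix.from_profiles(st_profiles)
        mp = phylo.mp_search(
            matrix, "anneal", seed=stage_seed(config.seed, "mp"), schedule=config.anneal
        )
        support = phylo.bootstrap(
            matrix,
            n_reps=config.bootstrap_reps,
            seed=stage_seed(config.seed, "bootstrap"),
            schedule=config.bootstrap_anneal,
            reference=mp,
        )
        mp_newick = phylo.root_by_deepest_branch(mp.adj, matrix, support=support)
        _write_text("upgma.nwk", dendro.newick() + "\n")
        _write_text("mp.nwk", mp_newick + "\n")
        _write_tsv(
            "tree_stats.tsv",
            pd.DataFrame(
                [
                    {
                        "cophenetic_r": round(dendro.cophenetic_r, 4),
                        "mp_score": mp.score,
                        "pearson_r": round(pearson[0], 4),
                        "pearson_p": pearson[1],
                        "n_sts": registry.n_sts,
                        "resolution_pct": gt.resolution_percent(registry.n_sts, len(profiles)),
                    }
                ]
            ),
        )

        stage = "mst"
        nodes = mstmod.collapse_identical(profiles, registry)
        graph = mstmod.build_mst(nodes, priority_weights=dict(config.priority_weights))
        groups = mstmod.find_groups(graph, config.max_group_diff, config.min_group_size)
        ranking = mstmod.founder_candidates(graph)
        graph = mstmod.MstGraph(graph.nodes, graph.edges, groups, ranking)
        group_of = {st: gi + 1 for gi, g in enumerate(groups) for st in g}
        _write_tsv(
            "mst_edges.tsv",
            pd.DataFrame([(e.u, e.v, e.weight) for e in graph.edges], columns=["u", "v", "weight"]),
        )
        _write_tsv(
            "mst_nodes.tsv",
            pd.DataFrame(
                [
                    {
                        "st_id": n.st_id,
                        "size": n.size,
                        "members": ",".join(n.members),
                        "group_id": group_of.get(n.st_id, 0),
                        "founder_rank": ranking.index(n.st_id) + 1,
                    }
                    for n in graph.nodes
                ]
            ),
        )
        _write_text("mst.dot", _dot(graph, group_of) + "\n")

        manifest = None
        if out is not None:
            manifest = {
                "seed": config.seed,
                "config": _config_dict(config),
                "artifacts": {
                    p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(written)
                },
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

        return RunResult(
            config=config,
            truth=truth,
            reads=reads,
            metrics=metrics,
            contigs_by_locus=contigs_by_locus,
            references=references,
            typed_loci=typed_loci,
            combination_report=report,
            pearson=pearson,
            profiles=profiles,
            columns=columns,
            registry=registry,
            upgma=dendro,
            mp=mp,
            support=support,
            mst=graph,
            outdir=out,
            manifest=manifest,
        )
    except Exception as exc:  # noqa: BLE001 - single halt point with cleanup
        _cleanup()
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def _dot(graph: mstmod.MstGraph, group_of: Mapping[int, int]) -> str:
    lines = ["graph mst {"]
    for n in graph.nodes:
        shade = "lightgrey" if group_of.get(n.st_id) else "white"
        lines.append(
            f'  ST{n.st_id} [label="ST{n.st_id}\\n(n={n.size})", style=filled, fillcolor={shade}];'
        )
    for e in graph.edges:
        style = "solid" if e.weight <= 2 else "dashed"
        lines.append(f'  ST{e.u} -- ST{e.v} [label="{e.weight}", style={style}];')
    lines.append("}")
    return "\n".join(lines)
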