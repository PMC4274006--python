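#!/usr/bin/env python
"""Simulate the three-species landrace panel and run trace QC.

Generates the default 29-sample panel (21 A. villosum-like, 2
A. xanthioides-like, 6 A. longiligulare-like samples; five barcode loci
with 35 planted SNPs) and 580 bidirectional reads, then scores every
trace (TS/CRL) and writes the per-region QC table.

Finding: the four informative loci sequence cleanly (100% pass under
TS>=35 and CRL>=200) while the mononucleotide-repeat locus fails in
roughly two thirds of traces, emulating a trnH-psbA-style dropout.
"""

import argparse
from pathlib import Path

from snptyper import pipeline, synth
from snptyper.traceqc import qc_report, success_rate, trace_metrics

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    truth = synth.make_panel(seed=pipeline.stage_seed(args.seed, "synth"))
    reads = synth.simulate_reads(
        truth, synth.TraceModel(), seed=pipeline.stage_seed(args.seed, "reads")
    )
    metrics = [trace_metrics(r) for r in reads]
    report = qc_report(metrics)
    RESULTS.mkdir(exist_ok=True)
    report.to_csv(RESULTS / "qc_report.tsv", sep="\t", index=False)

    print(f"panel: {len(truth.sample_ids)} samples, {truth.n_snp_columns()} planted SNP columns")
    print(f"traces scored: {len(metrics)}")
    for _, row in report.iterrows():
        print(
            f"  {row.region:>10}: {row.pct_pass:5.1f}% pass "
            f"(mean TS {row.mean_ts}, {row.n_pass}/{row.n_traces} traces)"
        )
    failing = [m for m in metrics if m.locus_id == "trnH-psbA"]
    print(f"repeat-failure locus success: {success_rate(failing)}% (study-like dropout)")
    print(f"wrote {RESULTS / 'qc_report.tsv'}")


if __name__ == "__main__":
    main()
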