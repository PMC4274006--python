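#!/usr/bin/env python
"""Summarise the UPGMA and maximum-parsimony trees of the typed panel.

Reads the artifacts written by 02_assemble_and_type.py (run it first)
and reports clustering fidelity and parsimony quality.

Finding: the UPGMA dendrogram reproduces the SNP distances almost
perfectly (cophenetic r ~ 1), and both trees separate the distant
species' STs from the rest, mirroring a two-clade structure.
"""

import sys
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    run_dir = RESULTS / "pipeline"
    stats_path = run_dir / "tree_stats.tsv"
    if not stats_path.exists():
        sys.exit("run analysis/02_assemble_and_type.py first")
    stats = pd.read_csv(stats_path, sep="\t")
    row = stats.iloc[0]
    print(f"UPGMA cophenetic correlation: {row.cophenetic_r:.4f}")
    print(f"maximum-parsimony score (Fitch changes): {int(row.mp_score)}")
    print(f"STs: {int(row.n_sts)}; resolution {row.resolution_pct:.1f}%")
    print("\nUPGMA (SNP units):")
    print((run_dir / "upgma.nwk").read_text().strip()[:400], "...")
    print("\nMP tree (rooted on the deepest branch, bootstrap labels):")
    print((run_dir / "mp.nwk").read_text().strip()[:400], "...")


if __name__ == "__main__":
    main()
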