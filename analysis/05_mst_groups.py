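#!/usr/bin/env python
"""Summarise the priority-rule minimum spanning tree and its groups.

Reads the MST node/edge tables written by 02_assemble_and_type.py (run
it first).

Finding: under the <=2-SNP grouping rule the STs fall into exactly two
groups — the large within-species radiation around the founder
genotype (the MST hub, carrying the most single-SNP neighbours and the
largest membership) and the distant species' cluster; the
near-neighbour species' ST stays ungrouped.
"""

import sys
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    run_dir = RESULTS / "pipeline"
    nodes_path = run_dir / "mst_nodes.tsv"
    if not nodes_path.exists():
        sys.exit("run analysis/02_assemble_and_type.py first")
    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(run_dir / "mst_edges.tsv", sep="\t")
    print(f"{len(nodes)} ST nodes, total MST weight {edges.weight.sum()}")
    for gid, group in nodes[nodes.group_id > 0].groupby("group_id"):
        print(f"group {gid}: {len(group)} STs -> {sorted(group.st_id)}")
    ungrouped = nodes[nodes.group_id == 0]
    print(f"ungrouped STs: {sorted(ungrouped.st_id)}")
    founder = nodes[nodes.founder_rank == 1].iloc[0]
    slv = edges[(edges.weight == 1) & ((edges.u == founder.st_id) | (edges.v == founder.st_id))]
    print(
        f"founder candidate: ST{founder.st_id} "
        f"({founder['size']} members, {len(slv)} single-SNP neighbours)"
    )


if __name__ == "__main__":
    main()
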