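"""Cluster the study's samples on their most variable cassette-exon PSI.

Reads the per-line tables from 01, pools all cassette events, keeps the most
variable ones, runs the gap statistic to choose the cluster count, then
partitions the fish with K-means at both the selected k and the two-center
analysis. Writes the gap curve and the assignments.
"""

import argparse
from pathlib import Path

import pandas as pd

from splicekit.cluster_analysis import (
    gap_statistic,
    kmeans_partition,
    top_variable_events,
)
from splicekit.io_formats import merge_event_tables, read_rmats_table

LINES = [f"line{i}" for i in range(7)]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/synthetic_study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--top", type=int, default=400)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    table = merge_event_tables(
        {
            line: read_rmats_table(args.study / f"SE.{line}.txt", "SE", genotype=line)
            for line in LINES
        }
    )
    matrix = top_variable_events(table, n=args.top)
    print(
        f"PSI matrix: {matrix.values.shape[0]} fish × "
        f"{matrix.values.shape[1]} most-variable cassette events"
    )

    curve, k_selected = gap_statistic(
        matrix, k_max=6, n_ref=30, seed=args.seed, n_init=5
    )
    curve.to_csv(args.out / "gap_curve.tsv", sep="\t", index=False)
    print(f"gap statistic selects k = {k_selected}")

    result = kmeans_partition(
        matrix, k=2, seed=args.seed, gap_curve=curve, k_selected=k_selected
    )
    assignments = pd.DataFrame(
        {
            "sample": matrix.samples,
            "genotype": [matrix.genotype_of[s] for s in matrix.samples],
            "cluster": [result.assignments[s] for s in matrix.samples],
        }
    )
    assignments.to_csv(args.out / "cluster_assignments.tsv", sep="\t", index=False)
    print("\ncluster composition (two centers):")
    print(
        assignments.groupby(["cluster", "genotype"]).size().unstack(fill_value=0)
        .to_string()
    )


if __name__ == "__main__":
    main()
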