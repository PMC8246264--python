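"""YGCY enrichment around regulated cassette exons, on planted sequences.

Builds a synthetic genome in which Mbnl-activated exons carry extra YGCY
motifs only in the downstream intron and Mbnl-repressed exons carry them
upstream and within the exon — the positional rule expected of direct MBNL
regulation — then computes the five-window enrichment heatmap against
non-regulated exons with composition-matched control 4-mers.
"""

import argparse
from pathlib import Path

from splicekit.motif_enrichment import (
    PRESETS,
    enrichment_heatmap,
    heatmap_frame,
)
from splicekit.synthetic_data import simulate_motif_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-per-class", type=int, default=200)
    parser.add_argument("--preset", choices=sorted(PRESETS), default="ygcy")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    motifs = PRESETS[args.preset]
    study = simulate_motif_study(
        n_per_class=args.n_per_class,
        density_activated={"intron_3prime_of_cassette": 4.0},
        density_repressed={"intron_5prime_of_cassette": 4.0, "cassette_exon": 4.0},
        density_nonregulated=0.0,
        seed=args.seed,
        motifs=motifs,
    )
    cells = enrichment_heatmap(
        study.regulated_sets,
        study.nonregulated,
        study.events_by_id,
        study.models,
        study.genome,
        motifs=motifs,
        cassette_index=study.cassette_index,
    )
    frame = heatmap_frame(cells)
    frame.to_csv(args.out / "motif_heatmap.tsv", sep="\t", index=False)
    print(f"motif preset: {motifs.name} = {sorted(motifs.motifs)}")
    print(f"{args.n_per_class} exons per regulation class\n")
    print(
        frame.pivot(index="region", columns="regulation_class", values="log2_ratio")
        .round(2)
        .to_string()
    )
    print(
        "\npositive cells should sit exactly where motifs were planted: "
        "downstream intron for activated exons; upstream intron and the exon "
        "body for repressed exons."
    )


if __name__ == "__main__":
    main()
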