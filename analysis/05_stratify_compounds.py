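"""Stratify ALT-elevating compounds by immune-cell trafficking.

Selects compounds with peak ALT >= 65 within 24 h, assembles the
16 trafficking features (Mon/Neu/CD4T/CD8T x 3/6/9/24 h control
z-scores), embeds them with six reduction methods, combines the
candidates by spectral meta-visualization, clusters the meta-distance
(average linkage, 4 clusters) and summarizes per-cluster time courses.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from immucast import io
from immucast.deconv import ScoreMatrix
from immucast.stratify import (
    assemble_trafficking_features,
    consensus_mds,
    embed_candidates,
    filter_compounds_by_alt,
    hierarchical_cluster,
    meta_combine,
    summarize_time_course,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--zscores", type=Path, default=Path("results/zscores.tsv"))
    ap.add_argument("--meta", type=Path,
                    default=Path("results/data/metadata.csv"))
    ap.add_argument("--alt-threshold", type=float, default=65.0)
    ap.add_argument("--n-clusters", type=int, default=4)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("-o", "--out", type=Path,
                    default=Path("results/clusters.csv"))
    args = ap.parse_args()

    z = ScoreMatrix(io.read_expression(args.zscores), "zscore_vs_control")
    meta = io.read_metadata(args.meta)
    compounds = filter_compounds_by_alt(meta, threshold=args.alt_threshold)
    print(f"{len(compounds)} compounds pass the ALT >= "
          f"{args.alt_threshold:g} screen")

    feats = assemble_trafficking_features(z, meta, compounds=compounds)
    emb = embed_candidates(feats, seed=args.seed)
    md = meta_combine(emb)
    assign = hierarchical_cluster(md, n_clusters=args.n_clusters)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    assign.as_series().rename_axis("compound").to_csv(args.out)
    feats.rename_axis("compound").to_csv(args.out.with_name("features.csv"))
    md.matrix.to_csv(args.out.with_name("meta_distance.csv"))
    md.weights.rename_axis("compound").to_csv(
        args.out.with_name("meta_weights.csv")
    )
    consensus_mds(md, seed=args.seed).rename_axis("compound").to_csv(
        args.out.with_name("consensus_coords.csv")
    )
    tc = summarize_time_course(z.data, meta, assign)
    tc.to_csv(args.out.with_name("timecourse.csv"), index=False)

    sizes = assign.as_series().value_counts().sort_index()
    print("candidate embeddings:", ", ".join(emb.method_names))
    print("mean candidate weights:",
          json.dumps(md.weights.mean().round(3).to_dict()))
    print("cluster sizes:", sizes.to_dict())
    for k in sizes.index:
        members = [c for c, lab in assign.labels.items() if lab == k]
        print(f"  cluster {k}: {', '.join(members)}")
    print(f"written to {args.out} (+ features, meta_distance, "
          f"meta_weights, consensus_coords, timecourse)")


if __name__ == "__main__":
    main()
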