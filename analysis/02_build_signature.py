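"""Build the cell-type signature matrix from the reference profiles.

Intersects the reference with the bulk gene space, applies the marker
rule (enrichment > 1.5-fold over every other cell type, up to 200 genes
per type ranked by enrichment over the strongest competitor) and writes
the marker-gene x cell-type signature matrix.
"""

import argparse
from pathlib import Path

import pandas as pd

from immucast import build_signature, intersect_genes, io, select_markers


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--ref", type=Path, default=Path("results/data/reference.tsv"))
    ap.add_argument("--mixture", type=Path,
                    default=Path("results/data/expression.tsv"))
    ap.add_argument("--fc", type=float, default=1.5)
    ap.add_argument("--max-genes", type=int, default=200)
    ap.add_argument("-o", "--out", type=Path,
                    default=Path("results/signature.tsv"))
    args = ap.parse_args()

    ref = io.read_expression(args.ref)
    bulk = io.read_expression(args.mixture)
    ref, bulk = intersect_genes(ref, bulk)
    markers = select_markers(ref, fc_threshold=args.fc,
                             max_genes=args.max_genes)
    X = build_signature(ref, markers)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    io.write_expression(X, args.out)
    table = pd.DataFrame(
        [(c, g, r) for c, lst in markers.items() for g, r in lst],
        columns=["cell_type", "gene", "enrichment_ratio"],
    )
    table.to_csv(args.out.with_name("markers.csv"), index=False)

    counts = {c: len(lst) for c, lst in markers.items()}
    print(f"signature: {X.shape[0]} marker genes x {X.shape[1]} cell types")
    print(f"markers per type: {counts}")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
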