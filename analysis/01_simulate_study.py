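"""Simulate the compound study the rest of the analysis consumes.

Generates sorted-cell reference profiles, a 16-compound / 4-archetype
liver time-course with matched vehicle controls and ALT values, and a
gene-set collection with one planted cluster-discriminative set; writes
everything as plain tables under results/data/.
"""

import argparse
import json
from pathlib import Path

from immucast import io, simulate_gene_sets, simulate_study


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--n-compounds", type=int, default=16)
    ap.add_argument("--n-clusters", type=int, default=4)
    ap.add_argument("--effect-scale", type=float, default=3.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = simulate_study(
        n_compounds=args.n_compounds,
        n_clusters=args.n_clusters,
        effect_scale=args.effect_scale,
        seed=args.seed,
    )
    sets, planted = simulate_gene_sets(
        study, n_sets=200, set_size=50, n_discriminative=1,
        target_cluster=2, seed=args.seed + 1,
    )

    io.write_expression(study.expression, args.out / "expression.tsv")
    io.write_expression(study.reference, args.out / "reference.tsv")
    io.write_metadata(study.metadata, args.out / "metadata.csv")
    io.write_expression(
        study.truth.true_proportions, args.out / "true_proportions.tsv"
    )
    io.write_gmt(sets, args.out / "gene_sets.gmt")
    truth = {
        "true_cluster": study.truth.true_cluster,
        "planted_sets": planted,
        "true_markers": study.truth.true_markers,
        "seed": args.seed,
        "effect_scale": args.effect_scale,
    }
    (args.out / "truth.json").write_text(json.dumps(truth, indent=2))

    meta = study.metadata
    print(f"simulated {study.expression.shape[0]} genes x "
          f"{study.expression.shape[1]} samples "
          f"({(~meta['is_control']).sum()} treated, "
          f"{meta['is_control'].sum()} control)")
    print(f"{args.n_compounds} compounds in {args.n_clusters} planted "
          f"clusters at effect scale {args.effect_scale}; "
          f"planted gene set(s): {planted}")
    print(f"tables written under {args.out}/")


if __name__ == "__main__":
    main()
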