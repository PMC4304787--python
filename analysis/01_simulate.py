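#!/usr/bin/env python
"""Generate the synthetic study cohort.

Builds the reference scene (a sagittal MEC wedge with labeled layers and
neighbors), a 200-gene cohort at the default pixel noise with known laminar
classes and dorsoventral coefficients, and the coupled dorsal/ventral FPKM
table.  Writes the truth table, the FPKM table, the reference image and the
label mask under results/simulation/.
"""

import argparse
from pathlib import Path

from lamina import synthdata as sd
from lamina.images import write_image, write_mask


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--genes", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results/simulation"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = sd.SceneConfig(seed=args.seed)
    reference, mask = sd.generate_reference_scene(config)
    write_image(args.out / "reference.png", reference)
    write_mask(args.out / "labels.tif", mask)

    truths = sd.make_default_truth(args.genes, args.seed, noise_sd=2.0)
    records, table = sd.generate_gene_cohort(truths, config, args.seed)
    table.to_csv(args.out / "truth.tsv", sep="\t", index=False)
    fpkm = sd.generate_fpkm_table(truths, seed=args.seed + 1)
    fpkm.to_tsv(args.out / "fpkm.tsv")

    # a handful of example images, one per truth class
    seen = set()
    for truth, rec in zip(truths, (r for r in records
                                   if r.plane == "C" and r.replicate == 0)):
        if truth.kind in seen:
            continue
        seen.add(truth.kind)
        write_image(args.out / f"example_{truth.kind}.png", rec.expression)

    by_kind = table.kind.value_counts().to_dict()
    print(f"cohort of {len(truths)} genes, {len(records)} images "
          f"({', '.join(f'{k}: {v}' for k, v in sorted(by_kind.items()))})")
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
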