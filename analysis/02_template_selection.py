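"""Select the NMF template genes: upregulated in tumors versus normal liver,
then highly variable across one independent tumor sample per patient.

Reads the cohort written by 01_simulate_cohort.py and writes the selected
gene list plus the differential-expression table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

import lmsubtypes as L
from lmsubtypes import io as lio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--lfc", type=float, default=0.0)
    ap.add_argument("--sd", type=float, default=0.8)
    args = ap.parse_args()

    expr = lio.read_expression_matrix(args.cohort / "expression.tsv")
    annot = lio.read_annotation(args.cohort / "annotation.tsv")

    chosen = L.select_one_sample_per_patient(annot, seed=args.seed)
    tumors = expr.subset_samples(chosen)
    normals = expr.subset_samples(annot.normal_samples)
    sel = L.select_template_genes(tumors, normals, fc_min=args.lfc, fdr_max=args.fdr, sd_min=args.sd)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.Series(chosen, name="sample_id").to_csv(args.out / "discovery_samples.tsv", sep="\t", index=False)
    pd.Series(sel.template_genes, name="gene").to_csv(args.out / "template_genes.tsv", sep="\t", index=False)

    print(f"discovery samples (one per patient): {len(chosen)}")
    print(f"step i (log2FC > {args.lfc}, q <= {args.fdr}): {sel.n_upregulated} of {sel.n_input} genes up in tumors")
    print(f"step ii (SD > {args.sd} across tumors):       {sel.n_template} template genes")
    print(f"written to {args.out}/template_genes.tsv")


if __name__ == "__main__":
    main()
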