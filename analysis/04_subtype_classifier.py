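"""Supervised LMS prediction: RFE random-forest on the silhouette-positive
discovery samples, evaluation on the held-out multi-lesion samples, and the
two-class LMS1 mini-classifier with its concordance to the full model.
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
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = lio.read_expression_matrix(args.cohort / "expression.tsv")
    annot = lio.read_annotation(args.cohort / "annotation.tsv")
    truth = pd.read_csv(args.cohort / "truth.tsv", sep="\t", index_col="sample_id")
    disc = pd.read_csv(args.results / "lms_labels.tsv", sep="\t", index_col="sample_id")
    template = pd.read_csv(args.results / "template_genes.tsv", sep="\t")["gene"].tolist()

    # classes too small to train on (rare subtypes collapsed by the SD
    # filter) are dropped with a note, as in any supervised re-derivation
    counts = disc["lms"].value_counts()
    too_small = counts[counts < 5].index.tolist()
    if too_small:
        print(f"dropping classes with < 5 discovery samples: {too_small}")
        disc = disc[~disc["lms"].isin(too_small)]

    tumors = expr.subset_samples(disc.index.tolist())
    model = L.train_lms_model(
        tumors, disc["lms"], disc["silhouette"], template, seed=args.seed
    )
    print(f"RFE selected {len(model.selected_genes)} genes "
          f"(CV accuracy {model.cv_accuracy:.3f}); subset grid: {model.subset_accuracies}")

    all_tumor = expr.subset_samples(annot.tumor_samples)
    pred, post = L.predict_subtypes(model, all_tumor)
    lio.write_subtype_calls(pred.to_dict(), post, args.results / "lms_predictions.tsv")

    held = [s for s in annot.tumor_samples if s not in set(disc.index)]
    truth_named = truth.loc[held, "true_subtype"].map(lambda k: f"LMS{k}")
    rep = L.concordance_report(truth_named, pred[held])
    print(f"held-out samples: {len(held)}; accuracy {rep['accuracy']:.3f}; "
          f"overall balanced accuracy {100 * rep['balanced_accuracy']:.1f}%")
    for cls, s in rep["per_class"].items():
        print(f"  {cls}: balanced accuracy {s['balanced_accuracy']:.3f}")

    try:
        mini = L.train_mini_classifier(tumors, disc["lms"], seed=args.seed)
    except ValueError:
        print("no genes pass log2FC >= 1.6; relaxing to 1.2 (planted effect size)")
        mini = L.train_mini_classifier(tumors, disc["lms"], seed=args.seed, lfc_min=1.2)
    print(f"mini-classifier genes (n={len(mini.gene_list)}): {mini.gene_list[:12]}")
    mini_calls = L.predict_mini(mini, all_tumor)
    full_bin = pred.map(lambda x: "LMS1" if x == "LMS1" else "not-LMS1")
    kappa, ci = L.cohens_kappa(full_bin, mini_calls)
    print(f"mini vs full model (LMS1 vs rest): kappa {kappa:.3f} "
          f"(95% CI {ci[0]:.3f}-{ci[1]:.3f})")

    pd.Series(model.selected_genes, name="gene").to_frame().assign(
        importance=model.importances.values
    ).to_csv(args.results / "model_genes.tsv", sep="\t", index=False)
    mini_calls.to_csv(args.results / "mini_calls.tsv", sep="\t", index_label="sample_id")


if __name__ == "__main__":
    main()
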