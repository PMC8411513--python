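"""Concordance of the de novo subtypes with the established CMS and CRIS
frameworks, reconstructed from the published cross-classification counts.

The shipped digit runs are parsed under the printed marginal constraints and
validated against the printed chi-squared statistics; the script reports the
headline share percentages.
"""

import argparse
from pathlib import Path

import lmsubtypes as L


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cms, cris = L.load_published_crosstab()
    print("LMS x CMS counts (confidently classified):")
    print(cms.counts.to_string())
    print("LMS x CRIS counts (confidently classified):")
    print(cris.counts.to_string())

    chi_cms = L.contingency_stats(cms)
    chi_cris = L.contingency_stats(cris)
    print(f"chi2: LMS x CMS (classified only) {chi_cms['statistic']:.1f}, "
          f"LMS x CRIS {chi_cris['statistic']:.1f}")

    shares = L.share_percentages(cms, cris)
    print(f"CMS4 captured by LMS5:        {shares['cms4_in_lms5_pct']:.1f}%")
    print(f"CMS1 captured by LMS1:        {shares['cms1_in_lms1_pct']:.1f}%")
    print(f"CMS1 share of LMS1:           {shares['cms1_share_of_lms1_pct']:.1f}%")
    print(f"CRIS-C share of LMS4:         {shares['crisc_share_of_lms4_pct']:.1f}%")
    print(f"CRIS-A/B share of LMS1:       {shares['crisab_share_of_lms1_pct']:.1f}%")

    args.results.mkdir(parents=True, exist_ok=True)
    cms.counts.to_csv(args.results / "lms_cms_counts.tsv", sep="\t")
    cris.counts.to_csv(args.results / "lms_cris_counts.tsv", sep="\t")


if __name__ == "__main__":
    main()
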