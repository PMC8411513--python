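"""Reconstruction of the published LMS-versus-CMS/CRIS cross-tabulation.

The published table is shipped as one undelimited digit run per subtype row
(4 CMS cells followed by 5 CRIS cells). The parser enumerates every split of
each run into 1-2 digit cells (no leading zeros on two-digit cells),
restricts the candidates with the marginal facts printed alongside the table
(count/denominator pairs such as 38/58 and 10/22, the confident
classification totals, and the subtype prevalences), and finally
disambiguates with the printed Pearson chi-squared statistics. For the CMS
table the printed statistic corresponds to the table extended with a
per-subtype "not confidently classified" remainder column (subtype totals
from the printed prevalence percentages of the 169-sample cohort); the CRIS
statistic corresponds to the 5x5 table as printed.
"""

from __future__ import annotations

import itertools
import json
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .datamodel import ContingencyTable

__all__ = [
    "load_published_crosstab",
    "parse_crosstab",
    "share_percentages",
]

_CHI2_TOL = 0.15  # printed statistics carry one decimal


def _splits(run: str, n_cells: int) -> list[tuple[int, ...]]:
    """All ways to cut a digit run into n_cells cells of 1-2 digits."""
    out: list[tuple[int, ...]] = []

    def rec(i: int, cells: list[int]) -> None:
        if len(cells) == n_cells:
            if i == len(run):
                out.append(tuple(cells))
            return
        for width in (1, 2):
            if i + width <= len(run):
                tok = run[i : i + width]
                if width == 2 and tok[0] == "0":
                    continue
                rec(i + width, cells + [int(tok)])

    rec(0, [])
    return out


def _row_candidates(run: str, n_cms: int, n_cris: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    cands = []
    for cms_len in range(n_cms, min(2 * n_cms, len(run) - n_cris) + 1):
        for cms in _splits(run[:cms_len], n_cms):
            for cris in _splits(run[cms_len:], n_cris):
                cands.append((cms, cris))
    return cands


def parse_crosstab(spec: dict) -> tuple[ContingencyTable, ContingencyTable]:
    """Parse the digit runs into the CMS and CRIS count tables.

    Raises if no candidate parse, or more than one, survives the marginal
    constraints and the chi-squared validation.
    """
    rows = spec["row_labels"]
    cms_cols = spec["cms_columns"]
    cris_cols = spec["cris_columns"]
    cons = spec["constraints"]
    n_cms, n_cris = len(cms_cols), len(cris_cols)

    known_cms = {tuple(k.split(",")): v for k, v in cons.get("known_cells_cms", {}).items()}
    known_cris = {tuple(k.split(",")): v for k, v in cons.get("known_cells_cris", {}).items()}
    cms_row_sums = cons.get("cms_row_sums", {})
    cris_row_sums = cons.get("cris_row_sums", {})

    per_row = []
    for ri, run in enumerate(spec["digit_runs"]):
        row = rows[ri]
        cands = []
        for cms, cris in _row_candidates(run, n_cms, n_cris):
            ok = True
            for (r, c), v in known_cms.items():
                if r == row and cms[cms_cols.index(c)] != v:
                    ok = False
            for (r, c), v in known_cris.items():
                if r == row and cris[cris_cols.index(c)] != v:
                    ok = False
            if row in cms_row_sums and sum(cms) != cms_row_sums[row]:
                ok = False
            if row in cris_row_sums and sum(cris) != cris_row_sums[row]:
                ok = False
            if ok:
                cands.append((cms, cris))
        if not cands:
            raise ValueError(f"no admissible parse for row {row}")
        per_row.append(cands)

    lms_totals = np.round(
        np.asarray(cons["lms_prevalence_percent"], dtype=float) / 100.0 * cons["cohort_size"]
    )
    # the rounded prevalences may not sum to the cohort; distribute the
    # remainder over the largest fractional parts
    frac = (
        np.asarray(cons["lms_prevalence_percent"], dtype=float) / 100.0 * cons["cohort_size"]
        - lms_totals
    )
    short = int(cons["cohort_size"] - lms_totals.sum())
    if short:
        order = np.argsort(-frac if short > 0 else frac)
        for i in range(abs(short)):
            lms_totals[order[i]] += np.sign(short)
    lms_totals = lms_totals.astype(int)

    matches = []
    for combo in itertools.product(*per_row):
        cms = np.array([c[0] for c in combo])
        cris = np.array([c[1] for c in combo])
        ok = True
        for col, total in cons.get("cms_column_sums", {}).items():
            if cms[:, cms_cols.index(col)].sum() != total:
                ok = False
        if "cris_total" in cons and cris.sum() != cons["cris_total"]:
            ok = False
        if not ok:
            continue
        unclassified = lms_totals - cms.sum(axis=1)
        if (unclassified < 0).any():
            continue
        extended = np.hstack([cms, unclassified[:, None]])
        chi2_cms = chi2_contingency(extended, correction=False)[0]
        chi2_cris = chi2_contingency(cris, correction=False)[0]
        if abs(chi2_cms - cons["chi2_cms"]) > _CHI2_TOL:
            continue
        if abs(chi2_cris - cons["chi2_cris"]) > _CHI2_TOL:
            continue
        matches.append((cms, cris))

    uniq = {(m[0].tobytes(), m[1].tobytes()) for m in matches}
    if not matches:
        raise ValueError("no parse satisfies the marginal and chi-squared constraints")
    if len(uniq) > 1:
        raise ValueError(f"ambiguous parse: {len(uniq)} tables satisfy all constraints")
    cms, cris = matches[0]
    return (
        ContingencyTable(pd.DataFrame(cms, index=rows, columns=cms_cols)),
        ContingencyTable(pd.DataFrame(cris, index=rows, columns=cris_cols)),
    )


def load_published_crosstab() -> tuple[ContingencyTable, ContingencyTable]:
    """Load and parse the shipped published cross-tabulation."""
    ref = resources.files("lmsubtypes.data").joinpath("lms_cms_cris_crosstab.json")
    spec = json.loads(ref.read_text())
    return parse_crosstab(spec)


def share_percentages(cms: ContingencyTable, cris: ContingencyTable) -> dict[str, float]:
    """The five headline share percentages of the cross-tabulation.

    Column shares answer "which subtype captures this framework class";
    row shares answer "how is this subtype composed".
    """
    c = cms.counts
    r = cris.counts
    return {
        "cms4_in_lms5_pct": 100.0 * c.loc["LMS5", "CMS4"] / c["CMS4"].sum(),
        "cms1_in_lms1_pct": 100.0 * c.loc["LMS1", "CMS1"] / c["CMS1"].sum(),
        "cms1_share_of_lms1_pct": 100.0 * c.loc["LMS1", "CMS1"] / c.loc["LMS1"].sum(),
        "crisc_share_of_lms4_pct": 100.0 * r.loc["LMS4", "CRIS-C"] / r.loc["LMS4"].sum(),
        "crisab_share_of_lms1_pct": 100.0
        * (r.loc["LMS1", "CRIS-A"] + r.loc["LMS1", "CRIS-B"])
        / r.loc["LMS1"].sum(),
    }
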