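"""Anti-correlation refinement of DEM-DEG pairs and epigenetic-regulator
classification.

A predicted miRNA-target pair survives refinement when the Pearson
correlation between the miRNA's and the transcript's expression over the
three temperature-condition means is strictly below -0.6, the miRNA is a DEM
and the transcript a DEG.  Retained pairs hitting annotated epigenetic
regulators are tabulated by modification category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: the eight epigenetic-regulator categories
REGULATOR_CATEGORIES = (
    "DNA methylation",
    "Histone methylation",
    "Histone acetylation",
    "Histone (protein) phosphorylation",
    "Histone ubiquitination (sumoylation)",
    "Chromatin remodeling",
    "sRNA pathways",
    "Thermosensing",
)

CONDITIONS = ("18", "23", "28")


def pearson_3pt(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over the three condition means; NaN when degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def correlate_pairs(
    target_table: pd.DataFrame,
    mirna_means: pd.DataFrame,
    mrna_means: pd.DataFrame,
    dems: set[str] | None = None,
    degs: set[str] | None = None,
    threshold: float = -0.6,
    method: str = "pearson",
) -> pd.DataFrame:
    """Attach cross-temperature correlations to predicted pairs.

    Parameters
    ----------
    target_table : DataFrame
        One row per (mirna, transcript) best site, with an ``expectation``
        column.
    mirna_means, mrna_means : DataFrame
        Condition means, rows indexed by id, columns "18"/"23"/"28".
    dems, degs : sets
        Differential-expression memberships; default: all ids present.
    threshold : float
        A pair is retained when r < threshold (strict).
    """
    cols = list(CONDITIONS)
    rows = []
    for rec in target_table.itertuples(index=False):
        m, t = rec.mirna, rec.transcript
        if m not in mirna_means.index or t not in mrna_means.index:
            rows.append((m, t, rec.expectation, np.nan, False, "missing expression"))
            continue
        r = pearson_3pt(mirna_means.loc[m, cols].values, mrna_means.loc[t, cols].values)
        if method == "spearman":
            from scipy import stats

            r = float(
                stats.spearmanr(
                    mirna_means.loc[m, cols].values, mrna_means.loc[t, cols].values
                ).statistic
            )
        # round before the strict comparison so an exact-threshold profile is
        # classified deterministically despite float noise
        if not np.isnan(r):
            r = float(np.round(r, 12))
        flag = ""
        if np.isnan(r):
            flag = "degenerate profile"
        retained = (
            (not np.isnan(r))
            and r < threshold
            and (dems is None or m in dems)
            and (degs is None or t in degs)
        )
        rows.append((m, t, rec.expectation, r, retained, flag))
    return pd.DataFrame(
        rows, columns=["mirna", "transcript", "expectation", "r", "retained", "flag"]
    )


def call_degs(
    mrna_means: pd.DataFrame, min_abs_log2: float = 1.0, pseudo: float | None = None
) -> set[str]:
    """Transcripts with |log2 fold change| > threshold in >=1 contrast.

    The mRNA table carries condition means only (transcript amounts taken
    from a prior expression study), so the DEG call is a fold-change rule.
    """
    vals = mrna_means[list(CONDITIONS)].values.astype(float)
    if pseudo is None:
        nz = vals[vals > 0]
        pseudo = float(nz.min()) / 2.0 if nz.size else 0.5
    lv = np.log2(vals + pseudo)
    contrasts = [(0, 1), (1, 2), (0, 2)]
    hit = np.zeros(len(mrna_means), dtype=bool)
    for a, b in contrasts:
        hit |= np.abs(lv[:, a] - lv[:, b]) > min_abs_log2
    return set(mrna_means.index[hit])


def classify_regulators(pairs: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach the regulator category of each target transcript.

    ``annotation`` maps transcript -> category; categories must come from
    the closed 8-value set.
    """
    bad = set(annotation["category"]) - set(REGULATOR_CATEGORIES)
    if bad:
        raise ValueError(
            f"unknown regulator categories {sorted(bad)}; "
            f"allowed: {list(REGULATOR_CATEGORIES)}"
        )
    cat = annotation.set_index("transcript")["category"]
    out = pairs.copy()
    out["category"] = out["transcript"].map(cat)
    return out


def summarize(
    pairs: pd.DataFrame,
    dems: set[str],
    degs: set[str],
    stage_counts: dict | None = None,
) -> dict:
    """Summary tables shaped like the per-category and per-family censuses.

    Returns a dict with ``category_table`` (category x [n miRNAs, n target
    gene models, n DEMs, n target DEGs]), ``census`` (targets per miRNA /
    miRNAs per target) and a JSON-ready ``report``.
    """
    cat_rows = []
    has_cat = "category" in pairs.columns
    for cat in REGULATOR_CATEGORIES:
        sub = pairs[pairs["category"] == cat] if has_cat else pairs.iloc[0:0]
        ret = sub[sub["retained"]] if len(sub) else sub
        cat_rows.append(
            {
                "category": cat,
                "n_mirnas": sub["mirna"].nunique() if len(sub) else 0,
                "n_targets": sub["transcript"].nunique() if len(sub) else 0,
                "n_dems": ret["mirna"].nunique() if len(ret) else 0,
                "n_target_degs": ret["transcript"].nunique() if len(ret) else 0,
            }
        )
    category_table = pd.DataFrame(cat_rows).set_index("category")

    if len(pairs):
        targets_per_mirna = pairs.groupby("mirna")["transcript"].nunique()
        mirnas_per_target = pairs.groupby("transcript")["mirna"].nunique()
    else:
        targets_per_mirna = pd.Series(dtype=int)
        mirnas_per_target = pd.Series(dtype=int)

    retained = pairs[pairs["retained"]] if len(pairs) else pairs
    report = {
        "n_pairs_scanned": int(len(pairs)),
        "n_pairs_retained": int(len(retained)),
        "n_dems": len(dems),
        "n_degs": len(degs),
        "n_mirnas_in_retained_pairs": int(retained["mirna"].nunique()) if len(retained) else 0,
        "n_targets_in_retained_pairs": int(retained["transcript"].nunique()) if len(retained) else 0,
    }
    if stage_counts:
        report["stages"] = dict(stage_counts)
    return {
        "category_table": category_table,
        "targets_per_mirna": targets_per_mirna,
        "mirnas_per_target": mirnas_per_target,
        "report": report,
    }
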