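"""miRNA expression quantification, differential expression and profile
clustering across the three epitype-inducing temperatures.

Expression is quantified as RPKM (reads per kilobase of mature sequence per
million library reads).  Differential expression between two temperature
conditions uses the classic Z-test on pooled proportions (Kal's test): reads
for a miRNA are pooled within each condition, the two pooled proportions are
compared with

    Z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/N1 + 1/N2))

and a miRNA is called differentially expressed (a DEM) when, in at least one
pairwise contrast, |log2 RPKM ratio| > 1 (strict) and p < 0.05 (strict).  A
two-sided Fisher exact test on the pooled counts is available as an
alternative.  No multiple-testing correction is applied by default; a
Benjamini-Hochberg option exists.

Profile clustering is deterministic: each contrast contributes a sign
(+/-/0, zero when not significant) and the sign triple is mapped onto the
weak orderings of the three temperatures.  There are 13 consistent weak
orderings of three conditions; removing the flat one leaves exactly 12
non-flat profile classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTRASTS = (("18", "23"), ("23", "28"), ("18", "28"))
CONTRAST_NAMES = tuple(f"{a}v{b}" for a, b in CONTRASTS)


# ---------------------------------------------------------------------------
# weak-ordering profile label space
# ---------------------------------------------------------------------------

def _sign_triple(ranks: tuple[int, int, int]) -> tuple[int, int, int]:
    r = dict(zip(("18", "23", "28"), ranks))
    return tuple(int(np.sign(r[a] - r[b])) for a, b in CONTRASTS)


def _ordering_name(ranks: tuple[int, int, int]) -> str:
    levels: dict[int, list[str]] = {}
    for temp, rank in zip(("18", "23", "28"), ranks):
        levels.setdefault(rank, []).append(temp)
    groups = ["=".join(levels[r]) for r in sorted(levels, reverse=True)]
    return ">".join(groups)


def weak_orderings() -> dict[tuple[int, int, int], str]:
    """Map each consistent sign triple to its weak-ordering name.

    Enumerates all rank assignments of the three temperatures; 13 distinct
    sign triples result (12 non-flat plus the flat one).
    """
    out: dict[tuple[int, int, int], str] = {}
    for ranks in itertools.product(range(3), repeat=3):
        triple = _sign_triple(ranks)
        if triple not in out:
            out[triple] = _ordering_name(ranks)
    return out


_ORDERINGS = weak_orderings()
FLAT_TRIPLE = (0, 0, 0)

#: the 12 non-flat profile classes, numbered deterministically
CLUSTER_LABELS: dict[tuple[int, int, int], tuple[int, str]] = {
    triple: (i + 1, name)
    for i, (triple, name) in enumerate(
        sorted((t, n) for t, n in _ORDERINGS.items() if t != FLAT_TRIPLE)
    )
}


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
    temperatures: pd.Series,
) -> "ExpressionSet":
    """Compute RPKM and per-temperature condition means.

    Parameters
    ----------
    counts : DataFrame
        Raw counts, miRNAs x libraries.
    lengths : Series
        Mature length (nt) per miRNA.
    library_sizes : Series
        Post-filter read total per library (RPKM denominator).
    temperatures : Series
        Temperature condition per library (values in {18, 23, 28}).
    """
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero-size libraries: {list(zero.index)}")
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    rpkm = counts.div(library_sizes / 1e6, axis=1).div(lengths / 1000.0, axis=0)
    return ExpressionSet(counts, rpkm, lengths, library_sizes, temperatures.astype(str))


@dataclass
class ExpressionSet:
    """Counts + RPKM for a miRNA catalog over the 18 libraries."""

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    temperatures: pd.Series  # library -> "18" / "23" / "28"

    def condition_libraries(self, cond: str) -> list[str]:
        return list(self.temperatures.index[self.temperatures == cond])

    def condition_mean_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: self.counts[self.condition_libraries(c)].mean(axis=1) for c in ("18", "23", "28")}
        )

    def condition_mean_rpkm(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: self.rpkm[self.condition_libraries(c)].mean(axis=1) for c in ("18", "23", "28")}
        )


def filter_expressed(expr: ExpressionSet, min_mean: float = 10.0) -> ExpressionSet:
    """Keep miRNAs whose mean raw count reaches ``min_mean`` in >=1 condition."""
    keep = (expr.condition_mean_counts() >= min_mean).any(axis=1)
    idx = expr.counts.index[keep]
    return ExpressionSet(
        expr.counts.loc[idx],
        expr.rpkm.loc[idx],
        expr.lengths.loc[idx],
        expr.library_sizes,
        expr.temperatures,
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def kal_z_test(x1: float, n1: float, x2: float, n2: float) -> float:
    """Two-sided p-value of the pooled-proportion Z-test."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x1 + x2 == 0:
        return 1.0
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    var = pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2)
    if var <= 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def fisher_test(x1: float, n1: float, x2: float, n2: float) -> float:
    """Two-sided Fisher exact test on pooled counts (alternative to Kal)."""
    table = [[round(x1), round(n1 - x1)], [round(x2), round(n2 - x2)]]
    return float(stats.fisher_exact(table).pvalue)


def de_test(
    expr: ExpressionSet,
    contrast: str,
    pseudo: float | None = None,
    method: str = "kal",
) -> pd.DataFrame:
    """Per-miRNA DE call for one contrast ("18v23", "23v28" or "18v28").

    log2 ratio is computed on mean RPKM with a pseudo-value (half the
    smallest nonzero RPKM in the matrix) guarding zeros; the p-value comes
    from pooled counts.
    """
    if contrast not in CONTRAST_NAMES:
        raise ValueError(f"unknown contrast {contrast!r}; expected {CONTRAST_NAMES}")
    a, b = contrast.split("v")
    libs_a = expr.condition_libraries(a)
    libs_b = expr.condition_libraries(b)
    if not libs_a or not libs_b:
        raise ValueError(f"contrast {contrast} has an empty condition")
    if pseudo is None:
        nz = expr.rpkm.values[expr.rpkm.values > 0]
        pseudo = float(nz.min()) / 2.0 if nz.size else 0.5
    mean_a = expr.rpkm[libs_a].mean(axis=1)
    mean_b = expr.rpkm[libs_b].mean(axis=1)
    # rounded so a ratio sitting exactly on the strict threshold is
    # classified deterministically
    log2_ratio = np.round(np.log2((mean_a + pseudo) / (mean_b + pseudo)), 12)
    n1 = float(expr.library_sizes[libs_a].sum())
    n2 = float(expr.library_sizes[libs_b].sum())
    x1 = expr.counts[libs_a].sum(axis=1)
    x2 = expr.counts[libs_b].sum(axis=1)
    test = {"kal": kal_z_test, "fisher": fisher_test}[method]
    pvals = np.array([test(float(a_), n1, float(b_), n2) for a_, b_ in zip(x1, x2)])
    out = pd.DataFrame(
        {
            "mirna": expr.counts.index,
            "contrast": contrast,
            "log2_ratio": log2_ratio.values,
            "p_value": pvals,
        }
    )
    out["significant"] = (out["log2_ratio"].abs() > 1.0) & (out["p_value"] < 0.05)
    return out


def de_all_contrasts(
    expr: ExpressionSet,
    method: str = "kal",
    alpha: float = 0.05,
    min_abs_log2: float = 1.0,
    bh_fdr: bool = False,
) -> pd.DataFrame:
    """DE calls for all three pairwise temperature contrasts."""
    frames = [de_test(expr, c, method=method) for c in CONTRAST_NAMES]
    de = pd.concat(frames, ignore_index=True)
    pcol = "p_value"
    if bh_fdr:
        de["q_value"] = _bh_adjust(de["p_value"].values)
        pcol = "q_value"
    de["significant"] = (de["log2_ratio"].abs() > min_abs_log2) & (de[pcol] < alpha)
    return de


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    q = np.empty(n)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        prev = min(prev, p[idx] * n / rank)
        q[idx] = prev
    return q


def call_dems(de: pd.DataFrame) -> list[str]:
    """miRNAs significant in at least one contrast."""
    sig = de[de["significant"]]
    return sorted(sig["mirna"].unique())


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------

def cluster_profiles(de: pd.DataFrame, condition_means: pd.DataFrame) -> pd.DataFrame:
    """Assign each DEM a profile class from its contrast sign triple.

    A contrast contributes +1/-1 (direction of the log2 ratio) when
    significant, else 0.  Triples consistent with a non-flat weak ordering of
    the three temperatures map onto one of the 12 classes; inconsistent
    triples are re-signed from the ranks of the condition means and flagged.
    """
    dems = call_dems(de)
    piv_sig = de.pivot(index="mirna", columns="contrast", values="significant")
    piv_lr = de.pivot(index="mirna", columns="contrast", values="log2_ratio")
    rows = []
    for m in dems:
        triple = tuple(
            int(np.sign(piv_lr.loc[m, c])) if piv_sig.loc[m, c] else 0
            for c in CONTRAST_NAMES
        )
        resolved = False
        if triple not in _ORDERINGS:
            means = condition_means.loc[m]
            ranks = tuple(int(r) for r in means.rank(method="dense").astype(int) - 1)
            triple = _sign_triple(ranks)
            resolved = True
        if triple == FLAT_TRIPLE:
            cluster, name = 0, "flat"
        else:
            cluster, name = CLUSTER_LABELS[triple]
        rows.append(
            {
                "mirna": m,
                "sign_18v23": triple[0],
                "sign_23v28": triple[1],
                "sign_18v28": triple[2],
                "cluster": cluster,
                "profile": name,
                "resigned": resolved,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "sign_18v23",
            "sign_23v28",
            "sign_18v28",
            "cluster",
            "profile",
            "resigned",
        ],
    )


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_dem_rate(
    rng: np.random.Generator,
    n_mirnas: int = 500,
    n_reps: int = 200,
    libs_per_condition: int = 6,
    library_size: int = 100_000,
    mean_count: float = 30.0,
) -> float:
    """Empirical DEM rate under the null (equal expected proportions).

    Simulates ``n_reps`` independent two-condition experiments with
    ``n_mirnas`` miRNAs whose expected proportion is identical in both
    conditions (per-miRNA Poisson counts, lognormal abundance spread), and
    returns the fraction of miRNA x replicate tests called significant at
    the joint threshold p < 0.05 and |log2 ratio| > 1.
    """
    n_sig = 0
    n_tot = 0
    n1 = n2 = float(libs_per_condition * library_size)
    for _ in range(n_reps):
        lam = mean_count * rng.lognormal(0.0, 1.0, size=n_mirnas)
        x1 = rng.poisson(lam * libs_per_condition)
        x2 = rng.poisson(lam * libs_per_condition)
        # pooled proportions Z-test, vectorised
        tot = x1 + x2
        with np.errstate(divide="ignore", invalid="ignore"):
            pbar = tot / (n1 + n2)
            var = pbar * (1 - pbar) * (1 / n1 + 1 / n2)
            z = np.where(var > 0, (x1 / n1 - x2 / n2) / np.sqrt(var), 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        pseudo = 0.5
        lr = np.log2((x1 + pseudo) / (x2 + pseudo))
        n_sig += int(((p < 0.05) & (np.abs(lr) > 1.0)).sum())
        n_tot += n_mirnas
    return n_sig / n_tot
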