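"""Flowering-trait derivation and treatment-comparison statistics.

Traits are days to buds visible (DTB) and days to first flower (DTF),
expressed relative to the end of vernalisation: day 0 is the day plants left
the cold, so negative values mean the stage was reached during pre-growth or
vernalisation. Never-flowering replicates are recorded missing. Group
comparisons use the two-sided Wilcoxon rank-sum test with the W statistic
reported on the Mann-Whitney scale (rank sum of group a minus
n_a(n_a+1)/2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PhenotypeTable

log = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "accession_id",
    "treatment",
    "replicate",
    "buds_day",
    "flower_day",
    "vern_end_day",
]


def read_scoring_records(path) -> pd.DataFrame:
    """Read per-plant scoring records (TSV with RECORD_COLUMNS; NA allowed)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scoring records missing column(s) {missing}")
    dup = df.duplicated(subset=["accession_id", "treatment", "replicate"])
    if dup.any():
        raise ValueError("replicate ids must be unique within accession x treatment")
    return df


def derive_traits(
    records: pd.DataFrame,
    nv_reference_day: float | None = None,
) -> PhenotypeTable:
    """Per-accession DTB/DTF traits from calendar-day scoring records.

    DTB = buds day - vernalisation end day; DTF likewise for first flower;
    values are averaged over replicates and missing when no replicate
    reached the stage. Treatments without a vernalisation end day (the
    non-vernalised control) use ``nv_reference_day``. Records with the
    flower before the buds stage are rejected with a log entry.
    """
    df = records.copy()
    bad = df["flower_day"].notna() & df["buds_day"].notna() & (df["flower_day"] < df["buds_day"])
    if bad.any():
        for _, row in df[bad].iterrows():
            log.warning(
                "rejecting record %s/%s rep %s: first flower before buds visible",
                row["accession_id"], row["treatment"], row["replicate"],
            )
        df = df[~bad]
    end = df["vern_end_day"].copy()
    if end.isna().any():
        if nv_reference_day is None:
            raise ValueError(
                "records without a vernalisation end day need nv_reference_day"
            )
        end = end.fillna(float(nv_reference_day))
    df = df.assign(dtb=df["buds_day"] - end, dtf=df["flower_day"] - end)
    cols = {}
    for (treatment,), grp in df.groupby(["treatment"], sort=False):
        cols[f"{treatment} DTB"] = grp.groupby("accession_id")["dtb"].mean()
        cols[f"{treatment} DTF"] = grp.groupby("accession_id")["dtf"].mean()
    values = pd.DataFrame(cols)
    values.index.name = "accession_id"
    return PhenotypeTable(values)


def derive_contrasts(
    pheno: PhenotypeTable,
    contrasts: list[tuple[str, str, str]],
) -> PhenotypeTable:
    """Difference traits: each spec entry is (new_name, trait_a, trait_b) with
    value a - b per accession, missing when either side is missing."""
    out = {}
    for name, a, b in contrasts:
        out[name] = pheno.trait(a) - pheno.trait(b)
    values = pd.DataFrame(out, index=pheno.values.index)
    return PhenotypeTable(values)


def compare_groups_wilcoxon(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) with W the Mann-Whitney statistic of group a (rank sum of
    a minus n_a(n_a+1)/2). The null distribution is enumerated exactly for
    n_a + n_b <= 20 without ties, otherwise the normal approximation with
    continuity and tie correction is used.
    """
    a = np.asarray(pd.Series(values_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(values_b).dropna(), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one non-missing value")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def summarize_treatments(
    pheno: PhenotypeTable, grouping: dict[str, list[str]]
) -> pd.DataFrame:
    """Pooled mean/sd/n per group of traits (missing excluded, sd with n-1)."""
    rows = []
    for group, traits in grouping.items():
        vals = pd.concat([pheno.trait(t) for t in traits]).dropna().to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def expression_trait_r2(
    expr: ExpressionMatrix,
    gene_id: str,
    trait: pd.Series,
    subset: str = "all",
    k_low: int = 5,
    k_high: int = 5,
) -> float:
    """Squared Pearson correlation between a gene's RPKM and a trait.

    ``subset="extremes"`` restricts to the k_low lowest- plus k_high
    highest-expressing accessions (by the gene's RPKM) before correlating,
    the comparison used to show that expression extremes track phenotype
    extremes. Constant expression yields NaN; fewer than 3 complete pairs is
    an error.
    """
    if gene_id not in expr.rpkm.index:
        raise KeyError(f"unknown gene {gene_id!r}")
    x = expr.rpkm.loc[gene_id]
    y = trait.reindex(x.index)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if subset == "extremes":
        order = x.sort_values(kind="mergesort").index
        pick = list(order[:k_low]) + list(order[-k_high:])
        x, y = x.loc[pick], y.loc[pick]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if len(x) < 3:
        raise ValueError("need at least 3 complete expression/trait pairs")
    if float(np.std(x)) == 0.0 or float(np.std(y)) == 0.0:
        log.warning("expression_trait_r2: constant input, R^2 undefined")
        return float("nan")
    r = np.corrcoef(x.to_numpy(dtype=float), y.to_numpy(dtype=float))[0, 1]
    return float(r * r)
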