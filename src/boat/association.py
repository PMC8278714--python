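"""Structure-corrected association scans, q-value FDR and linkage disequilibrium.

The marker scan regresses the trait on [intercept, structure covariates,
minor-allele dosage] by ordinary least squares and tests the dosage term with
a partial F-test, i.e. the general linear model used for continuous traits in
crop association panels. Marker R^2 is the incremental sum of squares of the
dosage term over the total (centred) trait sum of squares among the
accessions actually used. The gene-expression-marker (GEM) scan regresses the
trait on a gene's RPKM value and t-tests the slope, after excluding genes
with mean expression below an RPKM floor. Multiple testing is handled with
Storey q-values; with pi0 fixed at 1 these reduce exactly to step-up
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io import (
    AMBIGUITY,
    MISSING,
    AnnotationTable,
    ExpressionMatrix,
    MarkerTable,
    QMatrix,
    chromosome_sort_key,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dosage encoding
# ---------------------------------------------------------------------------

def _marker_alleles_and_dosage(calls: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Minor-allele dosage for one marker's calls (vector of single chars).

    Returns (dosage with NaN for missing, (major, minor)).
    """
    freqs: dict[str, float] = {}
    for c in calls:
        if c == MISSING:
            continue
        for a in AMBIGUITY.get(c, (c, c)):
            freqs[a] = freqs.get(a, 0.0) + 0.5
    alleles = sorted(freqs)
    if len(alleles) > 2:
        raise ValueError("marker has more than two underlying alleles")
    if len(alleles) == 0:
        return np.full(len(calls), np.nan), (None, None)
    if len(alleles) == 1:
        major, minor = alleles[0], None
    else:
        a, b = alleles
        # minor = rarer allele; tie -> alphabetically first
        minor, major = (a, b) if freqs[a] <= freqs[b] else (b, a)
        if freqs[a] == freqs[b]:
            minor, major = a, b
    dose = np.full(len(calls), np.nan)
    for i, c in enumerate(calls):
        if c == MISSING:
            continue
        if c in AMBIGUITY:
            dose[i] = 1.0
        else:
            dose[i] = 2.0 if c == minor else 0.0
    if minor is None:
        dose[~np.isnan(dose)] = 0.0
    return dose, (major, minor)


def encode_dosage(table: MarkerTable, marker_id: str) -> np.ndarray:
    """Per-accession minor-allele count in {0, 1, 2} (NaN = missing).

    Homozygous minor = 2, mixed-base call = 1, homozygous major = 0. The
    minor allele is the rarer of the two on the dosage scale; an exact tie is
    broken alphabetically.
    """
    if marker_id not in table.meta.index:
        raise KeyError(f"unknown marker {marker_id!r}")
    calls = table.calls.loc[marker_id].to_numpy(dtype="<U1")
    dose, _ = _marker_alleles_and_dosage(calls)
    return dose


def dosage_matrix(table: MarkerTable) -> tuple[np.ndarray, list[str]]:
    """accessions x markers minor-allele dosage matrix (NaN = missing).

    Markers with more than two underlying alleles are dropped; the retained
    marker ids are returned alongside.
    """
    cols, kept = [], []
    arr = table.calls.to_numpy(dtype="<U1")
    for l, mid in enumerate(table.meta.index):
        try:
            dose, _ = _marker_alleles_and_dosage(arr[l])
        except ValueError:
            continue
        cols.append(dose)
        kept.append(mid)
    X = np.column_stack(cols) if cols else np.empty((table.n_accessions, 0))
    return X, kept


# ---------------------------------------------------------------------------
# OLS machinery
# ---------------------------------------------------------------------------

def _ols_partial_f(y: np.ndarray, covariates: np.ndarray | None, x: np.ndarray):
    """Partial F-test of x in y ~ [1, covariates, x].

    Returns (p_value, incremental_r2, slope) or None when the full model is
    rank-deficient (x collinear with the covariates).
    """
    n = len(y)
    ones = np.ones((n, 1))
    reduced = ones if covariates is None else np.hstack([ones, covariates])
    full = np.hstack([reduced, x[:, None]])
    beta_r, _, rank_red, _ = np.linalg.lstsq(reduced, y, rcond=None)
    beta_f, _, rank_full, _ = np.linalg.lstsq(full, y, rcond=None)
    if rank_full <= rank_red:
        return None
    rss_r = float(np.sum((y - reduced @ beta_r) ** 2))
    rss_f = float(np.sum((y - full @ beta_f) ** 2))
    df_den = n - rank_full
    if df_den <= 0:
        return None
    tss = float(np.sum((y - y.mean()) ** 2))
    num = max(rss_r - rss_f, 0.0)
    if rss_f <= 0:
        p = 0.0
    else:
        f = (num / 1.0) / (rss_f / df_den)
        p = float(stats.f.sf(f, 1, df_den))
    r2 = num / tss if tss > 0 else np.nan
    return p, r2, float(beta_f[-1])


def _correction_matrix(correction, accessions: list[str]) -> tuple[np.ndarray | None, str]:
    """Covariate matrix + model tag from a QMatrix, PC-score frame, or None.

    Q-matrix correction drops the last ancestry column (rows sum to one, so
    the full matrix is collinear with the intercept).
    """
    if correction is None:
        return None, "GLM"
    if isinstance(correction, QMatrix):
        q = correction.proportions.loc[accessions].to_numpy(dtype=float)
        return (q[:, :-1] if q.shape[1] > 1 else None), "GLM+Q"
    if isinstance(correction, pd.DataFrame):
        return correction.loc[accessions].to_numpy(dtype=float), "GLM+PCA"
    raise TypeError(f"unsupported correction type {type(correction).__name__}")


# ---------------------------------------------------------------------------
# marker scan
# ---------------------------------------------------------------------------

def gwas_scan(
    pheno: pd.Series,
    geno: MarkerTable,
    correction: QMatrix | pd.DataFrame | None = None,
    min_maf: float = 0.05,
    compute_q: bool = True,
) -> pd.DataFrame:
    """Per-marker GLM association scan with casewise deletion.

    For each (<= 2)-allele marker: drop accessions missing the trait or the
    call, re-check MAF > min_maf on the used subset, then partial-F-test the
    dosage term over [intercept, correction covariates]. Returns an
    association table with -log10 p, marker R^2 and (optionally) q-values.
    """
    trait = pheno.reindex(geno.accessions)
    if trait.isna().all():
        raise ValueError("trait has no observed values")
    y_all = trait.to_numpy(dtype=float)
    X, kept = dosage_matrix(geno)
    cov_all, tag = _correction_matrix(correction, geno.accessions)

    if cov_all is None:
        return _simple_scan(y_all, X, kept, geno, min_maf, tag, compute_q)

    rows = []
    skipped = 0
    for j, mid in enumerate(kept):
        d = X[:, j]
        use = ~np.isnan(d) & ~np.isnan(y_all)
        n_used = int(use.sum())
        if n_used < 10:
            skipped += 1
            continue
        dsub = d[use]
        maf = float(dsub.mean() / 2.0)
        maf = min(maf, 1.0 - maf)
        if maf <= min_maf:
            continue
        res = _ols_partial_f(y_all[use], None if cov_all is None else cov_all[use], dsub)
        if res is None:
            log.info("gwas_scan: %s collinear with covariates; skipped", mid)
            skipped += 1
            continue
        p, r2, slope = res
        rows.append(
            {
                "unit_id": mid,
                "chromosome": geno.meta.loc[mid, "chromosome"],
                "order_index": int(geno.meta.loc[mid, "order_index"]),
                "maf": maf,
                "n_used": n_used,
                "p_value": p,
                "minus_log10_p": -np.log10(max(p, 1e-300)),
                "marker_r2": r2,
                "slope": slope,
                "model_tag": tag,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "chromosome", "order_index", "maf", "n_used",
            "p_value", "minus_log10_p", "marker_r2", "slope", "model_tag",
        ],
    )
    if compute_q and len(out):
        out["q_value"] = qvalues(out["p_value"].to_numpy()).q
    else:
        out["q_value"] = np.nan
    if skipped:
        log.info("gwas_scan: %d markers skipped", skipped)
    return out


def _simple_scan(y_all, X, kept, geno, min_maf, tag, compute_q):
    """Vectorised uncorrected scan: simple regression per marker via masked sums.

    Algebraically identical to the per-marker OLS/F path (F = (n-2) r^2 / (1 - r^2)).
    """
    obs = ~np.isnan(X) & ~np.isnan(y_all)[:, None]
    Xz = np.where(obs, X, 0.0)
    Yz = np.where(obs, y_all[:, None], 0.0)
    n = obs.sum(axis=0).astype(float)
    sx = Xz.sum(axis=0)
    sy = Yz.sum(axis=0)
    sxx = (Xz * Xz).sum(axis=0)
    syy = (Yz * Yz).sum(axis=0)
    sxy = (Xz * Yz).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = sxx - sx * sx / n
        syy_c = syy - sy * sy / n
        sxy_c = sxy - sx * sy / n
        maf = sx / n / 2.0
        maf = np.minimum(maf, 1.0 - maf)
        r2 = sxy_c * sxy_c / (sxx_c * syy_c)
        slope = sxy_c / sxx_c
    usable = (n >= 10) & (maf > min_maf) & (sxx_c > 1e-12)
    rows = []
    for j in np.flatnonzero(usable):
        nj = n[j]
        r2j = float(min(max(r2[j], 0.0), 1.0)) if syy_c[j] > 0 else np.nan
        if syy_c[j] <= 0:
            p = 1.0
            r2j = np.nan
        elif r2j >= 1.0:
            p = 0.0
        else:
            f = (nj - 2) * r2j / (1.0 - r2j)
            p = float(stats.f.sf(f, 1, nj - 2))
        mid = kept[j]
        rows.append(
            {
                "unit_id": mid,
                "chromosome": geno.meta.loc[mid, "chromosome"],
                "order_index": int(geno.meta.loc[mid, "order_index"]),
                "maf": float(maf[j]),
                "n_used": int(nj),
                "p_value": p,
                "minus_log10_p": -np.log10(max(p, 1e-300)),
                "marker_r2": r2j,
                "slope": float(slope[j]),
                "model_tag": tag,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "chromosome", "order_index", "maf", "n_used",
            "p_value", "minus_log10_p", "marker_r2", "slope", "model_tag",
        ],
    )
    if compute_q and len(out):
        out["q_value"] = qvalues(out["p_value"].to_numpy()).q
    else:
        out["q_value"] = np.nan
    return out


# ---------------------------------------------------------------------------
# GEM scan
# ---------------------------------------------------------------------------

def gem_scan(
    pheno: pd.Series,
    expr: ExpressionMatrix,
    min_mean_rpkm: float = 0.5,
    correction: QMatrix | pd.DataFrame | None = None,
    compute_q: bool = True,
) -> pd.DataFrame:
    """Per-gene fixed-effect linear model of the trait on RPKM.

    Genes with mean expression below ``min_mean_rpkm`` (recomputed on the
    used accessions) are excluded; the RPKM slope is t-tested. Output rows
    follow the expression matrix's gene order metadata when present.
    """
    trait = pheno.reindex(expr.accessions)
    y_all = trait.to_numpy(dtype=float)
    R = expr.rpkm.to_numpy(dtype=float)  # genes x accessions
    cov_all, tag = _correction_matrix(correction, expr.accessions)
    tag = "GEM" if tag == "GLM" else f"GEM+{tag.split('+')[-1]}"

    rows = []
    for g, gene in enumerate(expr.gene_ids):
        x = R[g]
        use = ~np.isnan(x) & ~np.isnan(y_all)
        n_used = int(use.sum())
        if n_used < 3:
            continue
        mean_rpkm = float(x[use].mean())
        if mean_rpkm < min_mean_rpkm:
            continue
        res = _ols_partial_f(y_all[use], None if cov_all is None else cov_all[use], x[use])
        if res is None:
            continue
        p, r2, slope = res
        chrom, order = "C00", g + 1
        if expr.meta is not None:
            if "chromosome" in expr.meta.columns and pd.notna(expr.meta.iloc[g].get("chromosome")):
                chrom = str(expr.meta.iloc[g]["chromosome"])
            if "order_index" in expr.meta.columns and pd.notna(expr.meta.iloc[g].get("order_index")):
                order = int(expr.meta.iloc[g]["order_index"])
        rows.append(
            {
                "unit_id": gene,
                "chromosome": chrom,
                "order_index": order,
                "mean_rpkm": mean_rpkm,
                "n_used": n_used,
                "p_value": p,
                "minus_log10_p": -np.log10(max(p, 1e-300)),
                "marker_r2": r2,
                "slope": slope,
                "model_tag": tag,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "chromosome", "order_index", "mean_rpkm", "n_used",
            "p_value", "minus_log10_p", "marker_r2", "slope", "model_tag",
        ],
    )
    if len(out) == 0:
        log.warning("gem_scan: no genes pass the %.2f RPKM floor", min_mean_rpkm)
    if compute_q and len(out):
        out["q_value"] = qvalues(out["p_value"].to_numpy()).q
    else:
        out["q_value"] = np.nan
    if len(out):
        key = out["chromosome"].map(lambda c: chromosome_sort_key(str(c)))
        out = out.iloc[np.lexsort((out["order_index"].to_numpy(), key.to_numpy()))]
        out = out.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

class QValueResult:
    """Container for a q-value computation: p, pi0 estimate, q."""

    def __init__(self, p: np.ndarray, pi0: float, q: np.ndarray):
        self.p = p
        self.pi0 = pi0
        self.q = q


def qvalues(p, pi0: float | None = None) -> QValueResult:
    """Storey q-values.

    pi0 (the null proportion) is estimated from pi0(lambda) = #{p > lambda} /
    (m (1 - lambda)) on the grid lambda = 0.05, 0.10, ..., 0.95, smoothed
    with a cubic spline and evaluated at lambda = 0.95, clamped to (0, 1].
    q_i = min over thresholds t >= p_i of pi0 * m * t / #{p <= t}. Passing
    pi0=1 yields step-up Benjamini-Hochberg exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
        if m < 5 or np.all(pi0_lam == pi0_lam[0]):
            pi0_est = float(pi0_lam.mean())
        else:
            spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
            pi0_est = float(spline(lam[-1]))
        pi0 = min(pi0_est, 1.0)
        pi0 = max(pi0, 1.0 / m)  # keep strictly positive
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q[order] = q_sorted
    return QValueResult(p, float(pi0), q)


def significant_hits(table: pd.DataFrame, fdr: float = 0.05):
    """Rows with q < fdr, plus the -log10 p height of the FDR threshold line.

    The threshold is the largest p among calls with q < fdr (None when
    nothing is significant).
    """
    if len(table) == 0:
        return table.copy(), None
    hits = table[table["q_value"] < fdr].copy()
    if len(hits) == 0:
        return hits, None
    threshold = float(-np.log10(max(hits["p_value"].max(), 1e-300)))
    return hits, threshold


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _pairwise_r2(a: np.ndarray, b: np.ndarray, min_pairs: int = 3) -> float:
    use = ~np.isnan(a) & ~np.isnan(b)
    if use.sum() < min_pairs:
        return np.nan
    x, y = a[use], b[use]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


class LDResult:
    """Window-limited pairwise r^2: pair table, mean, window size."""

    def __init__(self, pairs: pd.DataFrame, mean_r2: float, window: int):
        self.pairs = pairs
        self.mean_r2 = mean_r2
        self.window = window


def ld_window_r2(
    geno: MarkerTable,
    window: int = 50,
    min_maf: float = 0.05,
    within_chromosome: bool = False,
) -> LDResult:
    """Mean pairwise dosage r^2 for marker pairs within an index-distance window.

    Pairs are formed over the MAF-filtered marker list in overall order
    (chromosome-agnostic by default, mirroring a sliding window over the
    marker list); pairs with fewer than 3 co-observed accessions are skipped.
    """
    from .qc import marker_stats_table

    stats = marker_stats_table(geno)
    keep = stats.index[(stats["maf"].fillna(0) > min_maf) & (stats["n_alleles"] <= 2)]
    sub = geno.subset(keep)
    if sub.n_markers < 2:
        raise ValueError("need at least 2 qualifying markers")
    X, kept = dosage_matrix(sub)
    chroms = sub.meta.loc[kept, "chromosome"].to_numpy()
    rows = []
    skipped = 0
    m = len(kept)
    for d in range(1, min(window, m - 1) + 1):
        A, B = X[:, :-d], X[:, d:]
        for j in range(m - d):
            if within_chromosome and chroms[j] != chroms[j + d]:
                continue
            r2 = _pairwise_r2(A[:, j], B[:, j])
            if np.isnan(r2):
                skipped += 1
                continue
            rows.append((kept[j], kept[j + d], d, r2))
    pairs = pd.DataFrame(rows, columns=["marker_i", "marker_j", "index_distance", "r2"])
    mean_r2 = float(pairs["r2"].mean()) if len(pairs) else np.nan
    if skipped:
        log.info("ld_window_r2: %d pairs skipped (too few co-observed accessions)", skipped)
    return LDResult(pairs, mean_r2, window)


def ld_decay(geno: MarkerTable, focal_marker: str, max_index_distance: int = 50) -> pd.DataFrame:
    """r^2 of a focal marker against its neighbours, by index distance."""
    X, kept = dosage_matrix(geno)
    if focal_marker not in kept:
        raise KeyError(f"unknown or multi-allelic focal marker {focal_marker!r}")
    f = kept.index(focal_marker)
    rows = []
    for j, mid in enumerate(kept):
        d = abs(j - f)
        if d > max_index_distance:
            continue
        if mid == focal_marker:
            rows.append((mid, 0, 1.0))
            continue
        r2 = _pairwise_r2(X[:, f], X[:, j])
        if np.isnan(r2):
            continue
        rows.append((mid, d, r2))
    out = pd.DataFrame(rows, columns=["marker_id", "index_distance", "r2"])
    return out.sort_values(["index_distance", "marker_id"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# plotting tables and annotation
# ---------------------------------------------------------------------------

def manhattan_table(results: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cumulative x positions for a Manhattan plot.

    Markers are laid out chromosome by chromosome (C01..C09, then unanchored
    C00 last) in order_index order; x runs 1..N. Returns the augmented table
    and the per-chromosome x offsets.
    """
    out = results.copy()
    if len(out) == 0:
        out["x"] = []
        return out, {}
    key = out["chromosome"].map(lambda c: chromosome_sort_key(str(c)))
    out = out.iloc[np.lexsort((out["order_index"].to_numpy(), key.to_numpy()))].copy()
    offsets: dict[str, int] = {}
    x = np.empty(len(out), dtype=int)
    pos = 0
    for chrom in out["chromosome"].unique():
        n = int((out["chromosome"] == chrom).sum())
        offsets[chrom] = pos
        x[pos : pos + n] = np.arange(1, n + 1) + pos
        pos += n
    out["x"] = x
    return out.reset_index(drop=True), offsets


def annotate_candidates(hits: pd.DataFrame, annotation: AnnotationTable) -> pd.DataFrame:
    """Left-join orthologue annotation onto hits by gene id (blank when absent)."""
    out = hits.copy()
    gene_ids = out["unit_id"].map(lambda u: u.split(":")[0])
    ann_cols = [c for c in ("arabidopsis_id", "orthologue") if c in annotation.table.columns]
    for c in ann_cols:
        out[c] = gene_ids.map(annotation.table[c]).fillna("")
    for c in ("arabidopsis_id", "orthologue"):
        if c not in out.columns:
            out[c] = ""
    return out


def genomic_inflation(p: np.ndarray) -> float:
    """Median-based inflation factor of a p-value set (diagnostic only)."""
    p = np.asarray(p, dtype=float)
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
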