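"""Synthetic panels with known ground truth.

The generator emulates the structure of a fixed-line crop diversity panel:
K discrete subpopulations with admixture, Balding-Nichols allele-frequency
differentiation (cluster frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around an
ancestral frequency p), essentially homozygous doubled-haploid calls with a
small mixed-base (hemi-SNP) fraction and missingness, log-normal RPKM
expression with optional population shifts and zero-expression accessions,
and traits built as population effect + causal-marker effect +
causal-expression effect + Gaussian noise.

Default panel sizes mirror the study scale (69-90 accessions, a few hundred
to a thousand markers, K = 1-4) so that every pipeline stage runs at desk
scale with recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    PAIR_TO_CODE,
    AnnotationTable,
    ExpressionMatrix,
    MarkerTable,
    PhenotypeTable,
    write_annotation,
    write_expression,
    write_marker_table,
    write_phenotypes,
)

PROFILES = ("null", "structured_confounded", "causal_marker", "causal_gem", "flc_like")


@dataclass
class SynthTruth:
    """Ground truth behind a synthetic panel."""

    k_true: int
    q_true: pd.DataFrame          # accessions x K, rows sum to 1
    f_divergence: float           # Balding-Nichols F (shared across clusters)
    pop_effects: np.ndarray       # per-cluster additive trait effect (days)
    sigma: float                  # trait noise sd (days)
    seed: int
    causal_marker: str | None = None
    beta: float = 0.0             # effect per minor-allele dose
    causal_gene: str | None = None
    gamma: float = 0.0            # effect per RPKM unit
    zero_expression_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        arr = self.q_true.to_numpy(dtype=float)
        if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("q_true rows must sum to 1")

    @property
    def accessions(self) -> list[str]:
        return list(self.q_true.index)


def make_truth(
    n_accessions: int = 69,
    k: int = 4,
    f: float = 0.3,
    admix_alpha: float = 0.15,
    pop_effects=None,
    sigma: float = 10.0,
    seed: int = 0,
) -> SynthTruth:
    """Draw panel-level ground truth.

    Each line belongs to one cluster and carries an admixed ancestry fraction
    with mean ~ ``admix_alpha``, giving mostly-pure lines with occasional
    admixture, as in a crop panel of distinct fixed types. ``f`` is the
    Balding-Nichols divergence of every cluster.
    """
    if not (0.0 < f < 1.0):
        raise ValueError("divergence F must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    acc = [f"ACC{i+1:03d}" for i in range(n_accessions)]
    if k == 1:
        q = np.ones((n_accessions, 1))
    else:
        # every cluster represented; lines mostly pure (fixed crop types) with
        # an admixed fraction m_i of mean ~ admix_alpha per line
        base = np.repeat(np.arange(k), int(np.ceil(n_accessions / k)))[:n_accessions]
        rng.shuffle(base)
        m = rng.beta(1.0, 1.0 / admix_alpha, size=n_accessions)
        mix = rng.dirichlet([1.0] * k, size=n_accessions)
        q = np.zeros((n_accessions, k))
        q[np.arange(n_accessions), base] = 1.0
        q = (1.0 - m)[:, None] * q + m[:, None] * mix
    qdf = pd.DataFrame(q, index=pd.Index(acc, name="accession_id"),
                       columns=[f"Q{i+1}" for i in range(k)])
    effects = np.zeros(k) if pop_effects is None else np.asarray(pop_effects, dtype=float)
    return SynthTruth(
        k_true=k, q_true=qdf, f_divergence=f, pop_effects=effects, sigma=sigma, seed=int(seed)
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    truth: SynthTruth,
    n_markers: int = 500,
    n_genes: int | None = None,
    missing_rate: float = 0.03,
    ambiguity_rate: float = 0.02,
) -> tuple[MarkerTable, AnnotationTable]:
    """Balding-Nichols genotypes for the panel.

    Ancestral allele frequencies are Uniform(0.05, 0.95); cluster frequencies
    are Beta-distributed around them with divergence F; each accession's
    allele frequency is the ancestry-weighted mixture. Doubled-haploid calls
    are produced by drawing one allele and writing it homozygous; a small
    fraction of calls is replaced by the IUPAC mixed-base code of the two
    marker alleles (hemi-SNPs) or by N (missing). Markers are spread over
    genes (>= 1 per gene) with within-gene positions that exercise the
    pruning rules, and an annotation table with genomic gene starts is
    returned alongside.
    """
    if not (0.0 <= missing_rate < 1.0 and 0.0 <= ambiguity_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    f = truth.f_divergence
    if not (0.0 < f < 1.0):
        raise ValueError("divergence F must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 23]))
    n = len(truth.accessions)
    k = truth.k_true
    if n_genes is None:
        n_genes = max(1, n_markers // 3)
    n_genes = min(n_genes, n_markers)

    # marker -> gene assignment, every gene covered
    gene_of = np.concatenate([
        np.arange(n_genes), rng.integers(0, n_genes, size=n_markers - n_genes)
    ])
    gene_of.sort()

    chrom_of_gene = np.array([f"C{(g % 9) + 1:02d}" for g in range(n_genes)])
    gene_names = np.array([f"BoSg{g+1:06d}.1" for g in range(n_genes)])

    p_anc = rng.uniform(0.05, 0.95, size=n_markers)
    shape1 = p_anc * (1.0 - f) / f
    shape2 = (1.0 - p_anc) * (1.0 - f) / f
    p_clust = rng.beta(shape1, shape2, size=(k, n_markers))  # alt-allele freq per cluster
    q = truth.q_true.to_numpy(dtype=float)
    p_acc = q @ p_clust  # n x m mixture frequency of the alt allele

    # alleles per marker: distinct ref/alt nucleotides
    nucs = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_markers)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_markers)) % 4
    ref, alt = nucs[ref_idx], nucs[alt_idx]

    draw_alt = rng.random((n, n_markers)) < p_acc
    calls = np.where(draw_alt, alt[None, :], ref[None, :]).astype("<U1")
    amb = rng.random((n, n_markers)) < ambiguity_rate
    het_codes = np.array([PAIR_TO_CODE[frozenset((r, a))] for r, a in zip(ref, alt)])
    calls[amb] = np.broadcast_to(het_codes, (n, n_markers))[amb]
    miss = rng.random((n, n_markers)) < missing_rate
    calls[miss] = "N"

    # within-gene positions: sampled without replacement so some pairs fall
    # inside and some outside the 500-bp pruning distance
    positions = np.empty(n_markers, dtype=int)
    for g in range(n_genes):
        idx = np.where(gene_of == g)[0]
        pos = rng.choice(np.arange(1, 3001), size=len(idx), replace=False)
        positions[idx] = np.sort(pos)

    marker_ids, rows = [], []
    for j in range(n_markers):
        g = gene_of[j]
        state = alt[j]
        marker_ids.append(f"{gene_names[g]}:{positions[j]}:{state}")
        observed = sorted(set(calls[:, j]) - {"N"})
        rows.append(
            {
                "gene_id": gene_names[g],
                "chromosome": chrom_of_gene[g],
                "position": int(positions[j]),
                "allele_states": "/".join(observed),
            }
        )
    meta = pd.DataFrame(rows, index=pd.Index(marker_ids, name="marker_id"))
    meta["order_index"] = meta.groupby("chromosome").cumcount() + 1
    calls_df = pd.DataFrame(
        calls.T, index=meta.index, columns=truth.accessions
    )
    table = MarkerTable(meta, calls_df)

    gene_rank = pd.Series(range(n_genes)).groupby(pd.Series(chrom_of_gene)).cumcount().to_numpy()
    ann = pd.DataFrame(
        {
            "chromosome": chrom_of_gene,
            "order_index": gene_rank + 1,
            "start": gene_rank * 50_000 + 1,
            "end": gene_rank * 50_000 + 3000,
        },
        index=pd.Index(gene_names, name="gene_id"),
    )
    return table, AnnotationTable(ann)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: SynthTruth,
    n_genes: int = 200,
    gene_ids: list[str] | None = None,
    cluster_shifts: dict[str, np.ndarray] | None = None,
    log_mu: float = np.log(10.0),
    log_sd_gene: float = 1.0,
    log_sd_noise: float = 0.5,
) -> ExpressionMatrix:
    """Log-normal RPKM, genes x accessions.

    Each gene has a baseline log level; designated genes get per-cluster
    shifts on the log scale weighted by true ancestry; accessions listed in
    the truth's ``zero_expression_accessions`` have the causal gene set to
    exactly 0 (the no-expression extreme).
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 37]))
    if gene_ids is None:
        gene_ids = [f"BoSg{g+1:06d}.1" for g in range(n_genes)]
    n = len(truth.accessions)
    q = truth.q_true.to_numpy(dtype=float)
    base = rng.normal(log_mu, log_sd_gene, size=len(gene_ids))
    logv = base[:, None] + rng.normal(0.0, log_sd_noise, size=(len(gene_ids), n))
    if cluster_shifts:
        for gene, shift in cluster_shifts.items():
            gi = gene_ids.index(gene)
            logv[gi] += q @ np.asarray(shift, dtype=float)
    rpkm = np.exp(logv)
    df = pd.DataFrame(rpkm, index=pd.Index(gene_ids, name="gene_id"), columns=truth.accessions)
    if truth.causal_gene is not None and truth.zero_expression_accessions:
        df.loc[truth.causal_gene, list(truth.zero_expression_accessions)] = 0.0
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(
    truth: SynthTruth,
    geno: MarkerTable | None = None,
    expr: ExpressionMatrix | None = None,
    trait_names: tuple[str, ...] = ("NV DTB", "NV DTF"),
) -> PhenotypeTable:
    """Traits = population effect + beta * causal dosage + gamma * causal RPKM + noise.

    Each named trait gets an independent noise draw (distinct sub-seed);
    missing causal dosages are imputed to the panel mean so the causal signal
    is defined for every accession.
    """
    from .association import encode_dosage

    n = len(truth.accessions)
    q = truth.q_true.to_numpy(dtype=float)
    signal = q @ truth.pop_effects
    if truth.causal_marker is not None:
        if geno is None:
            raise ValueError("causal marker set but no genotypes supplied")
        d = encode_dosage(geno, truth.causal_marker)
        d = np.where(np.isnan(d), np.nanmean(d), d)
        signal = signal + truth.beta * d
    if truth.causal_gene is not None and truth.gamma != 0.0:
        if expr is None:
            raise ValueError("causal gene set but no expression supplied")
        signal = signal + truth.gamma * expr.rpkm.loc[truth.causal_gene].to_numpy(dtype=float)
    cols = {}
    for t, name in enumerate(trait_names):
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 53, t]))
        cols[name] = signal + rng.normal(0.0, truth.sigma, size=n)
    values = pd.DataFrame(cols, index=truth.q_true.index)
    return PhenotypeTable(values)


# ---------------------------------------------------------------------------
# profiles and fixture bundles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanel:
    truth: SynthTruth
    geno: MarkerTable
    annotation: AnnotationTable
    expr: ExpressionMatrix
    pheno: PhenotypeTable


def _pick_causal_marker(geno: MarkerTable, rng: np.random.Generator) -> str:
    """A common biallelic marker, so the causal signal is well powered."""
    from .qc import marker_stats_table

    stats = marker_stats_table(geno)
    good = stats[(stats["is_biallelic"]) & (stats["maf"] > 0.2) & (stats["missing_fraction"] < 0.1)]
    if good.empty:
        good = stats[stats["is_biallelic"]]
    return str(good.index[rng.integers(0, len(good))])


def make_panel(profile: str, seed: int = 0) -> SyntheticPanel:
    """Build one of the named study-condition profiles.

    - ``null``: unstructured panel of 69 lines, 1000 markers, trait is pure
      noise (type-I error checks).
    - ``structured_confounded``: 90 lines in 3 diverged clusters (F = 0.3),
      200 markers, trait driven by population membership only (inflation and
      structure-correction checks).
    - ``causal_marker``: as above plus one causal marker whose effect size is
      set to explain 25 % of the trait variance.
    - ``causal_gem``: 69 lines, one causal gene with slope 1.5 days per RPKM
      and unit noise (GEM recovery checks).
    - ``flc_like``: 69 lines where 5 accessions have exactly zero expression
      of the causal gene; the expression-trait correlation is strong at the
      phenotypic extremes and weak panel-wide.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 71]))
    if profile == "null":
        truth = make_truth(n_accessions=69, k=1, f=0.3, sigma=10.0, seed=seed)
        geno, ann = simulate_genotypes(truth, n_markers=1000)
        expr = simulate_expression(truth, n_genes=100)
        pheno = simulate_traits(truth, geno, expr)
    elif profile == "structured_confounded":
        truth = make_truth(
            n_accessions=90, k=3, f=0.3, pop_effects=[-15.0, 0.0, 15.0], sigma=10.0, seed=seed
        )
        geno, ann = simulate_genotypes(truth, n_markers=200)
        expr = simulate_expression(truth, n_genes=50)
        pheno = simulate_traits(truth, geno, expr)
    elif profile == "causal_marker":
        truth = make_truth(
            n_accessions=90, k=3, f=0.3, pop_effects=[-10.0, 0.0, 10.0], sigma=10.0, seed=seed
        )
        geno, ann = simulate_genotypes(truth, n_markers=500)
        truth.causal_marker = _pick_causal_marker(geno, rng)
        truth.beta = _beta_for_variance_fraction(truth, geno, fraction=0.25)
        expr = simulate_expression(truth, n_genes=100)
        pheno = simulate_traits(truth, geno, expr)
    elif profile == "causal_gem":
        truth = make_truth(n_accessions=69, k=1, f=0.3, sigma=1.0, seed=seed)
        geno, ann = simulate_genotypes(truth, n_markers=200)
        truth.causal_gene = "BoSg000001.1"
        truth.gamma = 1.5
        expr = simulate_expression(truth, n_genes=100)
        pheno = simulate_traits(truth, geno, expr)
    elif profile == "flc_like":
        truth = make_truth(
            n_accessions=69, k=4, f=0.3, pop_effects=[-8.0, 0.0, 8.0, 4.0], sigma=15.0, seed=seed
        )
        geno, ann = simulate_genotypes(truth, n_markers=300)
        truth.causal_gene = "BoSg000001.1"
        # the five "rapid-cycling" lines: zero expression, early flowering
        truth.zero_expression_accessions = tuple(truth.accessions[:5])
        # late-flowering cluster expresses the gene strongly (log-scale shift),
        # giving the zero-vs-high bimodality seen for vernalisation-pathway genes
        expr = simulate_expression(
            truth, n_genes=100, cluster_shifts={truth.causal_gene: np.array([0.0, 0.0, 0.0, 2.0])}
        )
        # expression effect sized below the noise sd panel-wide, so the whole-panel
        # correlation stays weak while the zero/high extremes correlate strongly
        x = expr.rpkm.loc[truth.causal_gene].to_numpy(dtype=float)
        truth.gamma = float(0.8 * truth.sigma / x.std())
        pheno = simulate_traits(truth, geno, expr)
    else:
        raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")
    return SyntheticPanel(truth, geno, ann, expr, pheno)


def _beta_for_variance_fraction(truth: SynthTruth, geno: MarkerTable, fraction: float) -> float:
    """Effect size so the causal marker explains the given trait-variance fraction."""
    from .association import encode_dosage

    d = encode_dosage(geno, truth.causal_marker)
    d = np.where(np.isnan(d), np.nanmean(d), d)
    q = truth.q_true.to_numpy(dtype=float)
    var_other = float(np.var(q @ truth.pop_effects)) + truth.sigma ** 2
    var_d = float(np.var(d))
    return float(np.sqrt(fraction / (1.0 - fraction) * var_other / var_d))


# ---------------------------------------------------------------------------
# truth file round-trip
# ---------------------------------------------------------------------------

def write_truth(truth: SynthTruth, path) -> None:
    """Key-value TSV with one section per truth component."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("section\tkey\tvalue\n")
        scalars = {
            "k_true": truth.k_true,
            "f_divergence": truth.f_divergence,
            "sigma": truth.sigma,
            "seed": truth.seed,
            "causal_marker": truth.causal_marker or "",
            "beta": truth.beta,
            "causal_gene": truth.causal_gene or "",
            "gamma": truth.gamma,
            "zero_expression_accessions": ",".join(truth.zero_expression_accessions),
        }
        for k, v in scalars.items():
            fh.write(f"scalar\t{k}\t{v}\n")
        for i, e in enumerate(truth.pop_effects):
            fh.write(f"pop_effect\tcluster{i+1}\t{float(e)!r}\n")
        for acc, row in truth.q_true.iterrows():
            fh.write(f"ancestry\t{acc}\t{','.join(repr(float(v)) for v in row)}\n")


def read_truth(path) -> SynthTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    scal = dict(zip(df[df["section"] == "scalar"]["key"], df[df["section"] == "scalar"]["value"]))
    pop = df[df["section"] == "pop_effect"]["value"].astype(float).to_numpy()
    anc = df[df["section"] == "ancestry"]
    q = pd.DataFrame(
        [list(map(float, v.split(","))) for v in anc["value"]],
        index=pd.Index(anc["key"].to_numpy(), name="accession_id"),
    )
    q.columns = [f"Q{i+1}" for i in range(q.shape[1])]
    zero = tuple(a for a in scal["zero_expression_accessions"].split(",") if a)
    return SynthTruth(
        k_true=int(scal["k_true"]),
        q_true=q,
        f_divergence=float(scal["f_divergence"]),
        pop_effects=pop,
        sigma=float(scal["sigma"]),
        seed=int(scal["seed"]),
        causal_marker=scal["causal_marker"] or None,
        beta=float(scal["beta"]),
        causal_gene=scal["causal_gene"] or None,
        gamma=float(scal["gamma"]),
        zero_expression_accessions=zero,
    )


def generate_fixture_bundle(profile: str, out_dir, seed: int = 0) -> dict[str, Path]:
    """Write a profile's marker/expression/phenotype/annotation/truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = make_panel(profile, seed=seed)
    paths = {
        "markers": out / "markers.tsv",
        "expression": out / "expression.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.tsv",
    }
    write_marker_table(panel.geno, paths["markers"])
    write_expression(panel.expr, paths["expression"])
    write_phenotypes(panel.pheno, paths["phenotypes"])
    write_annotation(panel.annotation, paths["annotation"])
    write_truth(panel.truth, paths["truth"])
    return paths
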