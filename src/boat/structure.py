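"""Population-structure inference for fixed-line panels.

The centrepiece is a Gibbs sampler for the Bayesian admixture model with
uncorrelated allele frequencies: each accession i has ancestry proportions
q_i ~ Dirichlet(alpha, ..., alpha), each cluster k has allele frequencies
p_kl ~ Dirichlet(lambda, ..., lambda) per marker l, and every observed allele
copy originates from cluster k with probability q_ik and then carries allele
a with probability p_kla. For a doubled-haploid/fixed panel a homozygous call
contributes two identical allele copies, a mixed-base (hemi-SNP) call one
copy of each constituent allele, and a missing call none.

The module also provides the Evanno delta-K table for choosing K, exact
permutation alignment of replicate Q matrices (label switching), PCA
covariates, identity-by-state neighbour-joining trees, and hard cluster
assignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import AMBIGUITY, MISSING, MarkerTable, QMatrix
from .qc import marker_stats_table

__all__ = [
    "AdmixtureGibbs",
    "StructureRun",
    "run_structure_gibbs",
    "structure_replicates",
    "evanno_delta_k",
    "align_q_matrices",
    "pca_covariates",
    "nj_tree",
    "assign_subpopulation",
]


# ---------------------------------------------------------------------------
# genotype -> allele-copy representation
# ---------------------------------------------------------------------------

def _allele_copies(table: MarkerTable):
    """Flatten calls into per-allele-copy arrays (accession, marker, allele idx).

    Markers must have at most two underlying alleles; each marker's alleles
    are indexed 0/1 in alphabetical order.
    """
    arr = table.calls.to_numpy(dtype="<U1")  # markers x accessions
    m, n = arr.shape
    acc_idx, mk_idx, al_idx = [], [], []
    marker_alleles = []
    for l in range(m):
        alleles = set()
        for c in set(arr[l]):
            if c == MISSING:
                continue
            alleles.update(AMBIGUITY.get(c, (c,)))
        alleles = sorted(alleles)
        if len(alleles) > 2:
            raise ValueError(
                f"marker {table.meta.index[l]!r} has {len(alleles)} underlying alleles; "
                "prune to biallelic markers first"
            )
        if len(alleles) == 0:
            alleles = ["A"]  # all-missing marker; contributes no copies
        marker_alleles.append(alleles)
        lookup = {a: i for i, a in enumerate(alleles)}
        for j in range(n):
            c = arr[l, j]
            if c == MISSING:
                continue
            for a in AMBIGUITY.get(c, (c, c)):
                acc_idx.append(j)
                mk_idx.append(l)
                al_idx.append(lookup[a])
    return (
        np.asarray(acc_idx, dtype=np.int64),
        np.asarray(mk_idx, dtype=np.int64),
        np.asarray(al_idx, dtype=np.int64),
        marker_alleles,
    )


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class AdmixtureGibbs:
    """Admixture-model Gibbs sampler (uncorrelated allele frequencies).

    sklearn-style estimator: configure in ``__init__``, run with ``fit``,
    read posterior means from trailing-underscore attributes.

    Parameters
    ----------
    n_populations : K, number of ancestral clusters (>= 1).
    burnin, n_sweeps : discarded and retained Gibbs sweeps.
    alpha_init : initial value of the symmetric Dirichlet ancestry
        concentration; inferred by a Metropolis random walk (step
        ``alpha_step``, uniform prior on (0, ``alpha_max``)) unless
        ``infer_alpha`` is False.
    freq_lambda : Dirichlet prior parameter for cluster allele frequencies.
    seed : integer seed; runs are bit-reproducible.

    Attributes (after fit)
    ----------------------
    q_mean_ : (n_accessions, K) posterior-mean ancestry proportions.
    p_mean_ : (K, n_markers, 2) posterior-mean allele frequencies.
    lnpd_ : model evidence estimate, mean(lnL) - var(lnL)/2 over retained sweeps.
    alpha_trace_ : alpha value at each retained sweep.
    loglik_trace_ : data log-likelihood at each retained sweep.
    """

    def __init__(
        self,
        n_populations: int = 2,
        burnin: int = 10000,
        n_sweeps: int = 10000,
        alpha_init: float = 1.0,
        alpha_step: float = 0.05,
        alpha_max: float = 10.0,
        infer_alpha: bool = True,
        freq_lambda: float = 1.0,
        seed: int | None = None,
    ):
        self.n_populations = n_populations
        self.burnin = burnin
        self.n_sweeps = n_sweeps
        self.alpha_init = alpha_init
        self.alpha_step = alpha_step
        self.alpha_max = alpha_max
        self.infer_alpha = infer_alpha
        self.freq_lambda = freq_lambda
        self.seed = seed

    # minimal get/set_params so the class composes with sklearn utilities
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_populations", "burnin", "n_sweeps", "alpha_init", "alpha_step",
                "alpha_max", "infer_alpha", "freq_lambda", "seed",
            )
        }

    def set_params(self, **params) -> "AdmixtureGibbs":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: MarkerTable) -> "AdmixtureGibbs":
        K = int(self.n_populations)
        if K < 1:
            raise ValueError("n_populations must be >= 1")
        if X.n_markers == 0:
            raise ValueError("no markers to fit on")
        n, m = X.n_accessions, X.n_markers
        acc, mk, al, _ = _allele_copies(X)
        ncopies = len(acc)
        rng = np.random.default_rng(self.seed)

        lam = float(self.freq_lambda)
        alpha = float(self.alpha_init)
        # flat index for P counts: (k, marker, allele)
        p_flat = mk * 2 + al

        # initialise from the prior: uniform ancestry, assignments drawn from
        # it, frequencies from their conditional, so no cluster starts empty
        q = np.full((n, K), 1.0 / K)
        z0 = rng.integers(0, K, size=ncopies)
        cnt_p0 = np.bincount(z0 * (2 * m) + p_flat, minlength=K * 2 * m).reshape(K, m, 2)
        g0 = rng.gamma(lam + cnt_p0)
        p = g0 / g0.sum(axis=2, keepdims=True)

        q_sum = np.zeros((n, K))
        p_sum = np.zeros((K, m, 2))
        lnl_trace: list[float] = []
        alpha_trace: list[float] = []

        total = self.burnin + self.n_sweeps
        for sweep in range(total):
            # P(z=k | copy) ~ q[i,k] * p[k,l,a]
            probs = q[acc] * p[:, mk, al].T  # (ncopies, K)
            tot = probs.sum(axis=1)
            lnl = float(np.log(tot).sum())
            if K == 1:
                z = np.zeros(ncopies, dtype=np.int64)
            else:
                cs = np.cumsum(probs, axis=1)
                r = rng.random(ncopies) * tot
                z = (cs < r[:, None]).sum(axis=1)
                np.clip(z, 0, K - 1, out=z)

            # update P | Z : Dirichlet(lambda + counts) per (k, marker)
            cnt_p = np.bincount(z * (2 * m) + p_flat, minlength=K * 2 * m).reshape(K, m, 2)
            g = rng.gamma(lam + cnt_p)
            p = g / g.sum(axis=2, keepdims=True)

            # update Q | Z : Dirichlet(alpha + counts) per accession
            cnt_q = np.bincount(acc * K + z, minlength=n * K).reshape(n, K)
            g = rng.gamma(alpha + cnt_q)
            q = g / g.sum(axis=1, keepdims=True)
            np.clip(q, 1e-300, None, out=q)

            # update alpha | Q by a Metropolis random walk
            if self.infer_alpha and K > 1:
                prop = alpha + rng.normal(0.0, self.alpha_step)
                if 0.0 < prop < self.alpha_max:
                    s_logq = float(np.log(q).sum())
                    delta = (
                        n * (gammaln(K * prop) - K * gammaln(prop))
                        - n * (gammaln(K * alpha) - K * gammaln(alpha))
                        + (prop - alpha) * s_logq
                    )
                    if math.log(rng.random()) < delta:
                        alpha = prop

            if sweep >= self.burnin:
                q_sum += q
                p_sum += p
                lnl_trace.append(lnl)
                alpha_trace.append(alpha)

        self.q_mean_ = q_sum / self.n_sweeps
        self.p_mean_ = p_sum / self.n_sweeps
        lnl_arr = np.asarray(lnl_trace)
        self.loglik_trace_ = lnl_arr
        self.alpha_trace_ = np.asarray(alpha_trace)
        self.lnpd_ = float(lnl_arr.mean() - lnl_arr.var(ddof=0) / 2.0)
        self.accessions_ = list(X.accessions)
        self.n_features_in_ = m
        return self

    def predict(self, X: MarkerTable | None = None) -> np.ndarray:
        """Hard cluster labels (1-based) by maximum posterior-mean ancestry."""
        if not hasattr(self, "q_mean_"):
            raise RuntimeError("fit the sampler first")
        return np.argmax(self.q_mean_, axis=1) + 1


@dataclass
class StructureRun:
    """One admixture-sampler run at a given K."""

    k: int
    q_mean: QMatrix
    p_mean: np.ndarray
    lnpd: float
    alpha_trace: np.ndarray
    seed: int | None
    burnin: int
    mcmc_reps: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def run_structure_gibbs(
    geno: MarkerTable,
    k: int,
    burnin: int = 10000,
    mcmc: int = 10000,
    seed: int | None = None,
    **kwargs,
) -> StructureRun:
    """Fit the admixture Gibbs sampler and package the posterior means."""
    model = AdmixtureGibbs(
        n_populations=k, burnin=burnin, n_sweeps=mcmc, seed=seed, **kwargs
    ).fit(geno)
    qdf = pd.DataFrame(
        model.q_mean_,
        index=pd.Index(geno.accessions, name="accession_id"),
        columns=[f"Q{i+1}" for i in range(k)],
    )
    qdf = qdf.div(qdf.sum(axis=1), axis=0)
    return StructureRun(
        k=k,
        q_mean=QMatrix(qdf),
        p_mean=model.p_mean_,
        lnpd=model.lnpd_,
        alpha_trace=model.alpha_trace_,
        seed=seed,
        burnin=burnin,
        mcmc_reps=mcmc,
        loglik_trace=model.loglik_trace_,
    )


def structure_replicates(
    geno: MarkerTable,
    k_range,
    replicates: int = 10,
    burnin: int = 10000,
    mcmc: int = 10000,
    seed: int = 0,
    **kwargs,
) -> dict[int, list[StructureRun]]:
    """Replicate runs across a K range; replicate r uses seed + r."""
    runs: dict[int, list[StructureRun]] = {}
    for k in k_range:
        runs[k] = [
            run_structure_gibbs(geno, k, burnin=burnin, mcmc=mcmc, seed=seed + r, **kwargs)
            for r in range(replicates)
        ]
    return runs


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(runs: dict[int, list[StructureRun]]) -> pd.DataFrame:
    """Evanno table from replicate runs grouped by K.

    L'(K) = mean L(K) - mean L(K-1); |L''(K)| = |L'(K+1) - L'(K)|;
    delta_K = |L''(K)| / sd L(K). Boundary Ks (and sd = 0) yield NaN.
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError(f"need >= 2 replicates per K (K={k} has {len(runs[k])})")
    mean_l = {k: float(np.mean([r.lnpd for r in runs[k]])) for k in ks}
    sd_l = {k: float(np.std([r.lnpd for r in runs[k]], ddof=1)) for k in ks}
    lprime = {k: mean_l[k] - mean_l[k - 1] for k in ks[1:]}
    lsecond = {k: abs(lprime[k + 1] - lprime[k]) for k in ks[1:-1]}
    rows = []
    for k in ks:
        dk = np.nan
        if k in lsecond and sd_l[k] > 0:
            dk = lsecond[k] / sd_l[k]
        rows.append(
            {
                "K": k,
                "mean_lnpd": mean_l[k],
                "sd_lnpd": sd_l[k],
                "l_prime": lprime.get(k, np.nan),
                "abs_l_second": lsecond.get(k, np.nan),
                "delta_k": dk,
            }
        )
    return pd.DataFrame(rows).set_index("K")


def best_k(evanno: pd.DataFrame) -> int:
    """K with maximal delta_K among the defined entries."""
    defined = evanno["delta_k"].dropna()
    if defined.empty:
        raise ValueError("delta_K undefined for every K")
    return int(defined.idxmax())


# ---------------------------------------------------------------------------
# replicate alignment (label switching)
# ---------------------------------------------------------------------------

def align_q_matrices(qs: list[QMatrix]) -> QMatrix:
    """Consensus Q over replicates by exact column-permutation alignment.

    Each replicate's columns are permuted to maximise the sum over accessions
    of dot products with the running mean of already-aligned replicates
    (exact search over K! permutations, K <= 8); the element-wise mean of the
    aligned replicates, rows renormalised, is returned.
    """
    if not qs:
        raise ValueError("no Q matrices to align")
    k = qs[0].k
    if any(q.k != k for q in qs) or any(q.proportions.shape != qs[0].proportions.shape for q in qs):
        raise ValueError("replicate Q matrices have mixed shapes or K")
    if k > 8:
        raise ValueError("exact permutation alignment supports K <= 8")
    ref = qs[0].to_array().copy()
    acc_sum = ref.copy()
    for q in qs[1:]:
        arr = q.to_array()
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(k)):
            score = float(np.sum(acc_sum / len(qs) * arr[:, perm]))
            if score > best_score:
                best_score, best_perm = score, perm
        acc_sum += arr[:, best_perm]
    mean = acc_sum / len(qs)
    mean = mean / mean.sum(axis=1, keepdims=True)
    out = pd.DataFrame(mean, index=qs[0].proportions.index, columns=qs[0].proportions.columns)
    return QMatrix(out)


def consensus_q(runs: list[StructureRun]) -> QMatrix:
    return align_q_matrices([r.q_mean for r in runs])


# ---------------------------------------------------------------------------
# PCA covariates
# ---------------------------------------------------------------------------

def pca_covariates(geno: MarkerTable, n_pcs: int = 5) -> pd.DataFrame:
    """Principal-component scores of the column-centred dosage matrix.

    Missing dosages are imputed to the marker mean; markers with more than
    two underlying alleles or no variation contribute nothing. Scores are
    ordered by explained variance.
    """
    from .association import dosage_matrix

    n = geno.n_accessions
    if n_pcs >= n:
        raise ValueError(f"n_pcs={n_pcs} must be smaller than the panel size {n}")
    X, _ = dosage_matrix(geno)
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X = X.copy()
    X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    # sign convention: largest-magnitude loading positive, for determinism
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores,
        index=pd.Index(geno.accessions, name="accession_id"),
        columns=[f"PC{i+1}" for i in range(n_pcs)],
    )


# ---------------------------------------------------------------------------
# neighbour-joining validation tree
# ---------------------------------------------------------------------------

_CALL_ALLELES = {c: (c, c) for c in "ACGT"} | dict(AMBIGUITY)


def ibs_distance_matrix(geno: MarkerTable) -> pd.DataFrame:
    """Pairwise 1 - IBS distances.

    IBS between two calls is the shared fraction of allele copies: identical
    homozygotes 1, ambiguity vs a constituent homozygote 0.5, identical
    ambiguity codes 1, disjoint calls 0. Pairs are averaged over co-observed
    markers; a pair with none raises.
    """
    chars = sorted(_CALL_ALLELES) + [MISSING]
    code = {c: i for i, c in enumerate(chars)}
    lut = np.zeros((len(chars), len(chars)))
    for a, ca in _CALL_ALLELES.items():
        for b, cb in _CALL_ALLELES.items():
            shared = len(set(ca) & set(cb))
            if ca == cb:
                sim = 1.0
            elif shared:
                sim = 0.5
            else:
                sim = 0.0
            lut[code[a], code[b]] = sim
    arr = geno.call_matrix()  # accessions x markers
    enc = np.zeros(arr.shape, dtype=np.int64)
    for c, i in code.items():
        enc[arr == c] = i
    obs = arr != MISSING
    n = geno.n_accessions
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            if not both.any():
                raise ValueError(
                    f"accessions {geno.accessions[i]!r} and {geno.accessions[j]!r} "
                    "share no co-observed markers"
                )
            sim = lut[enc[i, both], enc[j, both]].mean()
            dist[i, j] = dist[j, i] = 1.0 - sim
    return pd.DataFrame(dist, index=geno.accessions, columns=geno.accessions)


def nj_tree(geno: MarkerTable, min_maf: float = 0.05) -> str:
    """Neighbour-joining Newick tree on 1 - IBS distances (MAF-filtered markers).

    Negative branch lengths are clamped to zero. Ties are resolved by
    accession order, so the result is deterministic.
    """
    from io import StringIO

    from skbio import DistanceMatrix
    from skbio.tree import nj

    if geno.n_accessions < 3:
        raise ValueError("need at least 3 accessions for a tree")
    stats = marker_stats_table(geno)
    keep = stats.index[stats["maf"].fillna(0) > min_maf]
    sub = geno.subset(keep) if len(keep) else geno
    dist = ibs_distance_matrix(sub)
    dm = DistanceMatrix(dist.to_numpy(), ids=list(dist.index))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# hard assignment
# ---------------------------------------------------------------------------

def assign_subpopulation(q: QMatrix) -> pd.Series:
    """1-based cluster label per accession: argmax ancestry, ties to the lowest index."""
    arr = q.to_array()
    labels = np.argmax(arr, axis=1) + 1
    return pd.Series(labels, index=q.proportions.index, name="cluster")
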