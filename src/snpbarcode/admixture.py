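"""Maximum-likelihood admixture model, Evanno ΔK, and hybrid calling.

The model is the classic admixture likelihood for unlinked biallelic
SNPs: individual i draws each of its two allele copies at SNP l from
ancestral cluster k with probability q_ik, and the copy is the
diagnostic allele with probability p_kl.  The log-likelihood

    L = sum_i sum_l [ x_il log sum_k q_ik p_kl
                      + (2 - x_il) log sum_k q_ik (1 - p_kl) ]

(x_il = diagnostic-allele dosage, missing calls skipped) is maximized
by EM with multiplicative updates for Q and P; the EM ascent is
monotone.  Cluster allele frequencies are modelled as independent
between clusters, and no population labels enter the fit.  This is a
point-estimate stand-in for MCMC samplers of the same likelihood: for
diagnostic panels with (nearly) fixed inter-species differences the
posterior is sharply peaked and the MLE carries the same information.

The number of clusters is chosen with the ΔK second-difference
statistic computed over replicate fits per K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeMatrix, HybridCall

ADMIX_THRESHOLD = 0.05
_P_EPS = 1e-9


@dataclass
class AdmixtureFit:
    """One EM fit: ancestry matrix Q (n x K) and cluster frequencies P (K x L)."""

    K: int
    Q: np.ndarray
    P: np.ndarray
    loglik: float
    individuals: list[str]
    snp_ids: list[str]
    loglik_path: np.ndarray = field(repr=False, default=None)
    lambda_: float = 1.0  # Dirichlet prior weight, metadata only (flat default)
    seed: int = 0
    replicate: int = 0
    n_iter: int = 0
    converged: bool = True

    def q_dataframe(self, cluster_names=None) -> pd.DataFrame:
        cols = cluster_names if cluster_names is not None else [
            f"cluster{k + 1}" for k in range(self.K)
        ]
        return pd.DataFrame(self.Q, index=self.individuals, columns=cols)


def dosage_matrix(G: GenotypeMatrix, ref_alleles: dict[str, str] | None = None):
    """Diagnostic-allele dosage matrix with monomorphic SNPs dropped.

    When ``ref_alleles`` is omitted, the lexically-first observed allele
    of each SNP is counted; the choice only relabels P columns.
    Returns ``(X, kept_snp_ids)`` with NaN marking missing calls.
    """
    if ref_alleles is None:
        ref_alleles = {}
        for snp in G.snp_ids:
            alleles = G.alleles_of(snp)
            ref_alleles[snp] = alleles[0] if alleles else "A"
    X = G.dosage(ref_alleles)
    keep = []
    for j, snp in enumerate(G.snp_ids):
        col = X[:, j]
        vals = col[~np.isnan(col)]
        if vals.size and not (vals == vals[0]).all():
            keep.append(j)
    dropped = len(G.snp_ids) - len(keep)
    if dropped:
        warnings.warn(f"dropping {dropped} monomorphic/empty SNP(s)", stacklevel=2)
    return X[:, keep], [G.snp_ids[j] for j in keep]


def _em_once(X, K, rng, tol, max_iter):
    n, L = X.shape
    miss = np.isnan(X)
    x = np.where(miss, 0.0, X)          # diagnostic copies
    y = np.where(miss, 0.0, 2.0 - X)    # other copies
    copies_per_ind = (x + y).sum(axis=1)  # 2 * non-missing SNPs

    Q = rng.dirichlet(np.ones(K), size=n)
    P = rng.uniform(0.05, 0.95, size=(K, L))
    path = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        f_ref = Q @ P                     # n x L, P(copy = diagnostic)
        f_alt = Q @ (1.0 - P)
        f_ref = np.maximum(f_ref, _P_EPS)
        f_alt = np.maximum(f_alt, _P_EPS)
        ll = float((x * np.log(f_ref) + y * np.log(f_alt)).sum())
        path.append(ll)
        if ll - prev < tol and it > 0:
            converged = True
            break
        prev = ll
        # E-step responsibilities folded into the M-step sums; the
        # n x K x L responsibility tensor reduces to matrix products:
        #   sum_l r_ref[i,k,l] = q_ik * (A @ P.T)[i,k],  A = x / f_ref
        A = x / f_ref                     # n x L
        B = y / f_alt
        ref_q = Q * (A @ P.T)             # n x K, expected diagnostic copies
        alt_q = Q * (B @ (1.0 - P).T)
        Qn = (ref_q + alt_q) / np.maximum(copies_per_ind, 1)[:, None]
        empty = copies_per_ind == 0  # all-missing individuals stay uniform
        if empty.any():
            Qn[empty] = 1.0 / K
        num = P * (Q.T @ A)               # K x L, expected diagnostic copies
        den = num + (1.0 - P) * (Q.T @ B)
        Q = Qn / Qn.sum(axis=1, keepdims=True)
        P = np.clip(num / np.maximum(den, _P_EPS), _P_EPS, 1.0 - _P_EPS)
    return Q, P, path[-1], np.array(path), it + 1, converged


def admixture_em(G: GenotypeMatrix, K: int, seed: int = 0, *,
                 n_restarts: int = 5, tol: float = 1e-6,
                 max_iter: int = 2000,
                 ref_alleles: dict[str, str] | None = None,
                 replicate: int = 0) -> AdmixtureFit:
    """Fit the admixture model by EM, returning the best of ``n_restarts``.

    Restart seeds are derived from ``seed``; the fit is deterministic
    given (data, K, seed).  Raises for K exceeding the number of
    individuals; monomorphic SNPs are dropped with a warning.
    """
    n = len(G.individuals)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds {n} individuals")
    X, kept = dosage_matrix(G, ref_alleles)
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNPs to fit")
    best = None
    root = np.random.default_rng(seed)
    for r in range(n_restarts):
        rng = np.random.default_rng(root.integers(2**31))
        Q, P, ll, path, n_iter, conv = _em_once(X, K, rng, tol, max_iter)
        if best is None or ll > best[2]:
            best = (Q, P, ll, path, n_iter, conv)
    Q, P, ll, path, n_iter, conv = best
    return AdmixtureFit(K=K, Q=Q, P=P, loglik=ll, individuals=list(G.individuals),
                        snp_ids=kept, loglik_path=path, seed=seed,
                        replicate=replicate, n_iter=n_iter, converged=conv)


def fit_k_range(G: GenotypeMatrix, k_values, seed: int, *,
                n_replicates: int = 5, n_restarts: int = 3,
                tol: float = 1e-4, max_iter: int = 500) -> list[AdmixtureFit]:
    """Replicated fits across a K range, as input for :func:`evanno`.

    Each replicate is an independently seeded fit, so the spread of
    log-likelihoods over replicates reflects the multimodality of the
    likelihood surface at that K — the signal the ΔK statistic
    normalizes by.  A few restarts per replicate (default 3) keep a
    single stuck run from inflating the replicate SD at the true K
    while leaving the across-replicate spread intact; the looser
    stopping rule (0.0001 log-likelihood units) is ample for model
    selection.
    """
    fits = []
    root = np.random.default_rng(seed)
    for K in k_values:
        for rep in range(n_replicates):
            sub = int(root.integers(2**31))
            fits.append(
                admixture_em(G, K, seed=sub, n_restarts=n_restarts,
                             tol=tol, max_iter=max_iter, replicate=rep)
            )
    return fits


@dataclass
class EvannoSummary:
    """Mean/SD of log-likelihood per K and the ΔK second-difference table."""

    table: pd.DataFrame  # index K; columns mean_L, sd_L, delta_k, n_replicates
    best_k: int | None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.table.to_string()


def evanno(fits) -> EvannoSummary:
    """Evanno ΔK over replicated fits.

    ΔK(K) = |mean_L(K+1) - 2 mean_L(K) + mean_L(K-1)| / sd_L(K),
    defined only for internal K with nonzero replicate SD (zero-SD
    entries are flagged as NaN, not infinity).  Requires at least three
    consecutive K values with two or more replicates each.
    """
    by_k: dict[int, list[float]] = {}
    for fit in fits:
        by_k.setdefault(fit.K, []).append(fit.loglik)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(by_k[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1] or sd[k] == 0.0:
            dk = np.nan
        else:
            dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
        rows.append({"K": k, "mean_L": mean[k], "sd_L": sd[k],
                     "delta_k": dk, "n_replicates": len(by_k[k])})
    table = pd.DataFrame(rows).set_index("K")
    defined = table["delta_k"].dropna()
    best = int(defined.idxmax()) if not defined.empty else None
    return EvannoSummary(table=table, best_k=best)


def call_hybrids(Q: np.ndarray, individuals, cluster_names=None, *,
                 admix_threshold: float = ADMIX_THRESHOLD) -> list[HybridCall]:
    """Classify individuals as pure or admixed from their ancestry rows.

    An individual is *pure* when its majority ancestry is at least
    ``1 - admix_threshold`` (the boundary counts as pure); contributors
    are the clusters with ancestry strictly above the threshold.
    """
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q rows must sum to 1")
    names = list(cluster_names) if cluster_names is not None else [
        f"cluster{k + 1}" for k in range(Q.shape[1])
    ]
    calls = []
    for i, ind in enumerate(individuals):
        row = Q[i]
        k = int(np.argmax(row))
        max_q = float(row[k])
        status = "pure" if max_q >= 1.0 - admix_threshold else "admixed"
        contributors = tuple(names[j] for j in range(len(names))
                             if row[j] > admix_threshold)
        calls.append(HybridCall(ind, names[k], max_q, status, contributors))
    return calls


def match_clusters_to_groups(fit: AdmixtureFit, truth_q: np.ndarray) -> np.ndarray:
    """Permutation of fit clusters best matching reference ancestry columns.

    Resolves label switching by maximum-weight bipartite matching of
    Q columns; returns ``perm`` such that ``fit.Q[:, perm]`` aligns with
    ``truth_q`` columns.
    """
    from scipy.optimize import linear_sum_assignment

    truth_q = np.asarray(truth_q, dtype=float)
    if truth_q.shape != fit.Q.shape:
        raise ValueError("shape mismatch between fit Q and reference Q")
    cost = -(truth_q.T @ fit.Q)  # K x K overlap
    _, perm = linear_sum_assignment(cost)
    return perm
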