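"""Population structure: kinship, IBS distances, PCA, neighbor joining,
admixture-model fitting and Evanno delta-K model selection.

The kinship matrix is the centered-IBS genomic relationship: the cross
product of the column-centered dosage matrix scaled by the total expected
heterozygosity, symmetric positive semi-definite by construction.  The
admixture model treats each dosage as a Binomial(2) observation with success
probability q_i . p_m (ancestry-weighted subpopulation allele frequencies)
and is fitted by EM from multiple random restarts; the replicate final
log-likelihoods feed the Evanno delta-K statistic

    deltaK(K) = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_r(L_r(K)),

whose argmax over interior K estimates the supported number of
subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import MISSING, GenotypeMatrix


def _require_complete(gm: GenotypeMatrix, op: str) -> np.ndarray:
    if (gm.calls == MISSING).any():
        raise ValueError(f"{op} requires a complete matrix; run imputation first")
    return gm.calls.astype(float)


def centered_ibs_kinship(gm: GenotypeMatrix) -> np.ndarray:
    """Centered-IBS kinship: K = W'W / c with W the marker-centered dosage
    matrix and c = sum_m 2 p_m (1 - p_m)."""
    X = _require_complete(gm, "centered_ibs_kinship")  # (M, n)
    p = X.mean(axis=1) / 2.0
    W = X - X.mean(axis=1, keepdims=True)
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c == 0:
        raise ValueError("all markers are monomorphic; kinship undefined")
    K = (W.T @ W) / c
    return (K + K.T) / 2.0


def ibs_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state distances: score 1 for identical calls, 0.5 for one
    shared allele, 0 otherwise; missing pairs leave both numerator and
    denominator.  d = 1 - mean score.  Pairs with no overlapping calls are
    NaN."""
    if gm.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    X = gm.dosage()  # (M, n) NaN-missing
    n = gm.n_accessions
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X - X[:, i : i + 1])  # |a-b| in {0,1,2}; score = 1-|a-b|/2
        with np.errstate(invalid="ignore"):
            D[i] = np.nanmean(diff, axis=0) / 2.0
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def pca_genotypes(
    gm: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the marker-centered (not variance-scaled) dosage matrix.

    Returns (scores, variance_fractions): scores are accession coordinates on
    the leading components; fractions are each component's share of the total
    variance (all components, so the returned fractions sum to <= 1).  The
    sign of each component is fixed by forcing its largest-magnitude marker
    loading positive.
    """
    X = _require_complete(gm, "pca_genotypes")  # (M, n)
    A = (X - X.mean(axis=1, keepdims=True)).T  # (n, M), accessions as samples
    r = min(gm.n_accessions, gm.n_markers)
    if n_components > r:
        import warnings

        warnings.warn(f"n_components clipped to {r}", stacklevel=2)
        n_components = r
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    sign = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    sign[sign == 0] = 1.0
    scores = (U * s) * sign[None, :]
    return scores[:, :n_components], frac[:n_components]


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(
    dm: np.ndarray,
    labels: Sequence[str],
    midpoint_root: bool = True,
) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sister edge, preserving the pairwise path lengths.  On equal Q-criterion
    values the smallest (i, j) index pair is joined.  The tree is rooted at
    the midpoint by default.
    """
    D = np.asarray(dm, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("undefined distances in matrix")
    if len(labels) != n or len(set(labels)) != n:
        raise ValueError("labels must be unique and match the matrix size")
    nodes = [TreeNode(name=str(lbl)) for lbl in labels]
    active = list(range(n))
    D = D.copy()
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # first minimum = smallest (i, j) in row-major order
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negative lengths, moving the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        nodes.append(parent)
        new = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for a in active:
            if a in (i, j):
                continue
            D[new, a] = D[a, new] = 0.5 * (D[i, a] + D[j, a] - dij)
        active = [a for a in active if a not in (i, j)] + [new]
    i, j = active
    child_i, child_j = nodes[i], nodes[j]
    d = float(D[i, j])
    root = TreeNode(children=[child_i, child_j])
    child_i.length = d / 2.0
    child_j.length = d / 2.0
    if midpoint_root:
        root = root.root_at_midpoint()
    return root


# ---------------------------------------------------------------------------
# admixture EM

@dataclass
class AdmixtureReplicate:
    """One fitted admixture replicate: ancestry Q, allele frequencies P and
    the final binomial log-likelihood."""

    K: int
    replicate: int
    log_likelihood: float
    Q: np.ndarray  # (n, K), rows sum to 1
    P: np.ndarray  # (M, K) alt-allele frequencies
    n_iter: int = 0
    trajectory: np.ndarray | None = None  # per-iteration log-likelihood


_PCLIP = 1e-6


def _admixture_loglik(X: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    F = np.clip(Q @ P.T, _PCLIP, 1 - _PCLIP)  # (n, M)
    return float(np.sum(X * np.log(F) + (2.0 - X) * np.log(1.0 - F)))


def admixture_fit(
    gm: GenotypeMatrix,
    K: int,
    seeds: Sequence[int] = (0,),
    max_iter: int = 500,
    tol: float = 1e-4,
    keep_trajectory: bool = False,
) -> list[AdmixtureReplicate]:
    """Fit the binomial admixture model by EM, one replicate per seed.

    K = 1 has the closed-form optimum (P = observed allele frequencies) and
    is returned analytically.  The EM log-likelihood is monotone
    non-decreasing; convergence when the improvement falls below ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_accessions:
        raise ValueError("K exceeds the number of accessions")
    Xc = _require_complete(gm, "admixture_fit")  # (M, n)
    X = Xc.T  # (n, M)
    n, M = X.shape
    if K == 1:
        p = X.mean(axis=0) / 2.0
        Q = np.ones((n, 1))
        P = p[:, None]
        ll = _admixture_loglik(X, Q, P)
        return [
            AdmixtureReplicate(K=1, replicate=r, log_likelihood=ll, Q=Q.copy(),
                               P=P.copy(), n_iter=0,
                               trajectory=np.array([ll]) if keep_trajectory else None)
            for r in range(len(seeds))
        ]
    out = []
    for r, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(
            X.mean(axis=0)[:, None] / 2.0 + rng.uniform(-0.1, 0.1, size=(M, K)),
            0.05,
            0.95,
        )
        prev = -np.inf
        traj = []
        for it in range(1, max_iter + 1):
            F = np.clip(Q @ P.T, _PCLIP, 1 - _PCLIP)  # (n, M)
            alt_sum_p = np.empty((M, K))
            ref_sum_p = np.empty((M, K))
            resp_q = np.empty((n, K))
            for k in range(K):
                # E-step responsibilities for alt and ref allele copies
                a = (Q[:, k : k + 1] * P[None, :, k]) / F  # (n, M)
                b = (Q[:, k : k + 1] * (1.0 - P[None, :, k])) / (1.0 - F)
                xa = X * a
                xb = (2.0 - X) * b
                alt_sum_p[:, k] = xa.sum(axis=0)
                ref_sum_p[:, k] = xb.sum(axis=0)
                resp_q[:, k] = xa.sum(axis=1) + xb.sum(axis=1)
            P = np.clip(alt_sum_p / np.maximum(alt_sum_p + ref_sum_p, 1e-12),
                        _PCLIP, 1 - _PCLIP)
            Q = resp_q / (2.0 * M)
            Q = np.clip(Q, 1e-12, None)
            Q /= Q.sum(axis=1, keepdims=True)
            ll = _admixture_loglik(X, Q, P)
            traj.append(ll)
            if ll - prev < tol and it > 1:
                prev = ll
                break
            prev = ll
        out.append(
            AdmixtureReplicate(
                K=K, replicate=r, log_likelihood=prev, Q=Q, P=P, n_iter=it,
                trajectory=np.array(traj) if keep_trajectory else None,
            )
        )
    return out


def align_labels(Q: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute ancestry columns to best match reference columns (greedy)."""
    K = Q.shape[1]
    perm = [-1] * K
    used: set[int] = set()
    corr = np.array(
        [[float(np.dot(Q[:, a], reference[:, b])) for b in range(K)] for a in range(K)]
    )
    for _ in range(K):
        a, b = np.unravel_index(np.argmax(corr), corr.shape)
        perm[b] = a
        corr[a, :] = -np.inf
        corr[:, b] = -np.inf
    return Q[:, perm]


def evanno_delta_k(replicates: Sequence[AdmixtureReplicate]) -> pd.DataFrame:
    """Evanno table: per K the mean and sd of L(K), mean |L''(K)| and deltaK.

    L''(K) = L(K+1) - 2 L(K) + L(K-1) is evaluated per replicate (replicates
    paired by index across K) and deltaK = mean |L''(K)| / sd(L(K)) for
    interior K only.  Requires at least two replicates per K and a contiguous
    K range; sd = 0 yields NaN (flagged undefined).
    """
    by_k: dict[int, list[float]] = {}
    for rep in replicates:
        by_k.setdefault(rep.K, []).append(rep.log_likelihood)
    ks = sorted(by_k)
    if len(ks) < 2:
        raise ValueError("need replicates for at least two K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    n_rep = min(len(v) for v in by_k.values())
    if n_rep < 2:
        raise ValueError("need at least 2 replicates per K")
    L = np.array([by_k[k][:n_rep] for k in ks])  # (nK, n_rep)
    rows = []
    for idx, k in enumerate(ks):
        sd = float(np.std(L[idx], ddof=1))
        mean_l = float(L[idx].mean())
        if 0 < idx < len(ks) - 1:
            lpp = np.abs(L[idx + 1] - 2.0 * L[idx] + L[idx - 1])
            mean_lpp = float(lpp.mean())
            delta = mean_lpp / sd if sd > 0 else float("nan")
        else:
            mean_lpp, delta = float("nan"), float("nan")
        rows.append(
            {"K": k, "mean_L": mean_l, "sd_L": sd, "mean_abs_Lpp": mean_lpp,
             "delta_K": delta}
        )
    return pd.DataFrame(rows)
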