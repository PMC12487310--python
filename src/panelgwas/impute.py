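"""LD-kNNi genotype imputation.

Fills each missing call from the genotypes of the k accessions most similar
to the target accession, where similarity is measured only over the l sites
in highest linkage disequilibrium (squared Pearson correlation of dosages)
with the target site, restricted to the same chromosome within a maximum
base-pair distance.  Defaults follow the method's standard parameterization:
l = 30 high-LD sites, k = 10 neighbors, 1 Mb window.

The procedure is fully deterministic: candidate sites are ranked by r^2 with
ties broken by marker order, neighbors by distance with ties broken by
accession order, and the imputed genotype maximizes the sum of inverse
squared neighbor distances, with ties broken toward the more frequent
genotype at the site and then the lower dosage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, MarkerRecord

#: Distance floor avoiding division by zero for identical neighbors.
EPSILON = 1e-8


@dataclass(frozen=True)
class LdKnniParams:
    n_ld_sites: int = 30
    n_neighbors: int = 10
    max_distance_bp: int = 1_000_000
    fallback: str = "mode"  # or "leave_missing"

    def __post_init__(self) -> None:
        if self.n_ld_sites < 1 or self.n_neighbors < 1:
            raise ValueError("n_ld_sites and n_neighbors must be >= 1")
        if self.max_distance_bp < 0:
            raise ValueError("max_distance_bp must be >= 0")
        if self.fallback not in ("mode", "leave_missing"):
            raise ValueError("fallback must be 'mode' or 'leave_missing'")


def ld_r2(site_a: np.ndarray, site_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete accessions (missing encoded as -1 or
    NaN).  Zero variance at either site yields 0.  Requires at least two
    complete pairs.
    """
    a = np.array(site_a, dtype=float, copy=True)
    b = np.array(site_b, dtype=float, copy=True)
    a[a == MISSING] = np.nan
    b[b == MISSING] = np.nan
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete accessions")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _site_mode(col: np.ndarray) -> int:
    """Most frequent called genotype; ties toward the lower dosage."""
    counts = np.array([(col == g).sum() for g in (0, 1, 2)])
    if counts.sum() == 0:
        return MISSING
    return int(np.argmax(counts))  # argmax returns the first (lowest) on ties


def _pairwise_r2_to_site(X: np.ndarray, s_row: np.ndarray) -> np.ndarray:
    """r^2 of every row of X (sites x accessions, NaN-missing) with s_row."""
    ok = ~np.isnan(X) & ~np.isnan(s_row)[None, :]
    n = ok.sum(axis=1).astype(float)
    Xz = np.where(ok, X, 0.0)
    sz = np.where(ok, s_row[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = Xz.sum(axis=1) / n
        ms = sz.sum(axis=1) / n
        cov = (Xz * sz).sum(axis=1) / n - mx * ms
        vx = (Xz**2).sum(axis=1) / n - mx**2
        vs = (sz**2).sum(axis=1) / n - ms**2
        r2 = cov**2 / (vx * vs)
    r2[(n < 2) | ~np.isfinite(r2)] = 0.0
    return r2


def impute_ld_knni(
    gm: GenotypeMatrix,
    markers: Sequence[MarkerRecord],
    params: LdKnniParams = LdKnniParams(),
) -> GenotypeMatrix:
    """Impute missing calls; observed calls are never altered.

    With ``fallback="mode"`` the output contains no missing call (the site
    mode fills cells with no usable LD sites or neighbors); with
    ``fallback="leave_missing"`` such cells stay missing.
    """
    by_id = {m.id: m for m in markers}
    chroms = np.array([by_id[mid].chrom for mid in gm.marker_ids])
    pos = np.array([by_id[mid].pos for mid in gm.marker_ids], dtype=np.int64)
    X = gm.dosage()  # (M, n) float with NaN
    out = gm.copy()
    missing_rows = np.flatnonzero((gm.calls == MISSING).any(axis=1))
    for s in missing_rows:
        miss_acc = np.flatnonzero(gm.calls[s] == MISSING)
        same = np.flatnonzero(
            (chroms == chroms[s])
            & (np.abs(pos - pos[s]) <= params.max_distance_bp)
            & (np.arange(gm.n_markers) != s)
            & (chroms != "Un")
        )
        ld_sites = np.empty(0, dtype=int)
        if same.size and chroms[s] != "Un":
            r2 = _pairwise_r2_to_site(X[same], X[s])
            order = np.argsort(-r2, kind="stable")  # ties: lower marker index
            ld_sites = same[order[: params.n_ld_sites]]
        mode_g = _site_mode(gm.calls[s])
        for i in miss_acc:
            g = _impute_one(X, gm.calls[s], ld_sites, i, params)
            if g == MISSING:
                g = mode_g if params.fallback == "mode" else MISSING
            if g != MISSING:
                out.calls[s, i] = g
    return out


def _impute_one(
    X: np.ndarray,
    site_calls: np.ndarray,
    ld_sites: np.ndarray,
    i: int,
    params: LdKnniParams,
) -> int:
    if ld_sites.size == 0:
        return MISSING
    B = X[ld_sites]  # (l, n)
    target = B[:, i]
    diff = (B - target[:, None]) ** 2
    shared = ~np.isnan(diff)
    n_shared = shared.sum(axis=0)
    with np.errstate(invalid="ignore"):
        d = np.nansum(diff, axis=0) / n_shared
    called_at_s = site_calls != MISSING
    usable = called_at_s & (n_shared > 0)
    usable[i] = False
    cand = np.flatnonzero(usable)
    if cand.size == 0:
        return MISSING
    order = np.argsort(d[cand], kind="stable")  # ties: lower accession index
    nn = cand[order[: params.n_neighbors]]
    w = 1.0 / np.maximum(d[nn], EPSILON) ** 2
    weight_by_g = np.zeros(3)
    for j, wj in zip(nn, w):
        weight_by_g[site_calls[j]] += wj
    best = weight_by_g.max()
    tied = np.flatnonzero(np.isclose(weight_by_g, best, rtol=1e-12, atol=0.0))
    if tied.size == 1:
        return int(tied[0])
    freq = np.array([(site_calls == g).sum() for g in (0, 1, 2)])
    tied_freq = freq[tied]
    # more frequent genotype first, then lower dosage
    return int(tied[np.argmax(tied_freq)])
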