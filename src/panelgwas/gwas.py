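"""Mixed-linear-model association mapping and multiple-testing machinery.

Multi-year phenotypes are first condensed to best linear unbiased estimates
(BLUEs) per accession by a fixed-effects fit of value ~ accession + year with
sum-to-zero year coding.  Associations are then tested under the mixed model

    y = mu + PCs . gamma + x_m . beta + u + e,
    u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I),

with K the centered-IBS kinship.  Variance components are estimated by REML
through the spectral decomposition of K; in P3D mode (the default) they are
estimated once under the null model and reused for every marker, which is
the standard fast configuration.  Each marker gets an F-test of beta = 0.

Multiple testing uses the effective number of independent tests: per
chromosome the marker-marker dosage correlation matrix is
eigen-decomposed and the smallest number of leading eigenvalues reaching
99.5% of the eigenvalue total is summed over chromosomes; the corrected
alpha is alpha / Meff (Bonferroni on effective tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeMatrix, MarkerRecord
from .popstructure import centered_ibs_kinship, pca_genotypes


# ---------------------------------------------------------------------------
# BLUEs

def compute_blues(traits: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects multi-year adjustment: value ~ accession + year.

    Year effects use sum-to-zero coding so the accession effect (plus
    intercept) is the adjusted genotype value; with balanced data this
    reduces to the per-accession mean.  Returns a wide accession x trait
    table; an accession with no observations for a trait is NaN there.
    """
    from .io_formats import validate_trait_table

    validate_trait_table(traits)
    out: dict[str, pd.Series] = {}
    for trait, sub in traits.groupby("trait"):
        accs = sorted(sub["accession_id"].unique())
        years = sorted(sub["year"].unique())
        acc_idx = {a: i for i, a in enumerate(accs)}
        yr_idx = {y: i for i, y in enumerate(years)}
        n_obs = len(sub)
        A = np.zeros((n_obs, len(accs)))
        Yr = np.zeros((n_obs, max(len(years) - 1, 0)))
        y = sub["value"].to_numpy(dtype=float)
        for r, (acc, yr) in enumerate(zip(sub["accession_id"], sub["year"])):
            A[r, acc_idx[acc]] = 1.0
            j = yr_idx[yr]
            if len(years) > 1:
                if j < len(years) - 1:
                    Yr[r, j] = 1.0
                else:  # last year = -(sum of others), sum-to-zero
                    Yr[r, :] = -1.0
        X = np.hstack([A, Yr])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[str(trait)] = pd.Series(beta[: len(accs)], index=accs)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# REML via spectral decomposition

def _reml_neg_loglik(log_lam: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = s + lam  # eigenvalues of K + lambda I
    Xw = Xt / w[:, None]
    XtX = Xt.T @ Xw
    try:
        beta = np.linalg.solve(XtX, Xw.T @ yt)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    p = Xt.shape[1]
    nf = len(yt) - p
    rss = float(np.sum(r * r / w))
    if rss <= 0:
        return np.inf
    sign, logdet = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf
    return 0.5 * (nf * np.log(rss / nf) + float(np.sum(np.log(w))) + logdet)


@dataclass
class MlmSpec:
    """Configuration of the mixed-model scan."""

    n_pcs: int = 10
    kinship: np.ndarray | None = None  # computed from gm when None
    mode: str = "P3D"  # or "per_marker"
    alpha_nominal: float = 0.05
    covariates: np.ndarray | None = None  # extra fixed effects, (n, q)

    def __post_init__(self) -> None:
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.mode not in ("P3D", "per_marker"):
            raise ValueError("mode must be 'P3D' or 'per_marker'")


def mlm_association(
    gm: GenotypeMatrix,
    phenotype: pd.Series | np.ndarray,
    spec: MlmSpec = None,
    markers: Sequence[MarkerRecord] | None = None,
    alpha_corrected: float | None = None,
) -> pd.DataFrame:
    """Per-marker mixed-model association scan.

    ``phenotype`` is indexed by accession id (or aligned positionally).
    Returns a DataFrame of marker effects, F statistics, p-values and
    -log10 p, sorted by genomic position when marker metadata are given.
    Markers collinear with the covariates (e.g. constant dosage) are flagged
    with p = 1.
    """
    if spec is None:
        spec = MlmSpec()
    if isinstance(phenotype, pd.Series):
        phenotype = phenotype.reindex(gm.accession_ids)
        if phenotype.isna().any():
            raise ValueError("phenotype missing for some accessions")
        y = phenotype.to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if y.shape[0] != gm.n_accessions:
            raise ValueError("phenotype length mismatch")
    n = gm.n_accessions
    K = spec.kinship if spec.kinship is not None else centered_ibs_kinship(gm)
    if K.shape != (n, n):
        raise ValueError("kinship dimensions do not match the genotype matrix")
    covs = [np.ones((n, 1))]
    if spec.n_pcs > 0:
        scores, _ = pca_genotypes(gm, spec.n_pcs)
        covs.append(scores)
    if spec.covariates is not None:
        covs.append(np.asarray(spec.covariates, dtype=float).reshape(n, -1))
    X0 = np.hstack(covs)
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    X0t = U.T @ X0
    Xall = gm.calls.astype(float)  # (M, n)
    Xallt = (U.T @ Xall.T).T  # rotated marker dosages, (M, n)

    def fit_lambda(Xt: np.ndarray) -> float:
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(-12.0, 12.0), args=(s, yt, Xt), method="bounded"
        )
        return float(np.exp(res.x))

    lam0 = fit_lambda(X0t)
    rows = []
    p0 = X0.shape[1]
    for m in range(gm.n_markers):
        xt = Xallt[m]
        lam = lam0 if spec.mode == "P3D" else fit_lambda(np.hstack([X0t, xt[:, None]]))
        w = s + lam
        Xt = np.hstack([X0t, xt[:, None]])
        Xw = Xt / w[:, None]
        XtX = Xt.T @ Xw
        # collinearity of the marker with covariates -> degenerate test
        cond_bad = np.linalg.matrix_rank(XtX, tol=1e-8 * max(np.abs(XtX).max(), 1.0)) < Xt.shape[1]
        if cond_bad:
            rows.append((0.0, 0.0, 1.0, True))
            continue
        XtXinv = np.linalg.inv(XtX)
        beta = XtXinv @ (Xw.T @ yt)
        r = yt - Xt @ beta
        df = n - Xt.shape[1]
        sigma2 = float(np.sum(r * r / w)) / df
        se = float(np.sqrt(XtXinv[-1, -1] * sigma2))
        b = float(beta[-1])
        F = (b / se) ** 2 if se > 0 else 0.0
        p = float(stats.f.sf(F, 1, df)) if se > 0 else 1.0
        rows.append((b, F, p, False))
    df_out = pd.DataFrame(rows, columns=["beta", "F", "p", "degenerate"])
    df_out.insert(0, "marker_id", gm.marker_ids)
    if markers is not None:
        by_id = {m.id: m for m in markers}
        df_out["chrom"] = [by_id[mid].chrom for mid in gm.marker_ids]
        df_out["pos"] = [by_id[mid].pos for mid in gm.marker_ids]
        df_out = df_out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df_out["p"] = df_out["p"].clip(lower=np.finfo(float).tiny, upper=1.0)
    df_out["neglog10p"] = -np.log10(df_out["p"])
    if alpha_corrected is not None:
        df_out["significant"] = df_out["p"] < alpha_corrected
    return df_out


# ---------------------------------------------------------------------------
# SimpleM effective number of tests

def simplem_meff(
    gm: GenotypeMatrix,
    markers: Sequence[MarkerRecord] | None = None,
    cutoff: float = 0.995,
) -> int:
    """Effective number of independent tests from the eigenvalue spectrum.

    Per chromosome, the marker-marker dosage correlation matrix is
    eigen-decomposed and Meff_chrom is the smallest count of leading
    eigenvalues whose sum reaches ``cutoff`` of the eigenvalue total; Meff is
    the sum over chromosomes.  Zero-variance markers are dropped with a
    notice.
    """
    import warnings

    if gm.n_markers < 2:
        raise ValueError("need at least 2 markers")
    X = _as_complete_dosage(gm)
    if markers is not None:
        by_id = {m.id: m for m in markers}
        chroms = np.array([by_id[mid].chrom for mid in gm.marker_ids])
    else:
        chroms = np.array(["all"] * gm.n_markers)
    meff = 0
    n_dropped = 0
    for c in np.unique(chroms):
        block = X[chroms == c]
        sd = block.std(axis=1)
        n_dropped += int((sd == 0).sum())
        block = block[sd > 0]
        if block.shape[0] == 0:
            continue
        if block.shape[0] == 1:
            meff += 1
            continue
        R = np.corrcoef(block)
        ev = np.linalg.eigvalsh(R)[::-1]
        ev = np.clip(ev, 0.0, None)
        target = cutoff * ev.sum()
        meff += int(np.searchsorted(np.cumsum(ev), target - 1e-12) + 1)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-variance marker(s)", stacklevel=2)
    return meff


def _as_complete_dosage(gm: GenotypeMatrix) -> np.ndarray:
    from .io_formats import MISSING

    if (gm.calls == MISSING).any():
        raise ValueError("missing genotypes present; run imputation first")
    return gm.calls.astype(float)


def bonferroni_threshold(meff: int, alpha_nominal: float = 0.05) -> float:
    """Corrected per-test alpha: alpha_nominal / Meff."""
    if meff < 1:
        raise ValueError("Meff must be >= 1")
    return alpha_nominal / meff


# ---------------------------------------------------------------------------
# enrichment and QQ

def mta_category_enrichment(
    records: pd.DataFrame,
    categories: Mapping[str, str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category MTA proportions with pairwise Fisher exact tests.

    ``records`` must carry ``marker_id`` and boolean ``significant`` (a
    marker counts as hit when significant for at least one trait across the
    rows given).  Returns (summary with homogeneous-group letters, pairwise
    p-value matrix).  Empty categories are excluded with a notice.
    """
    import warnings

    import networkx as nx

    hit = records.groupby("marker_id")["significant"].any()
    cats = pd.Series({mid: categories[mid] for mid in hit.index})
    table = pd.DataFrame({"category": cats, "hit": hit})
    summary = (
        table.groupby("category")
        .agg(n_markers=("hit", "size"), n_significant=("hit", "sum"))
        .reset_index()
    )
    empty = summary[summary["n_markers"] == 0]["category"].tolist()
    if empty:
        warnings.warn(f"excluded empty categories {empty}", stacklevel=2)
        summary = summary[summary["n_markers"] > 0]
    summary["proportion"] = summary["n_significant"] / summary["n_markers"]
    cats_order = summary["category"].tolist()
    pmat = pd.DataFrame(1.0, index=cats_order, columns=cats_order)
    for i, a in enumerate(cats_order):
        for b in cats_order[i + 1 :]:
            ra = summary.loc[summary["category"] == a].iloc[0]
            rb = summary.loc[summary["category"] == b].iloc[0]
            tab = [
                [int(ra["n_significant"]), int(ra["n_markers"] - ra["n_significant"])],
                [int(rb["n_significant"]), int(rb["n_markers"] - rb["n_significant"])],
            ]
            p = float(stats.fisher_exact(tab, alternative="two-sided")[1])
            pmat.loc[a, b] = pmat.loc[b, a] = p
    # homogeneous-group letters: maximal cliques of the non-significance graph
    g = nx.Graph()
    g.add_nodes_from(cats_order)
    for i, a in enumerate(cats_order):
        for b in cats_order[i + 1 :]:
            if pmat.loc[a, b] >= alpha:
                g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g), key=lambda c: (-len(c), sorted(c)))
    letters: dict[str, str] = {c: "" for c in cats_order}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for c in clique:
            letters[c] += letter
    summary["group"] = summary["category"].map(lambda c: "".join(sorted(letters[c])))
    return summary.reset_index(drop=True), pmat


def qq_table(records: pd.DataFrame) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Expected quantiles are -log10((i - 0.5) / M) against the sorted observed
    p-values.
    """
    p = np.sort(records["p"].to_numpy(dtype=float))
    if p.size < 1:
        raise ValueError("no association records")
    M = p.size
    expected = -np.log10((np.arange(1, M + 1) - 0.5) / M)
    return pd.DataFrame({"expected": expected, "observed": -np.log10(p)})
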