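"""BLUEs, mixed-model association, SimpleM, enrichment and QQ tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelgwas.gwas import (
    MlmSpec,
    bonferroni_threshold,
    compute_blues,
    mlm_association,
    mta_category_enrichment,
    qq_table,
    simplem_meff,
)
from panelgwas.io_formats import GenotypeMatrix, MarkerRecord
from panelgwas.synthetic import (
    SimulationConfig,
    TraitSpec,
    simulate_population,
    simulate_traits,
)


def _gm(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        [f"m{i}" for i in range(calls.shape[0])],
        [f"a{j}" for j in range(calls.shape[1])],
        calls,
    )


# ---------------------------------------------------------------------- BLUEs

def test_blues_balanced_equals_three_year_mean():
    rows = []
    rng = np.random.default_rng(0)
    vals = {}
    for acc in ("a1", "a2", "a3"):
        vals[acc] = rng.normal(size=3)
        for yi, v in enumerate(vals[acc]):
            rows.append({"accession_id": acc, "trait": "t", "year": 2018 + yi,
                         "value": v})
    blues = compute_blues(pd.DataFrame(rows))
    for acc in vals:
        assert blues.loc[acc, "t"] == pytest.approx(vals[acc].mean(), abs=1e-10)


def test_blues_single_year_is_identity():
    df = pd.DataFrame({"accession_id": ["a", "b"], "trait": ["t", "t"],
                       "year": [2018, 2018], "value": [1.5, -0.5]})
    blues = compute_blues(df)
    assert blues.loc["a", "t"] == pytest.approx(1.5)
    assert blues.loc["b", "t"] == pytest.approx(-0.5)


def test_blues_unbalanced_matches_normal_equations():
    """Missing cells: solution equals the direct least-squares solve."""
    rows = [
        ("a1", 2018, 10.0), ("a1", 2019, 12.0), ("a1", 2020, 11.0),
        ("a2", 2018, 9.0), ("a2", 2020, 8.5),
        ("a3", 2019, 14.0),
    ]
    df = pd.DataFrame(rows, columns=["accession_id", "year", "value"])
    df["trait"] = "t"
    blues = compute_blues(df)
    # oracle: explicit design with accession dummies and sum-to-zero years
    accs, years = ["a1", "a2", "a3"], [2018, 2019, 2020]
    X = np.zeros((len(rows), 3 + 2))
    y = df["value"].to_numpy()
    for r, (acc, yr, _) in enumerate(rows):
        X[r, accs.index(acc)] = 1
        j = years.index(yr)
        if j < 2:
            X[r, 3 + j] = 1
        else:
            X[r, 3:] = -1
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    for i, acc in enumerate(accs):
        assert blues.loc[acc, "t"] == pytest.approx(beta[i], abs=1e-10)


# ---------------------------------------------------------------------- MLM

def _ols_pvalue(x, y):
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    df = len(y) - 2
    s2 = r @ r / df
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    F = (beta[1] / se) ** 2
    return beta[1], float(stats.f.sf(F, 1, df))


def test_mlm_zero_kinship_equals_ols():
    """With K = 0 and no PCs the mixed model collapses to OLS exactly."""
    rng = np.random.default_rng(1)
    n, M = 60, 30
    calls = rng.choice([0, 1, 2], size=(M, n), p=[0.4, 0.1, 0.5]).astype(np.int8)
    gm = _gm(calls)
    y = rng.normal(size=n) + 0.4 * calls[3]
    spec = MlmSpec(n_pcs=0, kinship=np.zeros((n, n)))
    assoc = mlm_association(gm, y, spec)
    for m in range(0, M, 5):
        x = calls[m].astype(float)
        if x.std() == 0:
            continue
        beta, p = _ols_pvalue(x, y)
        row = assoc[assoc["marker_id"] == f"m{m}"].iloc[0]
        assert row["beta"] == pytest.approx(beta, abs=1e-8)
        assert row["p"] == pytest.approx(p, abs=1e-8)


def test_mlm_constant_marker_flagged():
    rng = np.random.default_rng(2)
    calls = rng.choice([0, 2], size=(5, 30)).astype(np.int8)
    calls[2] = 2
    gm = _gm(calls)
    y = rng.normal(size=30)
    assoc = mlm_association(gm, y, MlmSpec(n_pcs=0, kinship=np.eye(30) * 0.1))
    row = assoc[assoc["marker_id"] == "m2"].iloc[0]
    assert row["degenerate"] and row["p"] == 1.0


def test_mlm_conditional_on_causal_kills_its_own_signal():
    """Adding the causal dosage as a covariate drives its own p to 1."""
    cfg = SimulationConfig(n_accessions=120, n_markers=100, rng_seed=3,
                           base_missing_rate=0.0, translocation=None,
                           traits=(TraitSpec("t", causal={7: 0.8},
                                             heritability=0.6, n_years=1),))
    gm, markers, truth = simulate_population(cfg)
    traits = simulate_traits(gm, markers, truth, cfg)
    blues = compute_blues(traits)
    x_causal = gm.calls[7].astype(float)
    spec = MlmSpec(n_pcs=0, covariates=x_causal)
    assoc = mlm_association(gm, blues["t"], spec)
    row = assoc[assoc["marker_id"] == gm.marker_ids[7]].iloc[0]
    assert row["degenerate"] and row["p"] == 1.0


def test_mlm_power_causal_locus_is_top_hit():
    """A locus explaining ~30% of variance at n=200 tops the scan in >= 18/20 seeds."""
    from dataclasses import replace

    hits = 0
    for seed in range(20):
        cfg = SimulationConfig(
            n_accessions=200, n_markers=250, rng_seed=seed,
            base_missing_rate=0.0, translocation=None,
        )
        gm, markers, truth = simulate_population(cfg)
        # pick a mid-frequency locus and scale beta to explain 30% of variance
        var = gm.calls.astype(float).var(axis=1)
        idx = int(np.argmax(var))
        beta = float(np.sqrt(0.30 / var[idx]))
        cfg = replace(cfg, traits=(TraitSpec("t", causal={idx: beta},
                                             heritability=0.5),))
        traits = simulate_traits(gm, markers, truth, cfg)
        blues = compute_blues(traits)
        assoc = mlm_association(gm, blues["t"])
        top = assoc.loc[assoc["p"].idxmin(), "marker_id"]
        if top == gm.marker_ids[idx]:
            hits += 1
    assert hits >= 18


def test_mlm_null_type_one_error_calibrated():
    """Without causal loci the fraction of p < alpha stays within 3 binomial
    SEs of alpha, pooled over 20 seeds."""
    alpha = 0.05
    n_sig = 0
    n_tests = 0
    for seed in range(20):
        cfg = SimulationConfig(
            n_accessions=100, n_markers=120, rng_seed=seed + 100,
            base_missing_rate=0.0, translocation=None,
            traits=(TraitSpec("t", causal={}, heritability=0.3),),
        )
        gm, markers, truth = simulate_population(cfg)
        traits = simulate_traits(gm, markers, truth, cfg)
        blues = compute_blues(traits)
        assoc = mlm_association(gm, blues["t"])
        ok = ~assoc["degenerate"]
        n_sig += int((assoc.loc[ok, "p"] < alpha).sum())
        n_tests += int(ok.sum())
    rate = n_sig / n_tests
    se = np.sqrt(alpha * (1 - alpha) / n_tests)
    assert abs(rate - alpha) < 3 * se, f"type-I rate {rate:.4f} over {n_tests} tests"


# ---------------------------------------------------------------------- SimpleM

def test_meff_orthogonal_markers():
    """Mutually uncorrelated dosage patterns count as independent tests."""
    # Hadamard-like orthogonal +-1 contrasts mapped to dosages {0,2}
    H = np.array([
        [1, 1, 1, 1, 1, 1, 1, 1],
        [1, -1, 1, -1, 1, -1, 1, -1],
        [1, 1, -1, -1, 1, 1, -1, -1],
        [1, -1, -1, 1, 1, -1, -1, 1],
    ])
    calls = ((H[1:] + 1)).astype(np.int8)  # drop constant row
    gm = _gm(calls)
    assert simplem_meff(gm) == 3


def test_meff_duplicate_and_block():
    rng = np.random.default_rng(0)
    M, n = 12, 40
    base = rng.choice([0, 2], size=(M, n), p=[0.5, 0.5]).astype(np.int8)
    gm = _gm(base)
    m_indep = simplem_meff(gm)
    # duplicate one marker -> effective count drops by one
    dup = np.vstack([base, base[0:1]])
    assert simplem_meff(_gm(dup)) == m_indep
    assert simplem_meff(_gm(dup)) == (M + 1) - 1
    # block of b perfectly correlated markers -> M - b + 1
    b = 4
    block = np.vstack([base, np.tile(base[0:1], (b - 1, 1))])
    assert simplem_meff(_gm(block)) == (M + b - 1) - b + 1


def test_meff_bounds_on_simulated_panel(small_panel):
    gm, markers, _ = small_panel
    clean = gm.copy()
    clean.calls[clean.calls == -1] = 0
    sd = clean.calls.std(axis=1)
    clean = clean.subset_markers(sd > 0)
    mk = [m for m in markers if m.id in set(clean.marker_ids)]
    meff = simplem_meff(clean, mk)
    assert 1 <= meff <= clean.n_markers


@pytest.mark.parametrize("meff,alpha,expected",
                         [(100, 0.05, 5e-4), (1, 0.05, 0.05),
                          (3456, 0.05, 0.05 / 3456)])
def test_bonferroni_threshold(meff, alpha, expected):
    assert bonferroni_threshold(meff, alpha) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------- enrichment

def _records(sig_by_cat):
    rows, cats = [], {}
    i = 0
    for cat, flags in sig_by_cat.items():
        for flag in flags:
            mid = f"m{i}"
            rows.append({"marker_id": mid, "significant": flag})
            cats[mid] = cat
            i += 1
    return pd.DataFrame(rows), cats


def test_enrichment_equal_proportions_p_one():
    records, cats = _records({"A": [True] * 5 + [False] * 5,
                              "B": [True] * 5 + [False] * 5})
    summary, pmat = mta_category_enrichment(records, cats)
    assert pmat.loc["A", "B"] == pytest.approx(1.0)
    assert summary["group"].nunique() == 1  # one homogeneous group


def test_enrichment_matches_hypergeometric_enumeration():
    """2x2 table (8,2; 1,9): two-sided exact p from full enumeration."""
    records, cats = _records({"A": [True] * 8 + [False] * 2,
                              "B": [True] * 1 + [False] * 9})
    _, pmat = mta_category_enrichment(records, cats)
    # enumeration oracle: sum P(X=k) over k with P(k) <= P(observed)
    n1, n2, k_obs = 10, 10, 8
    total_sig = 9
    probs = {k: (stats.hypergeom.pmf(k, n1 + n2, total_sig, n1)) for k in range(10)}
    p_obs = probs[k_obs]
    p_exact = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
    assert pmat.loc["A", "B"] == pytest.approx(p_exact, rel=1e-6)


def test_enrichment_extreme_difference_significant():
    records, cats = _records({"A": [False] * 10, "B": [True] * 10})
    summary, pmat = mta_category_enrichment(records, cats)
    assert pmat.loc["A", "B"] < 0.001
    ga = summary.loc[summary["category"] == "A", "group"].iloc[0]
    gb = summary.loc[summary["category"] == "B", "group"].iloc[0]
    assert set(ga).isdisjoint(set(gb))  # different letter groups


# ---------------------------------------------------------------------- QQ

def test_qq_single_record():
    df = qq_table(pd.DataFrame({"p": [0.5]}))
    assert df["expected"].iloc[0] == pytest.approx(0.301, abs=1e-3)
    assert df["observed"].iloc[0] == pytest.approx(0.301, abs=1e-3)


def test_qq_uniform_grid_on_diagonal():
    M = 99
    p = (np.arange(1, M + 1) - 0.5) / M
    df = qq_table(pd.DataFrame({"p": p}))
    assert np.allclose(df["expected"], df["observed"], atol=1e-12)
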