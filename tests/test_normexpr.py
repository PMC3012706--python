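"""TMM factors, effective sizes, RPKM."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from locustexpr.catalog import ClusterMap, ConsistencyError
from locustexpr.normexpr import (
    DegenerateInputError,
    effective_size,
    rpkm_matrix,
    tmm_factor,
    tmm_normalize,
)
from locustexpr.readcount import CountTable


def tmm_direct(obs, ref, n_obs=None, n_ref=None, logratio_trim=0.3, abundance_trim=0.05):
    """Independent direct rendering of the published weighted-TMM formula."""
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    no = obs.sum() if n_obs is None else float(n_obs)
    nr = ref.sum() if n_ref is None else float(n_ref)
    k = (obs > 0) & (ref > 0)
    o, r = obs[k], ref[k]
    m = np.log2((o / no) / (r / nr))
    a = 0.5 * np.log2((o / no) * (r / nr))
    n = len(m)
    keep = np.ones(n, bool)
    for v, trim in ((m, logratio_trim), (a, abundance_trim)):
        lo = np.floor(n * trim) + 1
        rk = rankdata(v)
        keep &= (rk >= lo) & (rk <= n + 1 - lo)
    w = (no - o[keep]) / (no * o[keep]) + (nr - r[keep]) / (nr * r[keep])
    return 2.0 ** (np.sum(m[keep] / w) / np.sum(1.0 / w))


def test_identical_library_gives_factor_one():
    counts = np.array([10, 200, 3000, 40, 5])
    assert tmm_factor(counts, counts) == 1.0


def test_uniform_scaling_gives_factor_one():
    counts = np.array([10, 200, 3000, 40, 5])
    assert tmm_factor(counts * 2, counts) == 1.0  # totals recomputed from columns


def test_fixed_totals_scaling_shifts_factor():
    rng = np.random.default_rng(3)
    ref = rng.poisson(np.exp(rng.normal(5, 1, 500))) + 1
    obs = rng.poisson(ref).astype(float) + 1
    n_obs, n_ref = obs.sum(), ref.sum()
    # multiply one column's counts but keep the stated totals fixed; with
    # the unweighted mean the shift in M is exact, with the default
    # precision weights it holds only approximately
    f1 = tmm_factor(obs, ref, n_obs, n_ref, weighted=False)
    f2 = tmm_factor(obs * 3, ref, n_obs, n_ref, weighted=False)
    assert f2 == pytest.approx(3 * f1, rel=1e-9)
    f1w = tmm_factor(obs, ref, n_obs, n_ref)
    f2w = tmm_factor(obs * 3, ref, n_obs, n_ref)
    assert f2w == pytest.approx(3 * f1w, rel=0.01)


@pytest.mark.parametrize("seed", range(3))
def test_composition_bias_recovery_matches_direct_formula(seed):
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(np.log(200), 1.0, 2000))
    ref = rng.poisson(mu)
    obs = rng.poisson(mu)
    inflated = rng.choice(2000, 100, replace=False)
    obs[inflated] = rng.poisson(mu[inflated] * 8)
    mine = tmm_factor(obs, ref)
    oracle = tmm_direct(obs, ref)
    assert mine == pytest.approx(oracle, rel=0.05)


def test_matches_edger_calcnormfactors(tmp_path):
    rng = np.random.default_rng(11)
    mu = np.exp(rng.normal(np.log(100), 1.2, 1500))
    ref = rng.poisson(mu)
    obs = rng.poisson(mu)
    inflated = rng.choice(1500, 75, replace=False)
    obs[inflated] = rng.poisson(mu[inflated] * 6)
    table = tmp_path / "tmm.tsv"
    pd.DataFrame({"obs": obs, "ref": ref}).to_csv(table, sep="\t", index=False)
    script = (
        'suppressMessages(library(edgeR));'
        f'd <- read.delim("{table}");'
        'y <- calcNormFactors(DGEList(counts=as.matrix(d)), method="TMM", refColumn=2);'
        'f <- y$samples$norm.factors; cat(f[1]/f[2])'
    )
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    edger = float(proc.stdout.strip())
    mine = tmm_factor(obs, ref)
    assert mine == pytest.approx(edger, rel=1e-4)


def test_degenerate_inputs_raise():
    with pytest.raises(DegenerateInputError):
        tmm_factor(np.array([0, 0, 5]), np.array([3, 4, 0]))


@pytest.mark.parametrize(
    "n,f,expected", [(1_000_000, 1.0, 1_000_000), (1_000_000, 4.0, 2_000_000),
                     (2_000_000, 0.25, 1_000_000)]
)
def test_effective_size(n, f, expected):
    assert effective_size(n, f) == pytest.approx(expected)


def test_tmm_normalize_reference_has_unit_factor(pair_counts):
    norm = tmm_normalize(pair_counts, "lib1")
    assert norm.loc["lib1", "f"] == 1.0
    assert norm.loc["lib1", "N_eff"] == pytest.approx(norm.loc["lib1", "N"])
    assert (norm["N_eff"] == norm["N"] * np.sqrt(norm["f"])).all()


def test_tmm_normalize_geomean_renorm(pair_counts):
    norm = tmm_normalize(pair_counts, "lib1", renorm="geomean")
    assert np.log(norm["f"]).mean() == pytest.approx(0.0, abs=1e-12)


def test_rpkm_values():
    counts = CountTable(
        pd.DataFrame({"L": [10, 0, 50]}, index=["a", "b", "c"]),
        totals=pd.Series({"L": 60}),
    )
    lengths = pd.Series({"a": 1000, "b": 700, "c": 2500})
    norm = pd.DataFrame({"N_eff": [1e6]}, index=["L"])
    r = rpkm_matrix(counts, lengths, norm)
    assert r.loc["a", "L"] == pytest.approx(10.0)
    assert r.loc["b", "L"] == 0.0
    norm2 = pd.DataFrame({"N_eff": [2e6]}, index=["L"])
    r2 = rpkm_matrix(counts, lengths, norm2)
    assert r2.loc["c", "L"] == pytest.approx(10.0)  # 50 / (2.5 * 2)


def test_rpkm_cluster_members_inherit_count(abc_clusters, small_catalog):
    counts = CountTable(
        pd.DataFrame({"L": [100, 10, 5]}, index=["B", "D", "E"]),
        totals=pd.Series({"L": 115}),
    )
    r = rpkm_matrix(counts, small_catalog.lengths, None, clusters=abc_clusters)
    # members A (900 bp) and C (700 bp) inherit the 100 reads of unit B
    assert r.loc["A", "L"] == pytest.approx(100 / (0.9 * 115 / 1e6))
    assert r.loc["C", "L"] == pytest.approx(100 / (0.7 * 115 / 1e6))
    assert set(r.index) == set(small_catalog.ids)


def test_rpkm_is_linear_in_counts():
    rng = np.random.default_rng(4)
    mat = pd.DataFrame(rng.integers(0, 100, (30, 3)), columns=list("xyz"))
    lengths = pd.Series(rng.integers(200, 3000, 30), index=mat.index)
    totals = mat.sum(axis=0)
    norm = pd.DataFrame({"N_eff": totals.astype(float)})
    r1 = rpkm_matrix(CountTable(mat, totals), lengths, norm)
    r2 = rpkm_matrix(CountTable(mat * 3, totals), lengths, norm)
    np.testing.assert_allclose(r2.values, 3 * r1.values)


def test_rpkm_missing_length_raises(pair_counts):
    with pytest.raises(ConsistencyError):
        rpkm_matrix(pair_counts, pd.Series({"u1": 100}), None)
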