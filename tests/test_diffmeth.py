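import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import xlogy

from rrbskit import diffmeth
from rrbskit.diffmeth import (
    call_dmcs,
    estimate_pi0_slim,
    lrt_test,
    map_dmcs_to_genes,
    overlap_contrasts,
    per_site_test,
    slim_qvalues,
)
from rrbskit.filtering import unite


def g_test_statistic(m_a, u_a, m_b, u_b):
    """Closed-form 2x2 G-test: 2 * sum O*ln(O/E) over the pooled table."""
    table = np.array([[m_a, u_a], [m_b, u_b]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(table, table / expected)
    return 2.0 * np.nansum(terms)


def test_identical_proportions_give_zero_diff_unit_p():
    diff, stat, p = lrt_test([20], [40], [10], [20])
    assert diff[0] == 0.0 and stat[0] == pytest.approx(0.0, abs=1e-12)
    assert p[0] == pytest.approx(1.0)


def test_lrt_equals_gtest_for_single_samples():
    rng = np.random.default_rng(21)
    cov_a = rng.integers(12, 80, 1000)
    cov_b = rng.integers(12, 80, 1000)
    m_a = rng.binomial(cov_a, rng.uniform(0.05, 0.95, 1000))
    m_b = rng.binomial(cov_b, rng.uniform(0.05, 0.95, 1000))
    _, stat, _ = lrt_test(m_a, cov_a, m_b, cov_b)
    oracle = [g_test_statistic(ma, ca - ma, mb, cb - mb)
              for ma, ca, mb, cb in zip(m_a, cov_a, m_b, cov_b)]
    assert np.abs(stat - oracle).max() < 1e-8


def test_strong_difference_detected():
    diff, _, p = lrt_test([40], [50], [10], [50])
    assert diff[0] == pytest.approx(60.0)
    assert p[0] < 1e-8


def test_boundary_proportions_handled_exactly():
    diff, stat, p = lrt_test([0], [40], [20], [40])
    assert np.isfinite(stat[0]) and p[0] < 1e-4 and diff[0] == -50.0
    # both groups at 0%: no signal
    _, stat0, p0 = lrt_test([0], [40], [0], [40])
    assert stat0[0] == 0.0 and p0[0] == 1.0


def test_lrt_matches_statsmodels_glm_with_replicates():
    """Independent oracle: iteratively fitted binomial GLM deviance LRT."""
    rng = np.random.default_rng(33)
    for _ in range(15):
        cov = rng.integers(15, 60, 8)
        p_a, p_b = rng.uniform(0.15, 0.85, 2)
        meth = np.concatenate(
            [rng.binomial(cov[:4], p_a), rng.binomial(cov[4:], p_b)]
        )
        group = np.repeat([1.0, 0.0], 4)
        endog = np.column_stack([meth, cov - meth])
        full = sm.GLM(endog, sm.add_constant(group), family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, np.ones((8, 1)), family=sm.families.Binomial()).fit()
        lrt_glm = 2.0 * (full.llf - null.llf)
        _, stat, _ = lrt_test(
            [meth[:4].sum()], [cov[:4].sum()], [meth[4:].sum()], [cov[4:].sum()]
        )
        assert stat[0] == pytest.approx(lrt_glm, abs=1e-6)


def test_per_site_test_swap_symmetry(two_group_null):
    _, sim = two_group_null
    united = unite(sim.samples, ("NC", "SS"))
    fwd = per_site_test(united, "SS", "NC")
    rev = per_site_test(united, "NC", "SS")
    np.testing.assert_allclose(fwd["diff"], -rev["diff"], atol=1e-12)
    np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)
    fwd["q"], _ = slim_qvalues(fwd["p"].to_numpy())
    rev["q"], _ = slim_qvalues(rev["p"].to_numpy())
    f, r = call_dmcs(fwd), call_dmcs(rev)
    np.testing.assert_allclose(f["q"], r["q"], atol=1e-12)
    assert ((f["status"] == "hyper") == (r["status"] == "hypo")).all()


# ---------------------------------------------------------------------------
# SLIM q-values


def test_pi0_near_one_for_uniform_pvalues():
    rng = np.random.default_rng(1)
    for _ in range(3):
        pi0 = estimate_pi0_slim(rng.uniform(size=10_000))
        assert 0.9 <= pi0 <= 1.0


def test_all_equal_pvalues_get_equal_qvalues():
    q, _ = slim_qvalues(np.full(100, 0.37))
    assert np.unique(q).size == 1


def test_mixture_signal_gets_small_q_and_bh_bound():
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.uniform(size=8_000), rng.uniform(0, 1e-8, 2_000)])
    q, pi0 = slim_qvalues(p)
    assert pi0 <= 1.0
    assert (q[p < 1e-6] < 0.01).all()
    # BH q-values (pi0 = 1) upper-bound SLIM q-values
    from statsmodels.stats.multitest import multipletests

    q_bh = multipletests(p, method="fdr_bh")[1]
    assert (q <= q_bh + 1e-12).all()


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(3)
    p = rng.beta(0.4, 1.0, 5_000)
    q, _ = slim_qvalues(p)
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-15).all()
    assert ((q >= 0) & (q <= 1)).all()


def test_small_input_falls_back_to_bh():
    with pytest.warns(UserWarning, match="Benjamini-Hochberg"):
        q, pi0 = slim_qvalues([0.01, 0.5, 0.9])
    assert pi0 == 1.0 and len(q) == 3


def test_invalid_pvalues_rejected():
    with pytest.raises(ValueError):
        slim_qvalues([0.1, 1.2])


# ---------------------------------------------------------------------------
# DMC calling and gene mapping


def result_table(rows):
    df = pd.DataFrame(rows, columns=["q", "diff"])
    df["p"] = df["q"]
    return df


def test_dmc_threshold_semantics():
    res = call_dmcs(result_table([(0.005, 25.0), (0.005, 19.9), (0.02, 60.0), (0.005, -25.0)]))
    assert list(res["status"]) == ["hyper", "ns", "ns", "hypo"]


def make_dmc_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "label", "gene_id", "status"])


def test_promoter_dmc_creates_flagged_dmg():
    dmg = map_dmcs_to_genes(make_dmc_table([("chr1", 10, "P250", "g1", "hyper")]))
    row = dmg.iloc[0]
    assert row["gene_id"] == "g1" and row["P250"] == 1
    assert bool(row["promoter"]) and row["hyper"] == 1 and row["hypo"] == 0


def test_intergenic_or_flank_only_dmcs_make_no_dmg():
    dmg = map_dmcs_to_genes(
        make_dmc_table(
            [("chr1", 10, "intergenic", ".", "hyper"), ("chr1", 20, "flanks", "g2", "hypo")]
        )
    )
    assert len(dmg) == 0


def test_unknown_label_raises():
    with pytest.raises(ValueError, match="unknown region label"):
        map_dmcs_to_genes(make_dmc_table([("chr1", 10, "enhancer", "g1", "hyper")]))


def test_gene_tallies_match_bruteforce_groupby():
    rng = np.random.default_rng(9)
    labels = np.array(["exon", "intron", "P250", "P1K", "P6K", "flanks"])
    rows = [
        ("chr1", i * 10, rng.choice(labels), f"g{rng.integers(0, 20)}",
         rng.choice(["hyper", "hypo"]))
        for i in range(400)
    ]
    dmcs = make_dmc_table(rows)
    dmg = map_dmcs_to_genes(dmcs).set_index("gene_id")
    body_prom = {"exon", "intron", "P250", "P1K", "P6K"}
    for gene, grp in dmcs.groupby("gene_id"):
        qualifies = grp["label"].isin(body_prom).any()
        assert (gene in dmg.index) == qualifies
        if qualifies:
            for lbl in [*body_prom, "flanks"]:
                assert dmg.loc[gene, lbl] == (grp["label"] == lbl).sum()
            assert dmg.loc[gene, "hyper"] == (grp["status"] == "hyper").sum()
            assert dmg.loc[gene, "hypo"] == (grp["status"] == "hypo").sum()


def test_overlap_counts_disjoint_and_identical():
    assert overlap_contrasts({"a": {"x"}, "b": {"y"}})["a&b"] == 0
    both = overlap_contrasts({"a": {"x", "y"}, "b": {"x", "y"}})
    assert both["a&b"] == 2 and both["a_only"] == 0


def test_overlap_counts_match_set_algebra():
    rng = np.random.default_rng(14)
    sets = {
        name: set(rng.choice(200, size=rng.integers(20, 120), replace=False).tolist())
        for name in ("SS:NC", "SO:NC", "SO:SS")
    }
    counts = overlap_contrasts(sets)
    a, b, c = sets["SS:NC"], sets["SO:NC"], sets["SO:SS"]
    assert counts["SS:NC&SO:NC"] == len(a & b)
    assert counts["SS:NC&SO:NC&SO:SS"] == len(a & b & c)
    assert counts["SO:SS_only"] == len(c - a - b)
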