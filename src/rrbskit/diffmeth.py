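"""Per-CpG differential methylation testing and DMC/DMG calling.

Each united CpG is tested with a binomial logistic regression of
methylated/unmethylated read counts on the group indicator; the p-value
comes from the likelihood-ratio (deviance) chi-square with one degree of
freedom.  With a single two-level factor the maximum-likelihood fit has
a closed form — the fitted probabilities are the coverage-weighted
pooled group proportions — so the deviance is computed exactly and
vectorised over sites rather than by iterative per-site fits.

Multiple testing uses q-values built on a sliding-linear-model (SLIM)
estimate of the null proportion pi0: the empirical CDF of the p-values
is locally regressed on a sliding window over [start, 1], where the
alternative component has exhausted its mass and the CDF slope equals
pi0.  A CpG is a differentially methylated cytosine (DMC) when q < 0.01
and the group difference is at least 20 percentage points; a gene with
at least one DMC in its body or promoter is a differentially methylated
gene (DMG).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .filtering import UnitedMatrix
from .regions import DMG_LABELS, PROMOTER_LABELS, REGION_LABELS

DMC_Q_MAX = 0.01
DMC_MIN_DIFF = 20.0


def _binom_loglik(meth, total, p):
    return xlogy(meth, p) + xlogy(total - meth, 1.0 - p)


def lrt_test(meth_t, cov_t, meth_c, cov_c):
    """Vectorised two-group binomial logistic-regression LRT.

    Arguments are pooled per-group (methylated, total-read) counts, one
    entry per site.  Returns (delta, stat, p) where delta is the percent
    methylation difference treatment minus control and stat the deviance
    chi-square.  Boundary proportions (0% or 100%) are handled exactly by
    the closed-form likelihood; no continuity correction is needed.
    """
    meth_t, cov_t = np.asarray(meth_t, float), np.asarray(cov_t, float)
    meth_c, cov_c = np.asarray(meth_c, float), np.asarray(cov_c, float)
    if np.any(cov_t <= 0) or np.any(cov_c <= 0):
        raise ValueError("every site needs positive pooled coverage in both groups")
    pt = meth_t / cov_t
    pc = meth_c / cov_c
    p0 = (meth_t + meth_c) / (cov_t + cov_c)
    ll_full = _binom_loglik(meth_t, cov_t, pt) + _binom_loglik(meth_c, cov_c, pc)
    ll_null = _binom_loglik(meth_t, cov_t, p0) + _binom_loglik(meth_c, cov_c, p0)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    return 100.0 * (pt - pc), stat, chi2.sf(stat, df=1)


def per_site_test(united: UnitedMatrix, treatment: str, control: str) -> pd.DataFrame:
    """Test every united site for the ``treatment`` vs ``control`` contrast.

    Group methylation pools counts across replicates (coverage-weighted).
    Returns one row per site with mean levels, difference (percentage
    points), deviance statistic and p-value.
    """
    mt, ct = united.pooled_counts(treatment)
    mc, cc = united.pooled_counts(control)
    diff, stat, p = lrt_test(mt.to_numpy(), ct.to_numpy(), mc.to_numpy(), cc.to_numpy())
    res = pd.DataFrame(
        {
            "mean_treatment": 100.0 * mt.to_numpy() / ct.to_numpy(),
            "mean_control": 100.0 * mc.to_numpy() / cc.to_numpy(),
            "diff": diff,
            "stat": stat,
            "p": p,
        },
        index=united.counts.index,
    )
    res.attrs["treatment"], res.attrs["control"] = treatment, control
    return res


# ---------------------------------------------------------------------------
# SLIM q-values


def estimate_pi0_slim(
    p_values, n_bins: int = 100, start: float = 0.1, n_windows: int = 10
) -> float:
    """Sliding-linear-model estimate of the null proportion pi0.

    The empirical CDF of the p-values is evaluated on a regular lambda
    grid; ordinary least-squares lines are fitted on ``n_windows``
    overlapping windows sliding across [start, 1].  Where the alternative
    component's CDF has flattened, the slope of the fit estimates pi0;
    the smallest window slope is taken (the flattest, most null-pure
    stretch) and clipped to [0, 1].
    """
    p = np.sort(np.asarray(p_values, float))
    lam = np.linspace(0.0, 1.0, n_bins + 1)
    cdf = np.searchsorted(p, lam, side="right") / len(p)
    width = (1.0 - start) / 2.0
    step = (1.0 - start - width) / max(n_windows - 1, 1)
    slopes = []
    for k in range(n_windows):
        lo = start + k * step
        m = (lam >= lo - 1e-12) & (lam <= lo + width + 1e-12)
        x, y = lam[m], cdf[m]
        slopes.append(np.polyfit(x, y, 1)[0])
    return float(np.clip(min(slopes), 0.0, 1.0))


def slim_qvalues(p_values, n_bins: int = 100, start: float = 0.1, n_windows: int = 10):
    """q-values from p-values via the SLIM pi0 estimate.

    q_(i) = pi0 * m * p_(i) / rank_i with maximal tie ranks, made
    monotone non-decreasing in p by a right-to-left running minimum.
    With fewer than 10 p-values the CDF is too coarse for the sliding
    fit; Benjamini-Hochberg is used instead (pi0 = 1) with a warning.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m < 10:
        warnings.warn("fewer than 10 p-values: falling back to Benjamini-Hochberg", stacklevel=2)
        return multipletests(p, method="fdr_bh")[1], 1.0
    pi0 = estimate_pi0_slim(p, n_bins=n_bins, start=start, n_windows=n_windows)
    order = np.argsort(p, kind="stable")
    ranks = np.searchsorted(p[order], p[order], side="right")  # maximal rank under ties
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, pi0


# ---------------------------------------------------------------------------
# DMC / DMG calling


def call_dmcs(
    results: pd.DataFrame, q_max: float = DMC_Q_MAX, min_diff: float = DMC_MIN_DIFF
) -> pd.DataFrame:
    """Attach q-values and hyper/hypo/ns status to a per-site result table.

    A site is a DMC iff q < ``q_max`` and |diff| >= ``min_diff`` points;
    the sign of the difference sets hyper (treatment above control) or
    hypo.
    """
    out = results.copy()
    if "q" not in out.columns:
        out["q"], out.attrs["pi0"] = slim_qvalues(out["p"].to_numpy())
    is_dmc = (out["q"] < q_max) & (out["diff"].abs() >= min_diff)
    out["status"] = np.where(is_dmc, np.where(out["diff"] > 0, "hyper", "hypo"), "ns")
    return out


def dmc_table(results: pd.DataFrame) -> pd.DataFrame:
    return results[results["status"] != "ns"]


def map_dmcs_to_genes(dmcs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene DMC tallies by sub-region, with hyper/hypo split.

    A gene is listed iff it has at least one DMC in the gene body or a
    promoter tier.  Flank DMCs never create a gene entry on their own,
    but are tallied for genes that qualify otherwise; intergenic DMCs map
    to no gene.
    """
    unknown = set(dmcs.get("label", pd.Series(dtype=object))) - set(REGION_LABELS)
    if unknown:
        raise ValueError(f"DMCs carry unknown region labels: {sorted(unknown)}")
    cols = list(DMG_LABELS) + ["flanks"]
    with_gene = dmcs[(dmcs["gene_id"] != ".") & (dmcs["label"] != "intergenic")]
    records = []
    for gene, grp in with_gene.groupby("gene_id"):
        by_label = grp["label"].value_counts()
        if sum(by_label.get(lbl, 0) for lbl in DMG_LABELS) == 0:
            continue  # flank-only gene: not a DMG
        rec = {"gene_id": gene}
        rec.update({lbl: int(by_label.get(lbl, 0)) for lbl in cols})
        rec["hyper"] = int((grp["status"] == "hyper").sum())
        rec["hypo"] = int((grp["status"] == "hypo").sum())
        rec["promoter"] = bool(sum(by_label.get(lbl, 0) for lbl in PROMOTER_LABELS))
        records.append(rec)
    return pd.DataFrame(records, columns=["gene_id", *cols, "hyper", "hypo", "promoter"])


def overlap_contrasts(dmg_sets: dict[str, set[str]]) -> dict[str, int]:
    """Venn-style intersection cardinalities over two or more gene sets.

    Returns sizes, all inclusive intersections, and the exclusive count
    unique to each contrast.
    """
    if len(dmg_sets) < 2:
        raise ValueError("need at least two contrasts")
    names = list(dmg_sets)
    out: dict[str, int] = {f"{n}": len(dmg_sets[n]) for n in names}
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(dmg_sets[n] for n in combo))
            out["&".join(combo)] = len(inter)
    for n in names:
        others = set().union(*(dmg_sets[m] for m in names if m != n))
        out[f"{n}_only"] = len(dmg_sets[n] - others)
    return out
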