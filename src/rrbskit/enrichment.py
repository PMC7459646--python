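"""Gene-set enrichment of differential methylation, three ways.

* ORA — hypergeometric over-representation of DMGs in each pathway.
* Wilcoxon — per pathway, a signed-rank test of paired per-site group
  methylation means (does the pathway's methylation shift as a whole?).
* KS-boot — a bootstrap Kolmogorov-Smirnov test of a pathway's per-site
  methylation differences against the background differences of all
  sites in the same genomic region, with a size-matched resampling null.

All three run per region scope (each region label plus "all") and are
Benjamini-Hochberg adjusted across pathways within a scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import REGION_LABELS

ENRICH_SCOPES = [*REGION_LABELS, "all"]


def _bh(df: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust the ``p`` column in place, ignoring NA rows."""
    df = df.copy()
    df["p_adj"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        df.loc[ok, "p_adj"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df


def pathway_members(pathway_map: pd.DataFrame) -> dict[str, set[str]]:
    return {pw: set(g["gene_id"]) for pw, g in pathway_map.groupby("pathway_id")}


def ora(dmgs: set[str], universe: set[str], pathway_map: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation per pathway.

    The universe is the set of genes that could have been called (those
    with at least one united CpG); pathways with no member in the
    universe are skipped.  p = P(X >= k) with k the DMG/pathway overlap,
    K the pathway size within the universe, n the DMG count, N the
    universe size.
    """
    if not dmgs <= universe:
        raise ValueError("DMG set must be a subset of the universe")
    N, n = len(universe), len(dmgs)
    rows = []
    for pw, members in sorted(pathway_members(pathway_map).items()):
        K = len(members & universe)
        if K == 0:
            continue
        k = len(members & dmgs)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway_id": pw, "test": "ORA", "overlap": k, "pathway_size": K, "statistic": float(k), "p": p})
    return _bh(pd.DataFrame(rows, columns=["pathway_id", "test", "overlap", "pathway_size", "statistic", "p"]))


def pathway_wilcoxon(
    sites: pd.DataFrame, pathway_map: pd.DataFrame, min_sites: int = 5
) -> pd.DataFrame:
    """Signed-rank test of paired per-site group means, per pathway.

    ``sites`` needs columns gene_id, mean_treatment, mean_control.  The
    pairing is per CpG site: each site contributes the difference of its
    two group methylation means.  Pathways with fewer than ``min_sites``
    usable (nonzero-difference) sites are reported NA and excluded from
    the BH adjustment.
    """
    diffs = (sites["mean_treatment"] - sites["mean_control"]).to_numpy()
    by_gene = sites.reset_index(drop=True).groupby("gene_id").indices
    rows = []
    for pw, members in sorted(pathway_members(pathway_map).items()):
        idx = np.concatenate([by_gene[g] for g in members if g in by_gene] or [np.array([], int)])
        d = diffs[idx.astype(int)]
        d = d[d != 0.0]
        if len(d) < min_sites:
            rows.append({"pathway_id": pw, "test": "Wilcox", "n_sites": len(d), "statistic": np.nan, "p": np.nan})
            continue
        stat, p = stats.wilcoxon(d)
        rows.append({"pathway_id": pw, "test": "Wilcox", "n_sites": len(d), "statistic": float(stat), "p": float(p)})
    return _bh(pd.DataFrame(rows, columns=["pathway_id", "test", "n_sites", "statistic", "p"]))


def _ks_distance(sample_sorted: np.ndarray, bg_sorted: np.ndarray) -> np.ndarray:
    """Sup-norm ECDF distance of each row of ``sample_sorted`` vs the background."""
    n = sample_sorted.shape[-1]
    N = len(bg_sorted)
    right = np.searchsorted(bg_sorted, sample_sorted, side="right") / N
    left = np.searchsorted(bg_sorted, sample_sorted, side="left") / N
    i = np.arange(n)
    d_plus = ((i + 1) / n - right).max(axis=-1)
    d_minus = (left - i / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def ks_boot(
    site_deltas: pd.DataFrame,
    pathway_map: pd.DataFrame,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap KS test of pathway methylation differences vs background.

    ``site_deltas`` needs columns gene_id and diff; the background is the
    diff of *all* rows passed in (scope the table to a region before
    calling).  For each pathway the observed KS distance between its
    sites' differences and the background is compared with ``n_iter``
    size-matched with-replacement draws from the background;
    p = (1 + #{D_boot >= D_obs}) / (n_iter + 1), which never returns 0.
    """
    bg = np.sort(site_deltas["diff"].to_numpy())
    if len(bg) == 0:
        raise ValueError("empty background")
    rng = np.random.default_rng(seed)
    by_gene = site_deltas.reset_index(drop=True).groupby("gene_id").indices
    rows = []
    for pw, members in sorted(pathway_members(pathway_map).items()):
        idx = np.concatenate([by_gene[g] for g in members if g in by_gene] or [np.array([], int)])
        if len(idx) == 0:
            raise ValueError(f"pathway {pw}: no sites in background")
        if len(idx) > len(bg):
            raise ValueError(f"pathway {pw}: background smaller than pathway")
        obs = np.sort(site_deltas["diff"].to_numpy()[idx.astype(int)])
        d_obs = float(_ks_distance(obs, bg))
        draws = np.sort(rng.choice(bg, size=(n_iter, len(obs)), replace=True), axis=1)
        d_boot = _ks_distance(draws, bg)
        p = (1.0 + float((d_boot >= d_obs - 1e-12).sum())) / (n_iter + 1.0)
        rows.append({"pathway_id": pw, "test": "KS-boot", "n_sites": len(obs), "statistic": d_obs, "p": p})
    return _bh(pd.DataFrame(rows, columns=["pathway_id", "test", "n_sites", "statistic", "p"]))


def run_enrichment(
    annotated_results: pd.DataFrame,
    pathway_map: pd.DataFrame,
    n_iter: int = 1000,
    seed: int = 0,
    scopes: list[str] | None = None,
) -> pd.DataFrame:
    """All three tests over every region scope, one stacked result table.

    ``annotated_results`` is a per-site table for one contrast carrying
    label, gene_id, mean_treatment, mean_control, diff and status.
    Within each scope the ORA universe is every gene with at least one
    united CpG in that scope and the significant set is every gene with
    at least one DMC there; Wilcoxon and KS-boot use the scope's sites
    directly.
    """
    out = []
    for scope in scopes or ENRICH_SCOPES:
        sub = (
            annotated_results
            if scope == "all"
            else annotated_results[annotated_results["label"] == scope]
        )
        genic = sub[sub["gene_id"] != "."]
        universe = set(genic["gene_id"])
        if not universe:
            continue
        pm = pathway_map[pathway_map["gene_id"].isin(universe)]
        if len(pm) == 0:
            continue
        sig = set(genic.loc[genic["status"] != "ns", "gene_id"])
        frames = [
            ora(sig, universe, pm),
            pathway_wilcoxon(genic, pm),
            ks_boot(genic, pm, n_iter=n_iter, seed=seed),
        ]
        for f in frames:
            f.insert(1, "region_scope", scope)
        out.extend(frames)
    return pd.concat(out, ignore_index=True)
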