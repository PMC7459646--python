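"""End-to-end orchestration: simulate -> filter -> unite -> annotate ->
differential methylation -> global patterns -> enrichment.

A run is driven by a :class:`RunConfig` whose threshold defaults are the
analysis constants used throughout the package (coverage > 10, 99.9th
percentile upper cut, q < 0.01, 20-point difference, 95th variance
percentile, t-SNE perplexity 2, 1000 KS-boot iterations).  Every stage
logs record counts in and out, and the manifest captures parameters,
per-stage counts and SHA-256 digests of each output so reruns can be
checked for bit-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffmeth, enrichment, io, patterns, regions
from .filtering import filter_by_coverage, unite
from .simulate import SimulationDesign, generate_genome, simulate_methylomes, simulate_pathway_map

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the analysis constants."""

    outdir: str = "rrbskit_run"
    seed: int = 0
    groups: tuple[str, ...] = ("NC", "SS", "SO")
    # input mode: simulate a dataset, or consume existing files
    simulate: bool = True
    design: dict = field(default_factory=dict)  # overrides for SimulationDesign
    coverage_files: dict = field(default_factory=dict)  # sample_id -> path
    sample_groups: dict = field(default_factory=dict)  # sample_id -> group
    gff: str | None = None
    pathways: str | None = None
    # thresholds
    min_coverage: int = 10
    upper_percentile: float = 99.9
    q_max: float = 0.01
    min_diff: float = 20.0
    variance_percentile: float = 95.0
    perplexity: float = 2.0
    ks_iterations: int = 1000

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for s, g in self.sample_groups.items():
            if g not in self.groups:
                raise ValueError(f"sample {s}: unknown group label {g!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        """(treatment, control) pairs: every later group against each earlier."""
        g = list(self.groups)
        return [(g[j], g[i]) for j in range(1, len(g)) for i in range(j)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    out = Path(config.outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "results").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _jsonable(asdict(config)), "stages": {}}

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        design = SimulationDesign(**{"seed": config.seed, "groups": config.groups, **config.design})
        genome = generate_genome(design)
        sim = simulate_methylomes(design, genome.cpg_sites)
        io.write_fasta(genome.sequences, out / "inputs" / "genome.fa")
        io.write_gff3(genome.transcripts, out / "inputs" / "genes.gff3")
        io.write_truth_table(sim.truth, out / "inputs" / "truth.tsv")
        for s in sim.samples:
            io.write_coverage(s, out / "inputs" / f"{s.sample_id}.cov")
        transcripts = genome.transcripts
        chrom_lengths = genome.chrom_lengths
        samples = sim.samples
        gene_ids = sorted({t.gene_id for t in transcripts})
        pathway_map = simulate_pathway_map(gene_ids, seed=config.seed)
        pathway_map.to_csv(out / "inputs" / "pathways.tsv", sep="\t", index=False)
        all_cpgs = genome.cpg_sites
    else:
        if not (config.coverage_files and config.gff and config.pathways):
            raise ValueError("non-simulated runs need coverage_files, gff and pathways")
        samples = [
            io.read_coverage(path, sample_id=sid, group=config.sample_groups[sid])
            for sid, path in config.coverage_files.items()
        ]
        transcripts = io.read_gff3(config.gff)
        pathway_map = io.read_pathway_map(config.pathways)
        margin = regions.FLANK_UP_END + 1
        chrom_lengths = {}
        for s in samples:
            for chrom, grp in s.records.groupby("chrom"):
                top = int(grp["pos"].max()) + margin
                chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), top)
        for t in transcripts:
            chrom_lengths[t.chrom] = max(
                chrom_lengths.get(t.chrom, 0), t.end + regions.FLANK_DOWN_LEN + 1
            )
        all_cpgs = None
    manifest["stages"]["input"] = {s.sample_id: len(s) for s in samples}

    # ---- filter ----------------------------------------------------------
    filtered = [
        filter_by_coverage(s, config.min_coverage, config.upper_percentile) for s in samples
    ]
    manifest["stages"]["filter"] = {s.sample_id: len(s) for s in filtered}

    # ---- annotation index ------------------------------------------------
    canonical = regions.select_canonical_isoforms(transcripts)
    rmap = regions.build_region_map(canonical, chrom_lengths)

    # ---- per-contrast differential methylation ---------------------------
    contrast_results: dict[str, pd.DataFrame] = {}
    dmg_tables: dict[str, pd.DataFrame] = {}
    for treatment, control in config.contrasts:
        name = f"{treatment}_vs_{control}"
        united = unite(filtered, (treatment, control))
        res = diffmeth.per_site_test(united, treatment, control)
        res["q"], pi0 = diffmeth.slim_qvalues(res["p"].to_numpy())
        res = diffmeth.call_dmcs(res, q_max=config.q_max, min_diff=config.min_diff)
        sites = res.index.to_frame(index=False)
        ann = rmap.annotate(sites[["chrom", "pos"]])
        res = res.reset_index()
        res["label"], res["gene_id"] = ann["label"].to_numpy(), ann["gene_id"].to_numpy()
        contrast_results[name] = res
        dmg = diffmeth.map_dmcs_to_genes(diffmeth.dmc_table(res))
        dmg_tables[name] = dmg
        res.to_csv(out / "results" / f"{name}.sites.tsv", sep="\t", index=False)
        dmg.to_csv(out / "results" / f"{name}.dmgs.tsv", sep="\t", index=False)
        manifest["stages"][name] = {
            "united_sites": len(res),
            "pi0": round(float(pi0), 6),
            "dmc": int((res["status"] != "ns").sum()),
            "hyper": int((res["status"] == "hyper").sum()),
            "hypo": int((res["status"] == "hypo").sum()),
            "dmg": len(dmg),
        }

    # ---- global patterns -------------------------------------------------
    united_all = unite(filtered, config.groups)
    pct = united_all.percent_matrix()
    hv = patterns.select_high_variance_sites(pct, config.variance_percentile)
    n_samples = pct.shape[1]
    if n_samples >= 4 and config.perplexity < (n_samples - 1) / 3:
        emb = patterns.embed_samples(hv, "tsne", config.perplexity, config.seed)
        emb.to_csv(out / "results" / "embedding_tsne.tsv", sep="\t")
    emb_pca = patterns.embed_samples(hv, "pca", seed=config.seed)
    emb_pca.to_csv(out / "results" / "embedding_pca.tsv", sep="\t")
    Z, corr = patterns.cluster_samples(pct)
    pd.DataFrame(Z, columns=["left", "right", "distance", "size"]).to_csv(
        out / "results" / "linkage.tsv", sep="\t", index=False
    )
    corr.to_csv(out / "results" / "correlation.tsv", sep="\t")
    manifest["stages"]["global"] = {
        "united_sites": len(pct),
        "high_variance_sites": len(hv),
        "samples": n_samples,
    }

    # ---- enrichment ------------------------------------------------------
    for name, res in contrast_results.items():
        enr = enrichment.run_enrichment(
            res, pathway_map, n_iter=config.ks_iterations, seed=config.seed
        )
        enr.to_csv(out / "results" / f"{name}.enrichment.tsv", sep="\t", index=False)
        manifest["stages"][f"{name}_enrichment"] = {"rows": len(enr)}

    # ---- summaries -------------------------------------------------------
    summary = summarize_run(contrast_results, dmg_tables, rmap, all_cpgs)
    for key, table in summary.items():
        table.to_csv(out / "results" / f"{key}.tsv", sep="\t", index=False)

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest["checksums"] = {str(p.relative_to(out)): _sha256(p) for p in files}
    with open(out / "results" / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def summarize_run(
    contrast_results: dict[str, pd.DataFrame],
    dmg_tables: dict[str, pd.DataFrame],
    rmap: regions.RegionMap,
    all_cpgs: pd.DataFrame | None,
) -> dict[str, pd.DataFrame]:
    """Report tables: regional distributions, per-region hyper/hypo DMC
    counts per contrast, Venn overlaps (body-or-promoter and
    promoter-only) and per-gene tallies with promoter markers."""
    out: dict[str, pd.DataFrame] = {}

    dist_rows = []
    if all_cpgs is not None and len(all_cpgs):
        frac = regions.region_distribution(rmap.annotate(all_cpgs))
        dist_rows.append(pd.DataFrame({"set": "genome", "label": frac.index, "fraction": frac.values}))
    for name, res in contrast_results.items():
        frac = regions.region_distribution(res)
        dist_rows.append(pd.DataFrame({"set": name, "label": frac.index, "fraction": frac.values}))
    out["region_distribution"] = pd.concat(dist_rows, ignore_index=True)

    rows = []
    for name, res in contrast_results.items():
        dmc = diffmeth.dmc_table(res)
        for label in regions.REGION_LABELS:
            sub = dmc[dmc["label"] == label]
            rows.append(
                {
                    "contrast": name,
                    "label": label,
                    "hyper": int((sub["status"] == "hyper").sum()),
                    "hypo": int((sub["status"] == "hypo").sum()),
                    "total": len(sub),
                }
            )
    out["dmc_by_region"] = pd.DataFrame(rows)

    if len(dmg_tables) >= 2:
        body_or_prom = {n: set(t["gene_id"]) for n, t in dmg_tables.items()}
        prom_only = {n: set(t.loc[t["promoter"], "gene_id"]) for n, t in dmg_tables.items()}
        venn_rows = [
            {"variant": "body_or_promoter", "region": k, "count": v}
            for k, v in diffmeth.overlap_contrasts(body_or_prom).items()
        ] + [
            {"variant": "promoter_only", "region": k, "count": v}
            for k, v in diffmeth.overlap_contrasts(prom_only).items()
        ]
        out["venn"] = pd.DataFrame(venn_rows)

    tallies = []
    for name, t in dmg_tables.items():
        t = t.copy()
        t.insert(0, "contrast", name)
        t["tally"] = [
            f"{h}/{p}" + ("^P" if pr else "")
            for h, p, pr in zip(t["hyper"], t["hypo"], t["promoter"])
        ]
        tallies.append(t)
    out["dmg_tallies"] = (
        pd.concat(tallies, ignore_index=True) if tallies else pd.DataFrame(columns=["contrast"])
    )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
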