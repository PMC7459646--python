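"""Synthetic genomes, gene models and bisulfite count data.

The generator emulates the study design the package is built for: three
parental dietary groups (NC control, SS and SO selenium-supplemented)
with four replicate fry-liver methylomes each.  A toy genome with
annotated genes supplies CpG positions; per-CpG counts follow a
beta-binomial model — baseline methylation drawn from a Beta
distribution, per-sample coverage negative-binomial, and an optional
within-group intra-class correlation ``rho`` (rho=0 recovers plain
binomial sampling).  A chosen subset of sites carries planted group
differences of a fixed size in percentage points; every planted site is
recorded in a truth table so downstream calls can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MethylationCallSet
from .regions import Transcript


class SizingError(ValueError):
    """Chromosomes too short to host the requested gene complement."""


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic experiment.

    Defaults mirror a small RRBS study: 3 diet groups x 4 replicates,
    mean CpG coverage 30 reads with negative-binomial spread, a mildly
    bimodal Beta(0.8, 0.8) baseline methylome, and planted group shifts
    of 30 percentage points (comfortably above the 20-point calling
    threshold).  ``within_group_overdispersion`` defaults to 0 so counts
    follow the binomial sampling model the per-site test assumes, which
    makes planted-truth benchmarks measure the procedure's intrinsic
    operating characteristics; set it above 0 to stress-test robustness
    to extra-binomial replicate variation.
    """

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_genes: int = 30
    groups: tuple[str, ...] = ("NC", "SS", "SO")
    samples_per_group: int = 4
    mean_coverage: float = 30.0
    coverage_dispersion: float = 8.0  # negative-binomial size; larger = tighter
    baseline_meth_alpha: float = 0.8
    baseline_meth_beta: float = 0.8
    within_group_overdispersion: float = 0.0  # intra-class correlation rho
    n_effect_sites: int = 300
    effect_size: float = 30.0  # percentage points
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if not (0 < self.effect_size <= 100):
            raise ValueError("effect_size must lie in (0, 100]")
        if not (0 <= self.within_group_overdispersion < 1):
            raise ValueError("within_group_overdispersion must lie in [0, 1)")
        if min(
            self.n_chromosomes,
            self.chrom_length,
            self.mean_coverage,
            self.coverage_dispersion,
            self.baseline_meth_alpha,
            self.baseline_meth_beta,
        ) <= 0 or min(self.n_genes, self.n_effect_sites) < 0:
            raise ValueError("design parameters must be positive")

    @property
    def control(self) -> str:
        return self.groups[0]

    @property
    def sample_ids(self) -> list[tuple[str, str]]:
        return [
            (f"{g}_{i + 1}", g) for g in self.groups for i in range(self.samples_per_group)
        ]


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    transcripts: list[Transcript]
    cpg_sites: pd.DataFrame  # columns chrom, pos (position of the plus-strand C)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class SimulatedMethylomes:
    samples: list[MethylationCallSet]
    truth: pd.DataFrame  # chrom, pos, affected_groups, direction, planted_delta
    group_pi: pd.DataFrame  # per-site true methylation level per group


def generate_genome(design: SimulationDesign) -> ToyGenome:
    """Random chromosomes with CpGs, plus gene models hosting isoforms.

    Gene loci are placed without overlap along each chromosome; roughly a
    third of genes carry a second, shorter, overlapping isoform so that
    canonical-isoform selection is exercised.  Deterministic under the
    design seed.
    """
    rng = np.random.default_rng(design.seed)
    bases = np.array(list("ACGT"))
    probs = np.array([0.29, 0.21, 0.21, 0.29])
    sequences = {
        f"chr{i + 1}": "".join(rng.choice(bases, size=design.chrom_length, p=probs))
        for i in range(design.n_chromosomes)
    }

    transcripts: list[Transcript] = []
    per_chrom = np.array_split(np.arange(design.n_genes), design.n_chromosomes)
    for ci, gene_idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(200, 1200))
        for gi in gene_idx:
            span = int(rng.integers(1500, 3501))
            if cursor + span > design.chrom_length - 200:
                raise SizingError(
                    f"chrom_length={design.chrom_length} too small for {design.n_genes} genes"
                )
            gid = f"gene{gi + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                _make_transcript(gid, f"{gid}.t1", chrom, cursor, cursor + span, strand, rng)
            )
            if rng.random() < 0.35:  # overlapping shorter isoform
                off = int(rng.integers(100, max(101, span // 3)))
                transcripts.append(
                    _make_transcript(
                        gid, f"{gid}.t2", chrom, cursor + off, cursor + span, strand, rng
                    )
                )
            cursor += span + int(rng.integers(200, 1001))

    rows = []
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        cg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": cg}))
    cpg = pd.concat(rows, ignore_index=True)
    return ToyGenome(sequences=sequences, transcripts=transcripts, cpg_sites=cpg)


def _make_transcript(gene_id, tx_id, chrom, start, end, strand, rng) -> Transcript:
    n_exons = int(rng.integers(2, 6))
    interior = np.sort(rng.choice(np.arange(start + 50, end - 50), 2 * (n_exons - 1), False))
    bounds = np.concatenate(([start], interior, [end]))
    exons = tuple((int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons))
    return Transcript(gene_id, tx_id, chrom, start, end, strand, exons)


def plan_effects(
    design: SimulationDesign, cpg_sites: pd.DataFrame, baseline_pi: np.ndarray, rng
) -> pd.DataFrame:
    """Choose planted sites, affected groups and shift directions.

    Half the sites are shifted up (hyper) and half down (hypo); to keep
    realized shifts near the nominal size, sites with the lower baselines
    take the upward shifts.  Each site affects one treatment group or,
    with equal probability, all of them.
    """
    n = design.n_effect_sites
    if n > len(cpg_sites):
        raise ValueError("n_effect_sites exceeds the number of CpG sites")
    if n == 0:
        return pd.DataFrame(columns=["site_idx", "affected_groups", "delta"])
    idx = rng.choice(len(cpg_sites), size=n, replace=False)
    order = idx[np.argsort(baseline_pi[idx], kind="stable")]
    delta = design.effect_size / 100.0
    deltas = np.where(np.arange(n) < n - n // 2, delta, -delta)  # low baselines go hyper
    treatments = list(design.groups[1:]) or list(design.groups)
    choices = [(t,) for t in treatments]
    if len(treatments) > 1:
        choices.append(tuple(treatments))
    picks = rng.integers(0, len(choices), size=n)
    return pd.DataFrame(
        {
            "site_idx": order,
            "affected_groups": [choices[p] for p in picks],
            "delta": deltas,
        }
    )


def simulate_methylomes(
    design: SimulationDesign,
    cpg_sites: pd.DataFrame,
    effect_spec: pd.DataFrame | None = None,
) -> SimulatedMethylomes:
    """Draw per-sample methylation calls with planted group differences.

    Per site, a baseline level pi ~ Beta(alpha, beta) is shared by all
    groups; planted sites shift the affected groups' level by the signed
    effect size, clipped to [0, 1] (the truth table records the realized,
    post-clipping shift).  Per sample, coverage is negative binomial and
    the methylated count beta-binomial with intra-class correlation rho.
    Sites drawing zero coverage are simply absent from that sample's
    calls, as in real coverage files.
    """
    if len(cpg_sites) == 0:
        raise ValueError("cpg_sites must be nonempty")
    rng = np.random.default_rng(design.seed + 1)
    n_sites = len(cpg_sites)
    pi0 = rng.beta(design.baseline_meth_alpha, design.baseline_meth_beta, size=n_sites)
    if effect_spec is None:
        effect_spec = plan_effects(design, cpg_sites, pi0, rng)

    group_pi = pd.DataFrame(
        {g: pi0.copy() for g in design.groups},
        index=pd.MultiIndex.from_frame(cpg_sites[["chrom", "pos"]]),
    )
    truth_rows = []
    for row in effect_spec.itertuples(index=False):
        i = int(row.site_idx)
        realized = None
        for g in row.affected_groups:
            shifted = float(np.clip(pi0[i] + row.delta, 0.0, 1.0))
            group_pi.iloc[i, group_pi.columns.get_loc(g)] = shifted
            realized = shifted - pi0[i]
        truth_rows.append(
            {
                "chrom": cpg_sites["chrom"].iloc[i],
                "pos": int(cpg_sites["pos"].iloc[i]),
                "affected_groups": ",".join(row.affected_groups),
                "direction": "hyper" if row.delta > 0 else "hypo",
                "planted_delta": round(100.0 * realized, 6),
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "affected_groups", "direction", "planted_delta"]
    )

    rho = design.within_group_overdispersion
    k = design.coverage_dispersion
    p_nb = k / (k + design.mean_coverage)
    samples = []
    for sample_id, group in design.sample_ids:
        cov = rng.negative_binomial(k, p_nb, size=n_sites)
        pi_g = group_pi[group].to_numpy()
        if rho > 0:
            interior = (pi_g > 0) & (pi_g < 1)
            p = pi_g.copy()
            c = (1.0 - rho) / rho
            p[interior] = rng.beta(pi_g[interior] * c, (1.0 - pi_g[interior]) * c)
        else:
            p = pi_g
        meth = rng.binomial(cov, p)
        keep = cov > 0
        rec = pd.DataFrame(
            {
                "chrom": cpg_sites["chrom"].to_numpy()[keep],
                "pos": cpg_sites["pos"].to_numpy()[keep],
                "strand": "+",
                "coverage": cov[keep],
                "methylated": meth[keep],
            }
        )
        samples.append(MethylationCallSet(sample_id=sample_id, group=group, records=rec))
    return SimulatedMethylomes(samples=samples, truth=truth, group_pi=group_pi)


def simulate_pathway_map(
    gene_ids: list[str], n_pathways: int = 15, mean_size: int = 8, seed: int = 0
) -> pd.DataFrame:
    """Random gene-to-pathway membership table for end-to-end runs."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_pathways):
        size = max(2, min(len(gene_ids), int(rng.poisson(mean_size))))
        for g in rng.choice(gene_ids, size=size, replace=False):
            rows.append({"gene_id": g, "pathway_id": f"pw{p + 1:03d}", "pathway_name": f"pathway {p + 1}"})
    return pd.DataFrame(rows)
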