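"""Genomic region model for CpG annotation.

Every CpG on the genome receives exactly one label drawn from seven
mutually exclusive region classes.  Gene bodies are split into exon and
intron; promoters are tiered by distance from the transcription start
site (TSS) into a proximal (P250, 1-250 bp), core (P1K, 251-1000 bp) and
distal (P6K, 1001-6000 bp) band; ``flanks`` combine the 6001-10,000 bp
band upstream of the TSS with 10 kb downstream of the mRNA 3' end;
everything else is intergenic.  When a site falls inside regions of
several genes the label is resolved by the fixed precedence

    exon > intron > P250 > P1K > P6K > flanks > intergenic

so the labels always partition any site set.

All coordinates are 0-based half-open internally; GFF3 and Bismark
coverage coordinates (1-based inclusive) are converted at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

# Region labels in precedence order (highest first).
REGION_LABELS = ["exon", "intron", "P250", "P1K", "P6K", "flanks", "intergenic"]
PROMOTER_LABELS = ("P250", "P1K", "P6K")
#: Labels whose DMCs qualify a gene as differentially methylated.
DMG_LABELS = ("exon", "intron", "P250", "P1K", "P6K")

# Distances (bp) from the TSS delimiting the promoter tiers and the
# upstream flank, and the length of the downstream flank.
P250_END = 250
P1K_END = 1000
P6K_END = 6000
FLANK_UP_END = 10_000
FLANK_DOWN_LEN = 10_000


class AnnotationError(ValueError):
    """Raised for structurally invalid gene models or unknown chromosomes."""


@dataclass(frozen=True)
class Transcript:
    """A single mRNA isoform with its exon structure.

    ``start``/``end`` delimit the mRNA span, 0-based half-open; ``exons``
    is a tuple of (start, end) pairs contained in that span.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(
                f"transcript {self.transcript_id} of gene {self.gene_id} has no exons"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon [{s},{e}) outside mRNA "
                    f"[{self.start},{self.end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site (the 5' base)."""
        return self.start if self.strand == "+" else self.end - 1


# A canonical gene model is simply the transcript retained for its gene.
GeneModel = Transcript


def select_canonical_isoforms(transcripts: list[Transcript]) -> list[GeneModel]:
    """Keep one mRNA per gene: the longest, ties broken by transcript id.

    Overlap between isoforms of *different* genes is left alone here; such
    collisions are resolved per CpG by the label precedence instead.
    """
    best: dict[str, Transcript] = {}
    for tx in transcripts:
        cur = best.get(tx.gene_id)
        if cur is None or (tx.length, _neg_lex(tx.transcript_id)) > (
            cur.length,
            _neg_lex(cur.transcript_id),
        ):
            best[tx.gene_id] = tx
    return [best[g] for g in sorted(best)]


def _neg_lex(s: str):
    # sort key making the lexicographically *smallest* id win at equal length
    return tuple(-ord(c) for c in s)


def _gene_region_intervals(model: GeneModel, chrom_len: int):
    """Yield (label, start, end) for one canonical gene, clipped to the chromosome.

    Promoter tiers extend upstream of the TSS along the annotated strand;
    for minus-strand genes "upstream" runs rightward in genome coordinates.
    """
    exons = sorted(model.exons)
    for s, e in exons:
        yield "exon", s, e
    # introns: gaps between consecutive exons within the mRNA span
    for (_, e1), (s2, _) in zip(exons, exons[1:]):
        if s2 > e1:
            yield "intron", e1, s2
    if model.strand == "+":
        t = model.start  # TSS; promoter occupies [t - d, t)
        tiers = [
            ("P250", t - P250_END, t),
            ("P1K", t - P1K_END, t - P250_END),
            ("P6K", t - P6K_END, t - P1K_END),
            ("flanks", t - FLANK_UP_END, t - P6K_END),
            ("flanks", model.end, model.end + FLANK_DOWN_LEN),
        ]
    else:
        t = model.end  # TSS base is end-1; first upstream base is `end`
        tiers = [
            ("P250", t, t + P250_END),
            ("P1K", t + P250_END, t + P1K_END),
            ("P6K", t + P1K_END, t + P6K_END),
            ("flanks", t + P6K_END, t + FLANK_UP_END),
            ("flanks", model.start - FLANK_DOWN_LEN, model.start),
        ]
    for label, s, e in tiers:
        s, e = max(s, 0), min(e, chrom_len)
        if s < e:
            yield label, s, e


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Union of possibly overlapping intervals as sorted disjoint arrays."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


@dataclass
class RegionMap:
    """Per-chromosome interval index of labelled regions.

    ``merged`` holds, per chromosome and label, the union of that label's
    intervals (for fast membership tests); ``trees`` keeps per-gene
    attribution so an annotated CpG can be traced to a gene id.
    """

    chrom_lengths: dict[str, int]
    models: list[GeneModel] = field(default_factory=list)
    merged: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)
    trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)

    def annotate(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Label sites (columns ``chrom``, ``pos``) by region and gene.

        Returns a copy with ``label`` and ``gene_id`` columns (gene id is
        "." for intergenic and flank/promoter sites outside any gene only
        when no gene owns the winning interval).
        """
        out = sites.copy()
        labels = np.full(len(out), "intergenic", dtype=object)
        genes = np.full(len(out), ".", dtype=object)
        pos = out["pos"].to_numpy()
        for chrom, idx in out.groupby("chrom", sort=False).indices.items():
            if chrom not in self.chrom_lengths:
                raise AnnotationError(f"unknown chromosome {chrom!r}")
            p = pos[idx]
            unassigned = np.ones(len(idx), dtype=bool)
            per_label = self.merged.get(chrom, {})
            for label in REGION_LABELS[:-1]:
                if label not in per_label or not unassigned.any():
                    continue
                starts, ends = per_label[label]
                j = np.searchsorted(starts, p, side="right") - 1
                inside = (j >= 0) & (p < ends[np.clip(j, 0, len(ends) - 1)])
                hit = inside & unassigned
                if hit.any():
                    labels[idx[hit]] = label
                    tree = self.trees[chrom][label]
                    for k in np.flatnonzero(hit):
                        ivs = tree[int(p[k])]
                        if ivs:
                            genes[idx[k]] = min(iv.data for iv in ivs)
                    unassigned &= ~inside
        out["label"] = labels
        out["gene_id"] = genes
        return out


def build_region_map(models: list[GeneModel], chrom_lengths: dict[str, int]) -> RegionMap:
    """Index canonical gene models into a :class:`RegionMap`.

    Requires one mRNA per gene (run :func:`select_canonical_isoforms`
    first) and every TSS within its chromosome.
    """
    seen: set[str] = set()
    raw: dict[str, dict[str, list[tuple[int, int, str]]]] = {}
    for m in models:
        if m.gene_id in seen:
            raise AnnotationError(f"gene {m.gene_id} has multiple models; select isoforms first")
        seen.add(m.gene_id)
        if m.chrom not in chrom_lengths:
            raise AnnotationError(f"gene {m.gene_id}: unknown chromosome {m.chrom}")
        clen = chrom_lengths[m.chrom]
        if not (0 <= m.start and m.end <= clen):
            raise AnnotationError(
                f"gene {m.gene_id}: mRNA [{m.start},{m.end}) outside chromosome bounds"
            )
        store = raw.setdefault(m.chrom, {})
        for label, s, e in _gene_region_intervals(m, clen):
            store.setdefault(label, []).append((s, e, m.gene_id))

    rm = RegionMap(chrom_lengths=dict(chrom_lengths), models=list(models))
    for chrom, per_label in raw.items():
        rm.merged[chrom] = {}
        rm.trees[chrom] = {}
        for label, ivs in per_label.items():
            starts = np.array([s for s, _, _ in ivs])
            ends = np.array([e for _, e, _ in ivs])
            rm.merged[chrom][label] = _merge_intervals(starts, ends)
            rm.trees[chrom][label] = IntervalTree.from_tuples((s, e, g) for s, e, g in ivs)
    return rm


def annotate_sites(sites: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    """Label a site table (columns ``chrom``, ``pos``) against a region map."""
    return region_map.annotate(sites)


def annotate_cpg(chrom: str, pos: int, region_map: RegionMap) -> tuple[str, str]:
    """Label a single CpG; returns (region label, gene id or ".")."""
    row = region_map.annotate(pd.DataFrame({"chrom": [chrom], "pos": [pos]}))
    return str(row["label"].iloc[0]), str(row["gene_id"].iloc[0])


def region_distribution(labeled: pd.DataFrame) -> pd.Series:
    """Fraction of sites per region label; fractions sum to one.

    Reported for whatever site set is passed in, so the same call serves
    the full-genome CpG complement and the assayed (mapped) subset.
    """
    if len(labeled) == 0:
        raise ValueError("region_distribution: empty site set")
    frac = labeled["label"].value_counts(normalize=True)
    return frac.reindex(REGION_LABELS, fill_value=0.0)
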