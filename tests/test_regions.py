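import numpy as np
import pandas as pd
import pytest

from rrbskit.regions import (
    REGION_LABELS,
    AnnotationError,
    Transcript,
    annotate_cpg,
    build_region_map,
    region_distribution,
    select_canonical_isoforms,
    _gene_region_intervals,
)


def tx(gene, tid, start, end, strand="+", chrom="chr1", exons=None):
    return Transcript(gene, tid, chrom, start, end, strand, exons or ((start, end),))


# ---------------------------------------------------------------------------
# canonical isoform selection


def test_longest_isoform_wins():
    models = [tx("g1", "g1.a", 1000, 1900), tx("g1", "g1.b", 1000, 2200)]
    (kept,) = select_canonical_isoforms(models)
    assert kept.transcript_id == "g1.b"


def test_single_isoform_unchanged():
    models = [tx("g1", "g1.a", 1000, 1900)]
    assert select_canonical_isoforms(models) == models


def test_length_ties_break_lexicographically():
    models = [tx("g1", "g1.b", 1000, 1900), tx("g1", "g1.a", 2000, 2900)]
    (kept,) = select_canonical_isoforms(models)
    assert kept.transcript_id == "g1.a"


def test_selection_matches_argmax_oracle():
    rng = np.random.default_rng(4)
    models = []
    for gi in range(50):
        for ti in range(rng.integers(1, 4)):
            s = int(rng.integers(0, 50_000))
            models.append(tx(f"g{gi}", f"g{gi}.t{ti}", s, s + int(rng.integers(100, 5000))))
    kept = {m.gene_id: m.transcript_id for m in select_canonical_isoforms(models)}
    for gi in range(50):
        cand = [m for m in models if m.gene_id == f"g{gi}"]
        best = sorted(cand, key=lambda m: (-m.length, m.transcript_id))[0]
        assert kept[f"g{gi}"] == best.transcript_id


def test_transcript_without_exons_rejected():
    with pytest.raises(AnnotationError):
        Transcript("g1", "g1.a", "chr1", 0, 100, "+", ())


# ---------------------------------------------------------------------------
# promoter geometry


def test_plus_strand_promoter_tiers_upstream_of_tss():
    gene = tx("g1", "g1.a", 10_000, 12_000)
    rm = build_region_map([gene], {"chr1": 50_000})
    # P250 covers [9750, 10000): 1-250 bp upstream of the TSS
    assert annotate_cpg("chr1", 9_750, rm)[0] == "P250"
    assert annotate_cpg("chr1", 9_999, rm)[0] == "P250"
    assert annotate_cpg("chr1", 9_749, rm)[0] == "P1K"
    assert annotate_cpg("chr1", 9_000, rm)[0] == "P1K"
    assert annotate_cpg("chr1", 8_999, rm)[0] == "P6K"
    assert annotate_cpg("chr1", 4_000, rm)[0] == "P6K"
    assert annotate_cpg("chr1", 3_999, rm)[0] == "flanks"
    assert annotate_cpg("chr1", 0, rm)[0] == "flanks"
    assert annotate_cpg("chr1", 12_000, rm)[0] == "flanks"  # downstream of 3' end
    assert annotate_cpg("chr1", 21_999, rm)[0] == "flanks"
    assert annotate_cpg("chr1", 22_000, rm)[0] == "intergenic"


def test_minus_strand_promoter_mirrors_right_of_tss():
    gene = tx("g1", "g1.a", 10_000, 12_000, strand="-")
    rm = build_region_map([gene], {"chr1": 50_000})
    assert annotate_cpg("chr1", 12_000, rm)[0] == "P250"
    assert annotate_cpg("chr1", 12_249, rm)[0] == "P250"
    assert annotate_cpg("chr1", 12_250, rm)[0] == "P1K"
    assert annotate_cpg("chr1", 9_999, rm)[0] == "flanks"  # downstream of 3' end (left)


def test_promoter_clipped_at_chromosome_start():
    gene = tx("g1", "g1.a", 100, 1_500)
    rm = build_region_map([gene], {"chr1": 50_000})
    for label, ivs in rm.merged["chr1"].items():
        assert (ivs[0] >= 0).all(), label
    assert annotate_cpg("chr1", 0, rm)[0] == "P250"


def test_tss_outside_chromosome_raises():
    gene = tx("g1", "g1.a", 10_000, 12_000)
    with pytest.raises(AnnotationError):
        build_region_map([gene], {"chr1": 11_000})


def test_duplicate_gene_models_rejected():
    models = [tx("g1", "g1.a", 0, 1000), tx("g1", "g1.b", 0, 2000)]
    with pytest.raises(AnnotationError):
        build_region_map(models, {"chr1": 50_000})


# ---------------------------------------------------------------------------
# precedence


def test_exon_beats_promoter_of_other_gene():
    a = tx("gA", "gA.t", 5_000, 8_000)  # exon across span
    b = tx("gB", "gB.t", 8_100, 9_000)  # P250 of gB covers [7850, 8100)
    rm = build_region_map([a, b], {"chr1": 50_000})
    label, gene = annotate_cpg("chr1", 7_900, rm)
    assert label == "exon" and gene == "gA"


def test_far_from_any_gene_is_intergenic():
    gene = tx("g1", "g1.a", 10_000, 12_000)
    rm = build_region_map([gene], {"chr1": 100_000})
    assert annotate_cpg("chr1", 40_000, rm) == ("intergenic", ".")


def test_unknown_chromosome_raises(toy_genome):
    rm = build_region_map(
        select_canonical_isoforms(toy_genome.transcripts), toy_genome.chrom_lengths
    )
    with pytest.raises(AnnotationError):
        rm.annotate(pd.DataFrame({"chrom": ["chrZ"], "pos": [10]}))


def brute_force_labels(models, chrom_lengths, sites):
    """Independent oracle: collect every labelled interval of every gene and
    apply the precedence ordering per site by exhaustive overlap."""
    rank = {lbl: i for i, lbl in enumerate(REGION_LABELS)}
    per_chrom = {}
    for m in models:
        for label, s, e in _gene_region_intervals(m, chrom_lengths[m.chrom]):
            per_chrom.setdefault(m.chrom, []).append((s, e, rank[label]))
    out = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        ivs = per_chrom.get(chrom, [])
        best = rank["intergenic"]
        for s, e, r in ivs:
            if s <= pos < e and r < best:
                best = r
        out.append(REGION_LABELS[best])
    return out


def test_annotation_matches_bruteforce_overlap_oracle(toy_genome):
    canonical = select_canonical_isoforms(toy_genome.transcripts)
    rm = build_region_map(canonical, toy_genome.chrom_lengths)
    rng = np.random.default_rng(8)
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": rng.integers(0, toy_genome.chrom_lengths["chr1"], 5_000)}
    )
    got = rm.annotate(sites)["label"].tolist()
    expected = brute_force_labels(canonical, toy_genome.chrom_lengths, sites)
    assert got == expected


def test_annotation_is_idempotent(toy_genome):
    rm = build_region_map(
        select_canonical_isoforms(toy_genome.transcripts), toy_genome.chrom_lengths
    )
    first = rm.annotate(toy_genome.cpg_sites)
    again = rm.annotate(first[["chrom", "pos"]])
    assert first["label"].tolist() == again["label"].tolist()
    assert first["gene_id"].tolist() == again["gene_id"].tolist()


def test_strand_reflection_preserves_labels(toy_genome):
    """Mirroring the genome (coordinates reversed, strands flipped) must
    leave every site's label unchanged."""
    canonical = select_canonical_isoforms(toy_genome.transcripts)
    L = toy_genome.chrom_lengths["chr1"]
    mirrored = [
        Transcript(
            m.gene_id, m.transcript_id, m.chrom, L - m.end, L - m.start,
            "-" if m.strand == "+" else "+",
            tuple(sorted((L - e, L - s) for s, e in m.exons)),
        )
        for m in canonical
    ]
    rm = build_region_map(canonical, toy_genome.chrom_lengths)
    rm_mir = build_region_map(mirrored, toy_genome.chrom_lengths)
    sites = toy_genome.cpg_sites.head(2_000)
    mir_sites = sites.assign(pos=L - 1 - sites["pos"])
    assert rm.annotate(sites)["label"].tolist() == rm_mir.annotate(mir_sites)["label"].tolist()


# ---------------------------------------------------------------------------
# region distribution


def test_distribution_all_intergenic():
    rm = build_region_map([], {"chr1": 10_000})
    ann = rm.annotate(pd.DataFrame({"chrom": "chr1", "pos": np.arange(100)}))
    dist = region_distribution(ann)
    assert dist["intergenic"] == 1.0 and dist.drop("intergenic").sum() == 0.0


def test_distribution_sums_to_one_and_is_scale_invariant(toy_genome):
    rm = build_region_map(
        select_canonical_isoforms(toy_genome.transcripts), toy_genome.chrom_lengths
    )
    ann = rm.annotate(toy_genome.cpg_sites)
    dist = region_distribution(ann)
    assert abs(dist.sum() - 1.0) < 1e-12
    doubled = region_distribution(pd.concat([ann, ann], ignore_index=True))
    pd.testing.assert_series_equal(dist, doubled)


def test_distribution_rejects_empty_input():
    with pytest.raises(ValueError):
        region_distribution(pd.DataFrame(columns=["label"]))
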