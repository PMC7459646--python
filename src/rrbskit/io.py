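"""Readers and writers for the plain-text formats the pipeline consumes.

Bismark coverage files (``.cov``) carry one methylation call per line:
chromosome, 1-based start, 1-based end, percent methylation, methylated
count, unmethylated count.  Internally positions are 0-based; conversion
happens here and nowhere else.  Gene models travel as GFF3 with
gene/mRNA/exon features, genomes as FASTA, raw reads as FASTQ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import AnnotationError, Transcript

COV_COLUMNS = ["chrom", "pos", "strand", "coverage", "methylated"]


class CoverageFormatError(ValueError):
    """Malformed Bismark coverage row; message carries the line number."""


@dataclass
class MethylationCallSet:
    """Per-sample CpG methylation calls.

    ``records`` columns: chrom, pos (0-based), strand, coverage,
    methylated.  One row per (chrom, pos, strand).
    """

    sample_id: str
    group: str
    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COV_COLUMNS))

    def __post_init__(self) -> None:
        r = self.records
        if len(r):
            if (r["methylated"] > r["coverage"]).any():
                raise ValueError(f"sample {self.sample_id}: methylated count exceeds coverage")
            if (r["coverage"] < 0).any() or (r["methylated"] < 0).any():
                raise ValueError(f"sample {self.sample_id}: negative counts")
            if r.duplicated(["chrom", "pos", "strand"]).any():
                raise ValueError(f"sample {self.sample_id}: duplicate site records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def percent_methylation(self) -> pd.Series:
        r = self.records
        return 100.0 * r["methylated"] / r["coverage"]


def read_coverage(path, sample_id: str | None = None, group: str = "") -> MethylationCallSet:
    """Parse a Bismark ``.cov`` file into a :class:`MethylationCallSet`.

    The reported percent-methylation column is cross-checked against the
    counts; a deviation beyond 0.5 percentage points raises a warning
    (the counts win).  The coverage dialect has no strand column, so
    strand is recorded as ".".
    """
    path = Path(path)
    sample_id = sample_id or path.stem.replace(".cov", "")
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise CoverageFormatError(f"{path}:{ln}: expected 6 tab-separated fields")
            try:
                chrom, start, end, pct = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                meth, unmeth = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise CoverageFormatError(f"{path}:{ln}: {exc}") from None
            cov = meth + unmeth
            if meth > cov or meth < 0 or unmeth < 0:
                raise CoverageFormatError(f"{path}:{ln}: invalid counts {meth}/{unmeth}")
            if cov > 0 and abs(pct - 100.0 * meth / cov) > 0.5:
                warnings.warn(
                    f"{path}:{ln}: reported %methylation {pct} disagrees with counts",
                    stacklevel=2,
                )
            rows.append((chrom, start - 1, ".", cov, meth))
    rec = pd.DataFrame(rows, columns=COV_COLUMNS)
    return MethylationCallSet(sample_id=sample_id, group=group, records=rec)


def write_coverage(calls: MethylationCallSet, path) -> None:
    """Write calls in the Bismark coverage dialect (1-based inclusive)."""
    r = calls.records
    with np.errstate(invalid="ignore"):
        pct = np.where(r["coverage"] > 0, 100.0 * r["methylated"] / r["coverage"], 0.0)
    out = pd.DataFrame(
        {
            "chrom": r["chrom"],
            "start": r["pos"] + 1,
            "end": r["pos"] + 1,
            "pct": np.round(pct, 6),
            "meth": r["methylated"],
            "unmeth": r["coverage"] - r["methylated"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA / GFF3


def write_fasta(sequences: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(transcripts: list[Transcript], path) -> None:
    """Write gene/mRNA/exon features, 1-based inclusive coordinates."""
    genes: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            txs = genes[gid]
            gs = min(t.start for t in txs)
            ge = max(t.end for t in txs)
            chrom, strand = txs[0].chrom, txs[0].strand
            fh.write(
                f"{chrom}\ttoy\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\tID={gid}\n"
            )
            for tx in sorted(txs, key=lambda t: t.transcript_id):
                fh.write(
                    f"{chrom}\ttoy\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t{strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gid}\n"
                )
                for i, (es, ee) in enumerate(sorted(tx.exons), start=1):
                    fh.write(
                        f"{chrom}\ttoy\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                        f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}\n"
                    )


def read_gff3(path) -> list[Transcript]:
    """Load all mRNA isoforms (with exons) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for mrna in db.features_of_type("mRNA"):
        exons = tuple(
            sorted((ex.start - 1, ex.end) for ex in db.children(mrna, featuretype="exon"))
        )
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.attributes.get("Parent", [mrna.id])[0]
        if not exons:
            raise AnnotationError(f"mRNA {mrna.id} has no exons")
        out.append(
            Transcript(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                start=mrna.start - 1,
                end=mrna.end,
                strand=mrna.strand,
                exons=exons,
            )
        )
    return out


# ---------------------------------------------------------------------------
# FASTQ digestion-signature filter

#: 5' trinucleotides compatible with an MspI (C^CGG) or TaqI (T^CGA) cut in
#: bisulfite-converted reads: the first C of the overhang may read C or T.
DIGESTION_SIGNATURES = frozenset({"CGG", "TGG", "CGA", "TGA"})


def filter_reads_by_digestion(
    fastq_in,
    fastq_out,
    max_len: int = 50,
    signatures: frozenset[str] = DIGESTION_SIGNATURES,
) -> tuple[int, int]:
    """Keep reads whose 5' end matches a restriction signature; trim to ``max_len``.

    Returns (n_kept, n_total).  Malformed records raise with the record index.
    """
    kept = total = 0
    with open(fastq_out, "w") as out:
        try:
            for total, rec in enumerate(SeqIO.parse(str(fastq_in), "fastq"), start=1):
                if str(rec.seq[:3]).upper() in signatures:
                    kept += 1
                    SeqIO.write(rec[:max_len], out, "fastq")
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ near record {total + 1}: {exc}") from None
    return kept, total


# ---------------------------------------------------------------------------
# Tables


def read_pathway_map(path) -> pd.DataFrame:
    """Read a gene-to-pathway mapping TSV (gene_id, pathway_id[, pathway_name])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "pathway_id"}
    if not required <= set(df.columns):
        raise ValueError(f"pathway map must have columns {sorted(required)}")
    return df


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
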