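"""Per-sample coverage filtering and site uniting across samples.

Sites are discarded when read depth is <= 10 (unreliable calls) or
strictly above the sample's own 99.9th coverage percentile (likely
PCR-duplicated or repetitive loci).  Both cuts are evaluated on the raw
per-sample coverage distribution.  The unite step then intersects the
surviving sites across every sample of the groups being compared, so
each retained CpG has counts in all samples.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import MethylationCallSet

logger = logging.getLogger(__name__)

SITE_KEY = ["chrom", "pos", "strand"]


class EmptyIntersectionError(ValueError):
    """No CpG site is covered in every sample of the contrast."""


def filter_by_coverage(
    calls: MethylationCallSet,
    min_exclusive: int = 10,
    upper_percentile: float = 99.9,
) -> MethylationCallSet:
    """Drop sites with coverage <= ``min_exclusive`` or above the percentile cut.

    The percentile is computed on this sample's own coverage values with
    linear interpolation; the upper cut is strict, so a sample with
    constant coverage loses nothing to it.
    """
    if len(calls) == 0:
        raise ValueError("filter_by_coverage: empty call set")
    cov = calls.records["coverage"].to_numpy()
    upper = float(np.percentile(cov, upper_percentile))
    keep = (cov > min_exclusive) & (cov <= upper)
    kept = calls.records.loc[keep].reset_index(drop=True)
    logger.info(
        "coverage filter %s: kept %d/%d sites (cutoffs >%d, <=%.1f)",
        calls.sample_id, len(kept), len(calls), min_exclusive, upper,
    )
    if len(kept) == 0:
        warnings.warn(f"sample {calls.sample_id}: coverage filter removed every site", stacklevel=2)
    return MethylationCallSet(sample_id=calls.sample_id, group=calls.group, records=kept)


class UnitedMatrix:
    """Counts for the sites shared by every sample of the selected groups.

    ``counts`` is indexed by (chrom, pos, strand) with a two-level column
    index (sample id, {"coverage", "methylated"}); ``groups`` maps sample
    id to group label.
    """

    def __init__(self, counts: pd.DataFrame, groups: dict[str, str]):
        self.counts = counts
        self.groups = dict(groups)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def percent_matrix(self) -> pd.DataFrame:
        """Sites x samples matrix of percent methylation."""
        meth = self.counts.xs("methylated", axis=1, level=1)
        cov = self.counts.xs("coverage", axis=1, level=1)
        return 100.0 * meth / cov

    def pooled_counts(self, group: str) -> tuple[pd.Series, pd.Series]:
        """Coverage-weighted pooled (methylated, total) counts per site."""
        ids = self.samples_in(group)
        meth = self.counts.loc[:, [(s, "methylated") for s in ids]].sum(axis=1)
        cov = self.counts.loc[:, [(s, "coverage") for s in ids]].sum(axis=1)
        return meth, cov


def unite(samples: list[MethylationCallSet], groups: list[str] | tuple[str, ...]) -> UnitedMatrix:
    """Intersect filtered call sets across all samples of ``groups``.

    Every group must contribute at least one sample; a site survives only
    if present in every selected sample.
    """
    chosen = [s for s in samples if s.group in groups]
    for g in groups:
        if not any(s.group == g for s in chosen):
            raise ValueError(f"no samples for group {g!r}")
    frames = []
    for s in chosen:
        f = s.records.set_index(SITE_KEY)[["coverage", "methylated"]]
        f.columns = pd.MultiIndex.from_product([[s.sample_id], f.columns])
        frames.append(f)
    merged = pd.concat(frames, axis=1, join="inner").sort_index()
    if len(merged) == 0:
        raise EmptyIntersectionError(
            "no site is covered in every sample; consider a lower coverage threshold"
        )
    logger.info("unite over %s: %d shared sites across %d samples", list(groups), len(merged), len(chosen))
    return UnitedMatrix(counts=merged, groups={s.sample_id: s.group for s in chosen})
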