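"""Risk-locus chromatin-accessibility normalization.

Pseudobulked ATAC peak counts per (donor, region, cell class) sample are put
through four transformations: (1) CPM normalization within each sample,
(2) per risk locus, summation of the CPM of all peaks overlapping the locus
by at least one base and division by the total length of those peaks,
(3) averaging over samples within each (region, cell class, population
group) combination, and (4) division by the maximum over all combinations
for that locus, so plotted values lie in [0, 1] with the most accessible
combination at exactly 1.

Intervals follow the BED convention (0-based, half-open); prose coordinates
quoted 1-based inclusive convert as (start-1, end) on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    @classmethod
    def from_one_based(cls, chrom: str, start: int, end: int, name: str = "") -> "GenomicInterval":
        """Convert 1-based inclusive prose coordinates to BED."""
        return cls(chrom=chrom, start=start - 1, end=end, name=name)

    def to_one_based(self) -> tuple[str, int, int]:
        return self.chrom, self.start + 1, self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least one shared base (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start


def cpm_normalize(peak_counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample row to counts-per-million; zero-total samples dropped."""
    totals = peak_counts.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.all():
        import warnings

        warnings.warn(
            f"excluding {(~nonzero).sum()} zero-total sample(s)", stacklevel=2
        )
    sub = peak_counts.loc[nonzero]
    return sub.div(sub.sum(axis=1), axis=0) * 1e6


def locus_values(
    cpm_table: pd.DataFrame,
    peaks: dict[str, GenomicInterval],
    loci: list[GenomicInterval],
    sample_meta: pd.DataFrame,
    clip: bool = False,
) -> pd.DataFrame:
    """Normalized accessibility per (locus, region, cell class, group).

    ``cpm_table`` has one row per sample and one CPM column per peak;
    ``peaks`` maps column names to intervals; ``sample_meta`` (same index)
    carries ``region``, ``cell_class``, ``group``. With ``clip=True`` the
    length denominator uses the peak-locus intersection lengths rather than
    full peak lengths.

    Returns a long-format frame with columns locus, region, cell_class,
    group, value, plus n_peaks and a ``flagged`` column marking loci with no
    overlapping peak (value 0 everywhere) or tied maxima.
    """
    missing = set(cpm_table.columns) - set(peaks)
    if missing:
        raise ValueError(f"peaks missing intervals for columns: {sorted(missing)[:5]}")
    combos = sample_meta.loc[cpm_table.index, ["region", "cell_class", "group"]]
    rows = []
    for locus in loci:
        hit_cols = [c for c in cpm_table.columns if peaks[c].overlaps(locus)]
        if clip:
            total_len = sum(
                min(peaks[c].end, locus.end) - max(peaks[c].start, locus.start)
                for c in hit_cols
            )
        else:
            total_len = sum(peaks[c].length for c in hit_cols)
        if hit_cols:
            per_sample = cpm_table[hit_cols].sum(axis=1) / total_len
        else:
            per_sample = pd.Series(0.0, index=cpm_table.index)
        means = per_sample.groupby(
            [combos["region"], combos["cell_class"], combos["group"]]
        ).mean()
        vmax = means.max()
        no_peaks = not hit_cols or vmax == 0
        normed = means / vmax if not no_peaks else means
        tied = (not no_peaks) and (np.isclose(normed, 1.0).sum() > 1)
        for (region, cell_class, group), val in normed.items():
            rows.append(
                {
                    "locus": locus.name or f"{locus.chrom}:{locus.start}-{locus.end}",
                    "region": region,
                    "cell_class": cell_class,
                    "group": group,
                    "value": float(val),
                    "n_peaks": len(hit_cols),
                    "flagged": bool(no_peaks or tied),
                }
            )
    return pd.DataFrame(rows)
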