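"""Orthologue expression-ratio construction and cross-species divergence
statistics.

Expression of each gene is summarised as mean cpm across samples per
species; orthologue pairs with cpm > 0.5 in both species enter the analysis.
The unit of comparison is the log2 ratio of species-A cpm over species-B cpm
for each orthologue pair, so a *reduction* in species A is a negative log2
ratio. A designated gene subset (e.g. predicted miRNA targets) is compared
to the genome-wide background of all pairs by:

* a two-sample Kolmogorov-Smirnov test on the ratio distributions, with the
  direction of the shift given by the sign of the median difference;
* medians and a Mann-Whitney U test after restricting to pairs with fold
  change above a threshold (|log2 ratio| > log2 1.2 by default);
* the excess-reduction percentage, the relative increase of the subset's
  absolute median ratio over the background's.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountTable
from .mirna_catalog import cpm_normalize

MIN_CPM = 0.5
MIN_FOLD_CHANGE = 1.2


@dataclasses.dataclass
class OrthologExpressionTable:
    """Matched per-gene cpm values and log2 ratios for orthologue pairs.

    Every retained row has cpm > ``min_cpm`` in both species, so all ratios
    are finite. ``data`` columns: gene_a, gene_b, cpm_a, cpm_b, log2_ratio.
    """

    data: pd.DataFrame
    species_a: str
    species_b: str
    min_cpm: float = MIN_CPM

    def __post_init__(self):
        if len(self.data) == 0:
            raise ValueError("no orthologue pairs survive the cpm filter")
        if not np.isfinite(self.data["log2_ratio"]).all():
            raise ValueError("non-finite log2 ratio in table")

    def ratios(self, genes: Iterable[str] | None = None,
               exclude: Iterable[str] | None = None) -> np.ndarray:
        """log2 ratios for a subset of species-A gene ids (all rows when
        ``genes`` is None), optionally excluding ids (e.g. genes targeted by
        both the focal and the complementary miRNA class)."""
        df = self.data
        if genes is not None:
            df = df[df["gene_a"].isin(set(genes))]
        if exclude is not None:
            df = df[~df["gene_a"].isin(set(exclude))]
        return df["log2_ratio"].to_numpy()


def build_ratio_table(expr_a: CountTable, expr_b: CountTable,
                      ortholog_map: Sequence[tuple[str, str]],
                      min_cpm: float = MIN_CPM,
                      species_a: str = "A", species_b: str = "B"
                      ) -> OrthologExpressionTable:
    """Collapse each species to per-gene mean cpm, join orthologue pairs and
    keep those with cpm > ``min_cpm`` in both species."""
    cpm_a = cpm_normalize(expr_a).mean(axis=1)
    cpm_b = cpm_normalize(expr_b).mean(axis=1)
    rows = []
    for gene_a, gene_b in ortholog_map:
        if gene_a not in cpm_a.index or gene_b not in cpm_b.index:
            raise KeyError(f"orthologue pair ({gene_a!r}, {gene_b!r}) references a "
                           "gene absent from the count tables")
        ca, cb = float(cpm_a[gene_a]), float(cpm_b[gene_b])
        if ca > min_cpm and cb > min_cpm:
            rows.append((gene_a, gene_b, ca, cb, float(np.log2(ca / cb))))
    data = pd.DataFrame(rows, columns=["gene_a", "gene_b", "cpm_a", "cpm_b",
                                       "log2_ratio"])
    return OrthologExpressionTable(data, species_a, species_b, min_cpm)


def cdf_shift_test(subset_ratios: Sequence[float], background_ratios: Sequence[float]
                   ) -> tuple[float, float, int]:
    """Two-sample KS test of a subset's ratio distribution against the
    background; returns (D, p, direction) with direction the sign of
    median(subset) - median(background) (negative = subset shifted left,
    i.e. reduced in species A)."""
    subset = np.asarray(subset_ratios, dtype=float)
    background = np.asarray(background_ratios, dtype=float)
    if subset.size == 0 or background.size == 0:
        raise ValueError("both ratio lists must be non-empty")
    res = stats.ks_2samp(subset, background, alternative="two-sided")
    direction = int(np.sign(np.median(subset) - np.median(background)))
    return float(res.statistic), float(res.pvalue), direction


def magnitude_reduction(subset_ratios: Sequence[float],
                        background_ratios: Sequence[float],
                        min_fold_change: float = MIN_FOLD_CHANGE
                        ) -> tuple[float, float, float]:
    """Median log2 ratios of subset and background among genes whose fold
    change exceeds ``min_fold_change`` in either direction, plus the
    two-sided Mann-Whitney U p-value comparing the filtered distributions."""
    cut = np.log2(min_fold_change)
    subset = np.asarray(subset_ratios, dtype=float)
    background = np.asarray(background_ratios, dtype=float)
    subset = subset[np.abs(subset) > cut]
    background = background[np.abs(background) > cut]
    if subset.size == 0 or background.size == 0:
        raise ValueError("fold-change filter removed every gene from one group")
    res = stats.mannwhitneyu(subset, background, alternative="two-sided")
    return float(np.median(subset)), float(np.median(background)), float(res.pvalue)


def excess_reduction_percent(median_subset: float, median_background: float) -> int:
    """Relative excess of the subset's absolute median ratio over the
    background's, as a whole-number percentage:
    (|subset| - |background|) / |background| * 100."""
    if median_background == 0:
        raise ValueError("background median is zero")
    return round((abs(median_subset) - abs(median_background))
                 / abs(median_background) * 100)
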