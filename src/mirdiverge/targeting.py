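"""Seed-site prediction on 3'UTRs, cross-species conservation labelling and
the normalized divergence-rate statistic.

Canonical site classes, in decreasing efficacy order:

* **8mer** — reverse complement of mature positions 2-8 followed by an A in
  the UTR (opposite miRNA position 1);
* **7mer-m8** — reverse complement of mature positions 2-8;
* **7mer-A1** — reverse complement of mature positions 2-7 followed by an A.

A predicted site on the reference species' UTR is *conserved* when at least
one species of the comparison panel is character-identical over the site's
alignment columns (any substitution or alignment gap counts as divergence),
otherwise *reference-specific*.

The normalized divergence rate of a site against one comparison species is
the substitution rate within the site minus the substitution rate of its
flanking sequence (total flank length 84 nt for 7-mers, 96 nt for 8-mers,
split equally upstream/downstream). Positive values indicate
site-accelerated sequence evolution. Gap columns are excluded from both the
numerator and denominator of these rates — substitutions only — whereas the
conservation label above does count indels; the two rules are deliberately
different.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import GAP, revcomp_rna, to_rna
from .io_formats import UTRAlignmentBlock

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
#: total flanking length used in the divergence-rate denominator, by site length
FLANK_TOTAL = {7: 84, 8: 96}
#: default site-efficacy scores by type (pluggable; rank order only)
DEFAULT_TYPE_SCORE = {"8mer": 3.0, "7mer-m8": 2.0, "7mer-A1": 1.0}

#: comparison panel used for conservation labelling
DEFAULT_PANEL = ("human", "dog", "mouse", "rat", "chicken")


@dataclasses.dataclass(frozen=True)
class DivergenceRecord:
    """Substitution rates of a site and its flanks versus one species."""

    site_rate: float
    flank_rate: float
    comparison_species: str

    @property
    def normalized(self) -> float:
        return self.site_rate - self.flank_rate


@dataclasses.dataclass
class TargetSiteCall:
    """One predicted seed site on the reference 3'UTR."""

    gene_id: str
    mirna_id: str
    site_type: str
    ref_start: int  # 0-based on the ungapped reference UTR
    site_len: int
    score: float = 0.0
    conservation: str = "unassessed"  # reference_specific | conserved | unassessed
    divergence: DivergenceRecord | None = None

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if (self.site_len == 8) != (self.site_type == "8mer"):
            raise ValueError("site_len 8 iff site_type 8mer")


SiteScorer = Callable[[TargetSiteCall], float]


def _type_scorer(site: TargetSiteCall) -> float:
    return DEFAULT_TYPE_SCORE[site.site_type]


def find_seed_sites(seed: str, utr: str, *, gene_id: str = "", mirna_id: str = "",
                    scorer: SiteScorer = _type_scorer) -> list[TargetSiteCall]:
    """Scan a UTR for canonical seed-match sites.

    Matches overlapping a higher-class call are suppressed, so each location
    is reported once at its highest class (8mer > 7mer-m8 > 7mer-A1). The A
    opposite miRNA position 1 is required to be an A in the UTR regardless of
    the mature's first base, per the canonical site definitions.
    """
    seed = to_rna(seed)
    if len(seed) != 7:
        raise ValueError(f"seed must be a 7-mer, got length {len(seed)}")
    utr = to_rna(utr)
    rc7 = revcomp_rna(seed)            # complement of positions 8..2, 5'->3'
    rc6 = revcomp_rna(seed[:6])        # complement of positions 7..2
    calls: list[TargetSiteCall] = []
    covered: list[tuple[int, int]] = []

    def overlaps(start: int, length: int) -> bool:
        return any(start < e and s < start + length for s, e in covered)

    # 8mer and 7mer-m8 share the heptamer anchor; the trailing A upgrades
    for p in range(len(utr) - 6):
        if utr[p:p + 7] != rc7:
            continue
        if p + 7 < len(utr) and utr[p + 7] == "A":
            calls.append(TargetSiteCall(gene_id, mirna_id, "8mer", p, 8))
            covered.append((p, p + 8))
        else:
            calls.append(TargetSiteCall(gene_id, mirna_id, "7mer-m8", p, 7))
            covered.append((p, p + 7))
    for p in range(len(utr) - 6):
        if utr[p:p + 6] == rc6 and utr[p + 6] == "A" and not overlaps(p, 7):
            calls.append(TargetSiteCall(gene_id, mirna_id, "7mer-A1", p, 7))
            covered.append((p, p + 7))
    calls.sort(key=lambda c: c.ref_start)
    for c in calls:
        c.score = scorer(c)
    return calls


def _site_columns(site: TargetSiteCall, block: UTRAlignmentBlock) -> list[int]:
    coord_map = block.ref_coord_map
    end = site.ref_start + site.site_len
    if site.ref_start < 0 or end > len(coord_map):
        raise ValueError(f"site [{site.ref_start}, {end}) extends past the reference "
                         f"UTR of {block.gene_id!r} (length {len(coord_map)})")
    return [coord_map[i] for i in range(site.ref_start, end)]


def classify_site_conservation(site: TargetSiteCall, block: UTRAlignmentBlock,
                               species_panel: Sequence[str] = DEFAULT_PANEL) -> str:
    """Conservation label of a site against a panel of species.

    ``conserved`` iff at least one panel species present in the block matches
    the reference exactly over every site column; substitutions and gaps both
    count as divergence. Panel species absent from the block are skipped;
    ``unassessed`` if none is present.
    """
    cols = _site_columns(site, block)
    ref = block.ref_seq
    present = [sp for sp in species_panel if sp in block.species and sp != block.ref_species]
    if not present:
        return "unassessed"
    for sp in present:
        row = block.row(sp)
        if all(row[c] == ref[c] and row[c] != GAP for c in cols):
            return "conserved"
    return "reference_specific"


def normalized_site_divergence(site: TargetSiteCall, block: UTRAlignmentBlock,
                               comparison_species: str) -> DivergenceRecord:
    """Substitution rate of the site minus that of its flanks, versus one
    comparison species.

    Flanks extend 42 nt (7-mer sites) or 48 nt (8-mer sites) up- and
    downstream on the ungapped reference, truncated at the UTR ends with the
    denominator adjusted. Columns where the comparison row has a gap are
    excluded from numerator and denominator alike.
    """
    if comparison_species not in block.species:
        raise ValueError(f"comparison species {comparison_species!r} not in block "
                         f"{block.gene_id!r}")
    coord_map = block.ref_coord_map
    ref_len = len(coord_map)
    ref = block.ref_seq
    other = block.row(comparison_species)
    site_cols = _site_columns(site, block)
    half = FLANK_TOTAL[site.site_len] // 2
    up = range(max(0, site.ref_start - half), site.ref_start)
    down = range(site.ref_start + site.site_len,
                 min(ref_len, site.ref_start + site.site_len + half))
    flank_cols = [coord_map[i] for i in up] + [coord_map[i] for i in down]

    def rate(cols: list[int]) -> float:
        ungapped = [c for c in cols if other[c] != GAP]
        if not ungapped:
            raise ValueError(f"no ungapped columns to compare for site at "
                             f"{site.ref_start} in {block.gene_id!r}")
        subs = sum(other[c] != ref[c] for c in ungapped)
        return subs / len(ungapped)

    return DivergenceRecord(site_rate=rate(site_cols), flank_rate=rate(flank_cols),
                            comparison_species=comparison_species)


def contingency_test(counts: np.ndarray | Sequence[Sequence[int]]
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Pearson chi-square test of independence (no continuity correction) on a
    2x2 table of site counts; returns (table, per-row proportions of the
    first column, p)."""
    table = np.asarray(counts, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 contingency table")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an empty margin")
    props = table[:, 0] / table.sum(axis=1)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return table, props, float(p)


def specificity_contingency(calls: Iterable[TargetSiteCall],
                            mirna_labels: Mapping[str, str]
                            ) -> tuple[pd.DataFrame, np.ndarray, float]:
    """2x2 contingency of site conservation by miRNA specificity class.

    Rows: miRNA label (specific, non_specific); columns: site conservation
    (reference_specific, conserved). Every call must carry an assessed
    conservation label. Returns the table, the per-row proportion of
    reference-specific sites, and the chi-square p-value.
    """
    counts = np.zeros((2, 2), dtype=np.int64)
    row_idx = {"specific": 0, "non_specific": 1}
    col_idx = {"reference_specific": 0, "conserved": 1}
    n = 0
    for call in calls:
        if call.conservation == "unassessed":
            raise ValueError(f"site {call.gene_id}:{call.ref_start} has no assessed "
                             "conservation label")
        counts[row_idx[mirna_labels[call.mirna_id]], col_idx[call.conservation]] += 1
        n += 1
    if n == 0:
        raise ValueError("no site calls")
    _, props, p = contingency_test(counts)
    table = pd.DataFrame(counts, index=["specific", "non_specific"],
                         columns=["reference_specific", "conserved"])
    return table, props, p


def divergence_distribution_test(records_a: Sequence[DivergenceRecord],
                                 records_b: Sequence[DivergenceRecord]
                                 ) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on normalized divergence
    rates of two site populations; returns (D, p)."""
    if not records_a or not records_b:
        raise ValueError("both record lists must be non-empty")
    a = [r.normalized for r in records_a]
    b = [r.normalized for r in records_b]
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
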