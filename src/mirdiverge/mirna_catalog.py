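"""miRNA records, seed extraction, expression filters and seed-family
diversification analysis.

The seed is the 7-mer at positions 2-8 (1-based) of the dominant mature
sequence; it is the primary determinant of target recognition in animals.
Families of paralogous miRNAs can diversify their seeds by *seed shifting*
(the dominant mature isoform's 5' start moves by a few nucleotides, sliding
the seed window along the precursor) or by point mutation within the seed.
``family_seed_analysis`` classifies every member pair accordingly.

Expression is measured as counts per million mapped reads (cpm). A miRNA is
*expressed* when its raw count exceeds 5 in every sample, and *highly
expressed* when its mean raw count across samples exceeds 50 (roughly cpm
1.5 at the library depths of typical blood small-RNA runs). The two
thresholds are applied independently.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import RNA_ALPHABET, validate_alphabet
from .io_formats import CountTable

SEED_START = 1  # 0-based: seed spans mature[1:8], i.e. 1-based positions 2-8
SEED_LEN = 7
MAX_SHIFT = 3

EXPRESSED_MIN_COUNT = 5       # strict: count > 5 in every sample
HIGHLY_EXPRESSED_MEAN = 50    # strict: mean count across samples > 50


@dataclasses.dataclass(frozen=True)
class MiRNARecord:
    """One miRNA: dominant mature, optional star and hairpin sequences,
    genomic position (0-based half-open) and per-sample read counts."""

    mirna_id: str
    mature_seq: str
    hairpin_seq: str
    star_seq: str | None = None
    genome_pos: tuple[str, int, int, str] | None = None  # chrom, start, end, strand
    counts: Mapping[str, int] | None = None

    def __post_init__(self):
        validate_alphabet(self.mature_seq, RNA_ALPHABET, what=f"{self.mirna_id} mature")
        validate_alphabet(self.hairpin_seq, RNA_ALPHABET, what=f"{self.mirna_id} hairpin")
        if not 8 <= len(self.mature_seq) <= 30:
            raise ValueError(f"{self.mirna_id}: mature length {len(self.mature_seq)} "
                             "outside [8, 30]")
        if self.mature_seq not in self.hairpin_seq:
            raise ValueError(f"{self.mirna_id}: mature is not a substring of hairpin")

    @property
    def seed(self) -> str:
        return extract_seed(self.mature_seq)


@dataclasses.dataclass(frozen=True)
class SeedRelation:
    """Relation between the seeds of two family members.

    ``relation`` is ``identical``, ``shift(k)`` for k in +-1..+-3,
    ``point_mutation`` or ``other``, resolved in that priority order.
    A positive k means the second member's seed window sits k nt downstream
    (3') of the first member's on its own mature sequence.
    """

    member_a: str
    member_b: str
    relation: str


def extract_seed(mature: str) -> str:
    """7-mer seed: characters at 1-based positions 2-8 of the mature."""
    if len(mature) < SEED_START + SEED_LEN:
        raise ValueError(f"mature sequence of length {len(mature)} too short for a "
                         f"{SEED_LEN}-mer seed at positions 2-8")
    return mature[SEED_START:SEED_START + SEED_LEN]


def cpm_normalize(table: CountTable) -> pd.DataFrame:
    """counts-per-million: count / per-sample mapped-read total * 1e6."""
    totals = np.array([table.totals[s] for s in table.samples], dtype=float)
    if (totals <= 0).any():
        bad = [s for s in table.samples if table.totals[s] <= 0]
        raise ValueError(f"non-positive mapped-read total for samples {bad}")
    return table.counts / totals * 1e6


def expression_filters(table: CountTable) -> pd.DataFrame:
    """Boolean ``expressed`` / ``highly_expressed`` flags per entity.

    expressed: raw count strictly greater than 5 in every sample.
    highly_expressed: mean raw count across samples strictly greater than 50.
    The flags are independent; neither implies the other.
    """
    if not table.samples:
        raise ValueError("count table has no samples")
    expressed = (table.counts > EXPRESSED_MIN_COUNT).all(axis=1)
    highly = table.counts.mean(axis=1) > HIGHLY_EXPRESSED_MEAN
    return pd.DataFrame({"expressed": expressed, "highly_expressed": highly})


def _shift_offset(mature_a: str, mature_b: str) -> int | None:
    """Smallest-|k| offset (k != 0, |k| <= 3) such that member B's seed equals
    the 7-mer at seed position + k on member A's mature; None if no such k.

    Checked both ways so that shift(k) on (A, B) implies shift(-k) on (B, A)
    whenever the corresponding window exists.
    """
    seed_b = extract_seed(mature_b)
    seed_a = extract_seed(mature_a)
    for k in sorted(range(-MAX_SHIFT, MAX_SHIFT + 1), key=lambda k: (abs(k), k)):
        if k == 0:
            continue
        start = SEED_START + k
        if 0 <= start and start + SEED_LEN <= len(mature_a):
            if mature_a[start:start + SEED_LEN] == seed_b:
                return k
        start_b = SEED_START - k
        if 0 <= start_b and start_b + SEED_LEN <= len(mature_b):
            if mature_b[start_b:start_b + SEED_LEN] == seed_a:
                return k
    return None


def classify_pair(mature_a: str, mature_b: str) -> str:
    """Relation between two matures: identical seeds, a seed shift of up to
    3 nt, a single-base seed substitution, or other."""
    seed_a, seed_b = extract_seed(mature_a), extract_seed(mature_b)
    if seed_a == seed_b:
        return "identical"
    k = _shift_offset(mature_a, mature_b)
    if k is not None:
        return f"shift({k:+d})"
    hamming = sum(a != b for a, b in zip(seed_a, seed_b))
    if hamming == 1:
        return "point_mutation"
    return "other"


def family_seed_analysis(members: Iterable[MiRNARecord]
                         ) -> tuple[int, list[SeedRelation]]:
    """Distinct seed count and pairwise seed relations for one miRNA family.

    The distinct-seed count is over ``extract_seed`` outputs and is invariant
    under member ordering; relations are reported for every unordered pair in
    input order.
    """
    members = list(members)
    if not members:
        raise ValueError("family has no members")
    n_seeds = len({m.seed for m in members})
    relations = [
        SeedRelation(a.mirna_id, b.mirna_id, classify_pair(a.mature_seq, b.mature_seq))
        for a, b in itertools.combinations(members, 2)
    ]
    return n_seeds, relations


def catalog_summary(records: Iterable[MiRNARecord], table: CountTable) -> pd.DataFrame:
    """Per-miRNA summary: seed, expression flags and mean cpm."""
    flags = expression_filters(table)
    cpm = cpm_normalize(table).mean(axis=1)
    rows = []
    for rec in records:
        rows.append({
            "mirna_id": rec.mirna_id,
            "seed": rec.seed,
            "expressed": bool(flags.loc[rec.mirna_id, "expressed"]),
            "highly_expressed": bool(flags.loc[rec.mirna_id, "highly_expressed"]),
            "mean_cpm": float(cpm.loc[rec.mirna_id]),
        })
    return pd.DataFrame(rows).set_index("mirna_id")
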