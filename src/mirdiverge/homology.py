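"""Cross-species miRNA homolog screen and lineage-specificity labelling.

A miRNA is called *reference-lineage-specific* when no comparison genome
contains a credible homolog. Homology is established by a three-step screen
applied per species:

1. **Mature scan** — every position (both strands) where the mature
   sequence matches the genome with at most ``max_mismatches`` Hamming
   mismatches (default 2, no indels).
2. **Hairpin alignment** — the full precursor hairpin is locally aligned
   (Smith-Waterman; match +1, mismatch -2, gap open -5, gap extend -2)
   against a genome window centred on each step-1 hit. The hit passes when
   the Karlin-Altschul E-value is below 0.1 and the fraction of identical
   columns exceeds 60% of the hairpin length.
3. **Hairpin stability** — the genome-side aligned span must fold into a
   hairpin with minimum free energy strictly below -25 kcal/mol.

A miRNA with no species passing all three steps is labelled ``specific``;
otherwise ``non_specific``. The net gain rate of lineage-specific miRNAs is
their count divided by the divergence time in million years.

The default folding model is a dynamic-programming energy minimisation over
canonical Watson-Crick plus G:U pairs with nearest-neighbour stack energies,
a hairpin-loop closure penalty and minimum loop size 3; any callable mapping
an RNA string to kcal/mol (e.g. a wrapper around an external folder) can be
substituted through the :class:`FoldingModel` contract.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import Align

from ._seq import revcomp_dna, to_dna, to_rna
from .mirna_catalog import MiRNARecord

MAX_MISMATCHES = 2
EVALUE_MAX = 0.1
IDENTITY_MIN = 0.60
MFE_MAX_KCAL = -25.0
STEP2_WINDOW_PAD = 100  # window = step-1 hit +- (hairpin length + this)

# Karlin-Altschul constants for the +1/-2 match/mismatch scoring, exposed in
# the config because published blastn statistics are not bit-reproducible.
KA_LAMBDA = 1.28
KA_K = 0.46


# ---------------------------------------------------------------------------
# Step 1: Hamming scan of the mature sequence

@dataclasses.dataclass(frozen=True)
class MatureHit:
    pos: int        # 0-based start on the forward genome strand
    strand: str     # '+' or '-'
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _hamming_scan(pattern: np.ndarray, genome: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All (pos, mismatches) with Hamming distance <= max_mm; vectorised."""
    m, n = len(pattern), len(genome)
    if n < m:
        return []
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mism += genome[j:n - m + 1 + j] != pattern[j]
    idx = np.nonzero(mism <= max_mm)[0]
    return [(int(i), int(mism[i])) for i in idx]


def mature_match(mature: str, genome: str, max_mismatches: int = MAX_MISMATCHES
                 ) -> list[MatureHit]:
    """Scan both genome strands for near-exact copies of the mature sequence.

    Returns all windows whose Hamming distance to the mature (as DNA) is at
    most ``max_mismatches``; indels are not considered. Positions are 0-based
    starts on the forward strand for both orientations.
    """
    genome = genome.upper()
    if not genome:
        return []
    pat_fwd = _encode(to_dna(mature))
    pat_rev = _encode(revcomp_dna(to_dna(mature)))
    g = _encode(genome)
    hits = [MatureHit(pos, "+", mm) for pos, mm in _hamming_scan(pat_fwd, g, max_mismatches)]
    hits += [MatureHit(pos, "-", mm) for pos, mm in _hamming_scan(pat_rev, g, max_mismatches)]
    return sorted(hits, key=lambda h: (h.pos, h.strand))


# ---------------------------------------------------------------------------
# Step 2: local hairpin alignment with Karlin-Altschul E-value

@dataclasses.dataclass(frozen=True)
class HairpinAlignment:
    identity_fraction: float
    aligned_span: tuple[int, int]  # 0-based half-open on the genome window
    evalue: float
    score: float
    passed: bool


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """E = K * m * n * exp(-lambda * score) for search space sizes m, n."""
    return k * m * n * math.exp(-lam * score)


def hairpin_align(hairpin: str, genome_window: str,
                  search_space: tuple[int, int] | None = None,
                  evalue_max: float = EVALUE_MAX,
                  identity_min: float = IDENTITY_MIN) -> HairpinAlignment:
    """Smith-Waterman alignment of the hairpin against a genome window.

    ``identity_fraction`` is identical columns divided by the full hairpin
    length, so a perfect but partial alignment of less than 60% of the
    hairpin cannot pass. An empty window fails with an infinite E-value.
    """
    hairpin_dna = to_dna(hairpin)
    window = genome_window.upper()
    if not window:
        return HairpinAlignment(0.0, (0, 0), math.inf, 0.0, False)
    m, n = search_space if search_space is not None else (len(hairpin_dna), len(window))
    aln = _make_aligner().align(window, hairpin_dna)[0]
    counts = aln.counts()
    identity = counts.identities / len(hairpin_dna)
    span = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    evalue = karlin_altschul_evalue(aln.score, m, n)
    passed = evalue < evalue_max and identity > identity_min
    return HairpinAlignment(identity, span, evalue, float(aln.score), passed)


# ---------------------------------------------------------------------------
# Step 3: hairpin minimum free energy

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

# Watson-Crick nearest-neighbour stack free energies at 37 C (kcal/mol),
# keyed by (closing pair i.j, inner pair i+1.j-1); wobble-containing stacks
# get a uniform modest stabilisation.
_WC_STACKS = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08, ("CG", "AU"): -2.11, ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35, ("CG", "GC"): -2.36, ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
}
_GU_STACK = -1.2

_HAIRPIN_LOOP = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_RT = 0.616  # kcal/mol at 37 C
MIN_LOOP = 3
_MAX_INTERIOR = 30  # cap on (bulge + interior) unpaired bases per loop


def _stack_energy(outer: str, inner: str) -> float:
    if (outer, inner) in _WC_STACKS:
        return _WC_STACKS[(outer, inner)]
    # strand symmetry: the same stack read from the other strand
    rev = (_pair_flip(inner), _pair_flip(outer))
    if rev in _WC_STACKS:
        return _WC_STACKS[rev]
    return _GU_STACK


def _pair_flip(pair: str) -> str:
    return pair[::-1]


def _hairpin_loop_energy(size: int) -> float:
    if size in _HAIRPIN_LOOP:
        return _HAIRPIN_LOOP[size]
    return _HAIRPIN_LOOP[9] + 1.75 * _RT * math.log(size / 9)


def _internal_loop_energy(size: int) -> float:
    # simplified bulge/interior initiation, logarithmic in loop size
    return 2.0 + 1.3 * math.log(size) if size > 1 else 3.0


def nearest_neighbor_mfe(seq: str) -> float:
    """Minimum free energy (kcal/mol) of ``seq`` under the built-in model.

    Energy minimisation over nested structures made of stacked canonical and
    G:U pairs, hairpin loops (minimum size 3) and bulge/interior loops of up
    to 30 unpaired bases; multibranch loops are not modelled, which is
    adequate for the single-stem precursors this screen evaluates. The empty
    structure has energy 0, so the result is never positive.
    """
    s = to_rna(seq)
    n = len(s)
    if n < 15:
        raise ValueError(f"sequence of length {n} too short to fold (need >= 15)")
    INF = math.inf

    def pairable(i: int, j: int) -> bool:
        return (s[i], s[j]) in _CANONICAL

    V = {}
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if not pairable(i, j):
                continue
            best = _hairpin_loop_energy(j - i - 1)
            outer = s[i] + s[j]
            kmax = min(i + 1 + _MAX_INTERIOR, j - MIN_LOOP - 1)
            for k in range(i + 1, kmax + 1):
                left = k - i - 1
                lmin = max(k + MIN_LOOP + 1, j - 1 - (_MAX_INTERIOR - left))
                for l in range(lmin, j):
                    inner_e = V.get((k, l))
                    if inner_e is None:
                        continue
                    unpaired = left + (j - l - 1)
                    if unpaired == 0:
                        e = _stack_energy(outer, s[k] + s[l]) + inner_e
                    else:
                        e = _internal_loop_energy(unpaired) + inner_e
                    if e < best:
                        best = e
            V[(i, j)] = best

    # external: best over pairings anywhere in the sequence, or no structure
    W = [0.0] * (n + 1)
    for j in range(1, n + 1):
        W[j] = W[j - 1]
        for i in range(0, j - MIN_LOOP - 1):
            vij = V.get((i, j - 1))
            if vij is not None:
                cand = W[i] + vij
                if cand < W[j]:
                    W[j] = cand
    return min(0.0, W[n])


@dataclasses.dataclass(frozen=True)
class FoldingModel:
    """Pluggable folding contract: name plus an RNA string -> kcal/mol
    energy function (more negative = more stable)."""

    name: str
    energy: Callable[[str], float]

    def __call__(self, seq: str) -> float:
        return self.energy(seq)


DEFAULT_FOLDING_MODEL = FoldingModel("nearest_neighbor_dp", nearest_neighbor_mfe)


def hairpin_mfe(seq: str, model: FoldingModel = DEFAULT_FOLDING_MODEL) -> float:
    """Minimum free energy of the putative precursor under ``model``."""
    if len(seq) < 15:
        raise ValueError(f"sequence of length {len(seq)} too short to fold")
    return float(model(seq))


# ---------------------------------------------------------------------------
# Verdicts

@dataclasses.dataclass(frozen=True)
class SpeciesEvidence:
    """Evidence trail for one comparison species: all step-1 hits, the best
    step-2 alignment evaluated, the step-3 fold of the passing candidate."""

    step1_hits: tuple[MatureHit, ...]
    step2: HairpinAlignment | None
    step3_mfe: float | None
    step3_pass: bool
    passed: bool  # all three steps


@dataclasses.dataclass(frozen=True)
class HomologyVerdict:
    mirna_id: str
    evidence: Mapping[str, SpeciesEvidence]
    label: str  # 'specific' | 'non_specific'


def _window_for_hit(genome: str, hit: MatureHit, mature_len: int, hairpin_len: int
                    ) -> str:
    pad = hairpin_len + STEP2_WINDOW_PAD
    lo = max(0, hit.pos - pad)
    hi = min(len(genome), hit.pos + mature_len + pad)
    window = genome[lo:hi]
    return revcomp_dna(window) if hit.strand == "-" else window


def classify_specificity(mirna: MiRNARecord, genomes: Mapping[str, str],
                         model: FoldingModel = DEFAULT_FOLDING_MODEL,
                         max_mismatches: int = MAX_MISMATCHES,
                         evalue_max: float = EVALUE_MAX,
                         identity_min: float = IDENTITY_MIN,
                         mfe_max: float = MFE_MAX_KCAL) -> HomologyVerdict:
    """Run the three-step screen against every comparison genome.

    The step-2 window is the step-1 hit padded by (hairpin length + 100) nt
    on each side, taken on the hit strand. ``non_specific`` iff some species
    has a hit passing all three steps; evidence is recorded either way.
    """
    if not genomes:
        raise ValueError("need at least one comparison genome")
    evidence: dict[str, SpeciesEvidence] = {}
    any_pass = False
    for species, genome in genomes.items():
        hits = mature_match(mirna.mature_seq, genome, max_mismatches)
        best_step2: HairpinAlignment | None = None
        step3_mfe: float | None = None
        step3_pass = False
        species_pass = False
        for hit in hits:
            window = _window_for_hit(genome, hit, len(mirna.mature_seq),
                                     len(mirna.hairpin_seq))
            step2 = hairpin_align(mirna.hairpin_seq, window,
                                  evalue_max=evalue_max, identity_min=identity_min)
            if best_step2 is None or step2.evalue < best_step2.evalue:
                best_step2 = step2
            if not step2.passed:
                continue
            span_seq = window[step2.aligned_span[0]:step2.aligned_span[1]]
            if len(span_seq) < 15:
                continue
            mfe = hairpin_mfe(to_rna(span_seq), model)
            step3_mfe = mfe
            step3_pass = mfe < mfe_max  # strictly below
            if step3_pass:
                species_pass = True
                break
        evidence[species] = SpeciesEvidence(tuple(hits), best_step2, step3_mfe,
                                            step3_pass, species_pass)
        any_pass = any_pass or species_pass
    label = "non_specific" if any_pass else "specific"
    return HomologyVerdict(mirna.mirna_id, evidence, label)


def net_gain_rate(n_specific: int, divergence_myr: float) -> float:
    """Lineage-specific miRNA count per million years of divergence,
    reported to one decimal."""
    if divergence_myr <= 0:
        raise ValueError("divergence time must be positive")
    if n_specific < 0:
        raise ValueError("count must be non-negative")
    return round(n_specific / divergence_myr, 1)
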