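# Methods

This note records the models and procedures `mirdiverge` implements, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the design was genuinely open.

## Seeds, families and expression filters

The seed is the 7-mer at 1-based positions 2–8 of the dominant (major)
mature sequence. The optional 8th-nucleotide match and the A opposite
position 1 enter only at the target-site level (8mer / 7mer-A1 classes),
never into seed identity.

Pairwise family relations are resolved in a fixed priority order:
*identical* (equal seeds) > *shift(k)* (one member's seed equals the 7-mer
window offset by k ∈ ±1..±3 on the other's mature; the smaller |k| wins) >
*point_mutation* (seed Hamming distance exactly 1) > *other*. The priority
order is this package's tie-break; shifts are tested in both directions so
the relation is symmetric up to the sign of k.

Expression flags use raw counts, not cpm: *expressed* requires count > 5
(strict) in every sample; *highly expressed* requires mean count across
samples > 50 (strict). "Count greater than 50" is ambiguous about
aggregation across samples; the mean was chosen because it reconciles with
the quoted cpm ≈ 1.5 equivalence at typical 26–33 M mapped reads per
sample. The two flags are deliberately independent — a miRNA absent from
one sample but huge in another can be highly expressed yet not expressed —
and the per-sample counts are retained so the choice can be revisited.

## The three-step homolog screen

Published screens of this kind chain a short-read aligner, blastn and an
RNA folder. `mirdiverge` re-implements the three contracts directly so the
pipeline is self-contained and deterministic:

1. **Mature scan** — exact-window Hamming distance ≤ 2 (default), both
   strands, no indels; vectorised over all genome windows and verified
   against a brute-force scan in the tests.
2. **Hairpin alignment** — Smith–Waterman (match +1, mismatch −2, gap open
   −5, gap extend −2, via Biopython's `PairwiseAligner`) of the full
   precursor against a window of the step-1 hit padded by (hairpin length
   + 100) nt per side, taken on the hit strand. The padding guarantees the
   true precursor is inside the window while keeping the E-value search
   space m·n small and explicit; how the published screens restricted their
   search space is not documented. The E-value is Karlin–Altschul,
   `E = K·m·n·exp(−λ·S)` with λ = 1.28, K = 0.46 for this scoring scheme;
   because blastn's internal statistics are not bit-reproducible, both
   constants are exposed as configuration. Identity is counted over the
   full hairpin length, so a perfect partial alignment cannot reach the
   60% rule. Pass ⇔ E < 0.1 **and** identity > 0.60.
3. **Stability** — the genome-side aligned span must fold below −25
   kcal/mol, strictly. The default `FoldingModel` is a dynamic-programming
   energy minimisation over nested structures of stacked canonical + G:U
   pairs with Watson–Crick nearest-neighbour stack energies (37 °C), a
   tabulated hairpin-loop closure penalty (minimum loop 3, logarithmic
   extrapolation beyond size 9), a simplified logarithmic bulge/interior
   penalty capped at 30 unpaired bases per loop, and a uniform −1.2
   kcal/mol term for wobble-containing stacks. Multibranch loops are not
   modelled — adequate for the single-stem precursors this screen
   evaluates, and the tests cross-check stability classification against
   ViennaRNA's RNAfold. Any callable `RNA string → kcal/mol` can replace
   the default (e.g. an external folder).

A miRNA is *specific* iff no species has a hit passing all three steps;
the per-species evidence trail (all step-1 hits, the best step-2 alignment,
the step-3 fold) is recorded either way. Whether the published screens
required the mature region itself to be intact at step 3 is unstated; here
step 3 folds the whole aligned span.

The net gain rate is `n_specific / divergence_myr`, reported to one
decimal (71 specific miRNAs over 64.5 Myr gives 1.1 per Myr).

## Target sites, conservation and divergence rates

Site classes follow the canonical definitions: 7mer-m8 = reverse complement
of mature positions 2–8; 7mer-A1 = reverse complement of positions 2–7
followed by an A in the UTR; 8mer = 7mer-m8 plus the A. The A is required
in the UTR regardless of the mature's first base. Overlapping matches are
reported once at the highest class. Site efficacy scoring is a pluggable
scorer; the default ranks site types (8mer 3 > 7mer-m8 2 > 7mer-A1 1).
Context-style efficacy features (local AU content, 3' pairing) are out of
scope, and any percentile-style filter on scores is a plain configurable
cutoff on the scorer's output.

Conservation is assessed per site on a multi-species alignment against a
panel (default: human, dog, mouse, rat, chicken): *conserved* iff at least
one panel species is character-identical over every site column — a
substitution **or a gap** anywhere in the site breaks it. Panel species
absent from a block are skipped; a site with no panel species present is
*unassessed*.

The normalized divergence rate against one comparison species is
`site substitutions / site length − flank substitutions / flank length`,
with total flank lengths 84 (7-mers) and 96 (8-mers) interpreted as
42/48 nt per side, split symmetrically (only the totals are conventionally
stated; symmetric flanks reconcile with those denominators). Flanks
truncated by the UTR end shrink the denominator accordingly. Gap columns
are excluded from numerator and denominator alike — the rates count
nucleotide substitutions only — whereas the conservation label above does
count indels. These are two deliberately different rules, each matching
its own definition.

Association between miRNA specificity class and site conservation uses a
Pearson chi-square test of independence on the 2×2 table without
continuity correction; distributional comparisons of normalized rates use
the two-sample two-sided KS test.

## Orthologue expression divergence

Genes are summarised as mean cpm across samples per species; orthologue
pairs with cpm > 0.5 in both species are retained. The comparison unit is
`log2(cpm_A / cpm_B)` with species A the focal lineage, so reduction in A
is negative. The subset-vs-background comparisons are: two-sample KS with
the shift direction given by the sign of the median difference; medians and
a two-sided Mann–Whitney U test after keeping |log2 ratio| > log2(1.2)
(the fold-change filter is applied symmetrically in both directions, since
"fold change greater than 1.2" carries no stated directionality); and the
excess-reduction percentage
`(|median_subset| − |median_background|) / |median_background| × 100`,
rounded to a whole percent. Genes targeted by both the focal and the
complementary miRNA class can be excluded from subsets via the
`exclude=` argument of `OrthologExpressionTable.ratios`.

## Enrichment

Over-representation uses the hypergeometric upper tail
`P(X ≥ k)` for an overlap of k between an n-gene query and a K-gene set in
an N-gene universe, after intersecting sets with the universe. Reporting
filters are raw p < 0.05 and overlap ≥ 3, matching raw-p pathway-table
practice; a Benjamini–Hochberg FDR column is emitted for context but never
filters. The universe is an explicit required input (all-annotated vs
all-expressed universes give different answers; that choice belongs to the
caller). Conditional/ontology-structured testing is not implemented.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their integer seed.

* **Catalog** — one ancestral locus per family (mature length 22 plus 3 nt
  margin each side); members shift their 5' start by 1–3 nt with
  probability `shift_prob` and take one random seed substitution with
  probability `point_mut_prob`. Precursors are single stems: a 12-nt stem
  extension, the mature, an 8-nt loop and a near-complementary 3' arm
  carrying three G:U wobbles. The wobbles matter: they keep the star arm
  more than two mismatches away from the mature's reverse complement (so
  the homolog screen's step 1 sees only the mature arm) while leaving the
  stem far below −25 kcal/mol, as in real precursors whose arms are
  imperfect duplexes. Read counts are negative-binomial around lognormal
  per-miRNA means.
* **Genomes** — uniform-random background with planted hairpins (carriers
  get exactly `mismatch_level` substitutions confined to the mature
  region), shuffled-hairpin decoys that exercise step-2 rejection, and a
  scrubbing pass that mutates any chance background window within 2
  mismatches of a non-carrier mature. Caveat: scrubbing skips planted
  intervals, so catalogs used for genome planting should carry mutually
  dissimilar matures (one member per family) — paralogues with
  near-identical matures would legitimately cross-match.
* **UTR alignments** — the reference row is ungapped; planted sites are
  exact 8mer/7mer-m8 patterns placed with full flank room (a trailing A
  after a planted 7mer-m8 is resampled so the planted class is what the
  scanner sees). Per non-reference species, site bases substitute at
  `site_sub_rate`, non-site bases at `flank_sub_rate`; a site that is not
  *retained* (per-species probability) is forcibly disrupted with at least
  one substitution. Deletions appear as single gap columns in
  non-reference rows at `indel_rate` per base, keeping blocks rectangular
  and reference coordinates contiguous. Truth records the realised
  per-species conservation of every planted site.
* **Expression** — shared lognormal relative abundances; target genes'
  species-A abundance scaled by 2^(−effect); counts negative-binomial with
  variance μ + dispersion·μ² at library-scaled means (default three
  20 M-read samples per species). The orthologue map is the identity.
  Scaling targets slightly perturbs non-target cpm through the
  compositional normalisation, as in real libraries.
* **Gene sets** — one set with an exact planted overlap with the target
  list, the rest uniform.

The generators emulate the *statistical* structure the analyses assume —
independent per-base substitutions, NB counts, uniform backgrounds. They do
not emulate alignment error, GC/composition bias, repeat structure,
correlated substitution processes, miRNA biogenesis signal or 3'UTR length
variation; passing tests therefore demonstrate correctness of the
statistics and decision rules, not robustness to those real-data artefacts.

## Numerical choices and degenerate inputs

* Genomic intervals are 0-based half-open everywhere; BED is written
  natively and 1-based inputs must be converted at the boundary.
* Transcript-side sequences are canonicalised to RNA (T→U) on input.
* An empty step-2 window fails with E = +∞; aligned spans shorter than
  15 nt cannot be folded and fail step 3 by omission.
* Divergence rates over fully-gapped column sets raise rather than
  returning 0/0; callers skip such sites.
* `ks_2samp` uses SciPy's default method selection; with the discrete
  normalized-divergence values its asymptotic p is conservative under
  ties, so null rejection rates sit at or below the nominal level.
* Chi-square contingency tests reject tables with an empty margin.

## Problem sizes in the checks

The acceptance script and end-to-end tests run at desk scale, chosen to
make each statistical property measurable with comfortable margins:
2000 planted sites for divergence-rate recovery (3-SE band), 20 replicates
of n = 1000 per group for KS power, 400 replicates for the null
false-positive band, genomes of ~9 kb over 4 comparison species for the
homolog screen, 100 replicates of 3000-gene tables (500 targets, 1 log2
effect) for expression-shift detection, and 12 gene sets of 25 over a
2000-gene universe for enrichment recovery. Dataset-scale quantities that
depend on the original sequencing data (hundreds of miRNAs, tens of
thousands of real sites) are recomputed only at the worked-example level
from their printed inputs.
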