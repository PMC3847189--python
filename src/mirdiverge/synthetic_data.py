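"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a comparative
miRNA/mRNA study: paralogous miRNA families that diversify by seed shifting
and point mutation; comparison-species genomes carrying planted precursor
homologs at controlled mismatch levels (plus shuffled decoys); multi-species
3'UTR alignments whose site and flank columns substitute at independently
controlled rates, with gap columns in non-reference rows; overdispersed
(negative-binomial) orthologue count tables in which a designated target set
is down-regulated in one species by a chosen log2 effect; and gene-set
annotations containing one deliberately enriched set.

Every generator is a pure function of its seed: identical seeds give
identical outputs. Raw reads, quality scores and adapters are not simulated
— the pipeline starts from counts and sequences.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp_rna, to_dna
from .io_formats import CountTable
from .mirna_catalog import MAX_SHIFT, SEED_LEN, SEED_START, MiRNARecord, extract_seed
from .targeting import FLANK_TOTAL

RNA = np.array(list("ACGU"))
MATURE_LEN = 22
HAIRPIN_LOOP_LEN = 8


@dataclasses.dataclass
class SimTruth:
    """Ground truth for one synthetic dataset.

    Only the fields relevant to the generator that produced it are filled;
    ids in the truth are resolvable in the generated files.
    """

    # (mirna id, species id, mismatch count, identity fraction)
    planted_homologs: list[tuple[str, str, int, float]] = dataclasses.field(default_factory=list)
    # (gene id, mirna id, site type, ref_start, site_len, {species: conserved flag})
    planted_sites: list[tuple[str, str, str, int, int, dict[str, bool]]] = \
        dataclasses.field(default_factory=list)
    site_sub_rate: float = 0.0
    flank_sub_rate: float = 0.0
    target_effect: float = 0.0
    enriched_set_id: str | None = None
    target_ids: list[str] = dataclasses.field(default_factory=list)
    # member id -> (relation to family ancestor, seed shift in nt)
    member_relations: dict[str, tuple[str, int]] = dataclasses.field(default_factory=dict)
    # (mirna id, species id, chrom, start, end, strand) of planted hairpins
    planted_positions: list[tuple[str, str, str, int, int, str]] = \
        dataclasses.field(default_factory=list)

    def __post_init__(self):
        for rate in (self.site_sub_rate, self.flank_sub_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if not np.isfinite(self.target_effect):
            raise ValueError("target_effect must be finite")


def write_truth_json(path: str | Path, truth: SimTruth) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=1))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA, size=length))


def _substitute(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGU" if b != base]
    return others[rng.integers(len(others))]


# ---------------------------------------------------------------------------
# miRNA catalog

STEM_EXT_LEN = 12      # extra stem beyond the mature duplex, as in real precursors
ARM_WOBBLES = 3        # G:U wobbles on the 3' arm opposite the mature


def _build_hairpin(rng: np.random.Generator, mature: str) -> str:
    """Single-stem precursor: a 5' stem extension, the mature on the 5' arm,
    a short loop and the near-complementary 3' arm.

    The 3' arm opposite the mature carries a few G:U wobbles, so the star
    strand still pairs (the stem stays very stable) but is more than two
    mismatches away from the mature's reverse complement — as in real
    precursors, whose arms are imperfect duplexes.
    """
    ext = _random_rna(rng, STEM_EXT_LEN)
    loop = _random_rna(rng, HAIRPIN_LOOP_LEN)
    arm = list(revcomp_rna(mature))
    # arm position len-1-i faces mature position i; U/G there admit a wobble
    candidates = [len(arm) - 1 - i for i, b in enumerate(mature) if b in "UG"]
    rng.shuffle(candidates)
    for j in candidates[:ARM_WOBBLES]:
        arm[j] = "G" if arm[j] == "A" else "U"  # A->G keeps U:G, C->U keeps G:U
    return ext + mature + loop + "".join(arm) + revcomp_rna(ext)


def gen_mirna_catalog(n_families: int, members_per_family: int,
                      shift_prob: float, point_mut_prob: float, rng_seed: int,
                      n_samples: int = 3) -> tuple[list[MiRNARecord], SimTruth]:
    """Families of paralogous miRNAs diversified from one ancestral mature.

    Each member copies the ancestral mature; with probability ``shift_prob``
    its dominant 5' start is offset by 1-3 nt (either direction) along the
    ancestral locus, sliding the seed window, and with probability
    ``point_mut_prob`` one seed base is substituted. Per-sample read counts
    are drawn from a negative-binomial around a lognormal per-miRNA mean.
    The truth records each member's relation to its ancestor.
    """
    if n_families < 1 or members_per_family < 1:
        raise ValueError("family and member counts must be positive")
    for p in (shift_prob, point_mut_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    rng = np.random.default_rng(rng_seed)
    records: list[MiRNARecord] = []
    truth = SimTruth()
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    for f in range(n_families):
        locus = _random_rna(rng, MATURE_LEN + 2 * MAX_SHIFT)
        for m in range(members_per_family):
            mid = f"mir-{f + 1}-{m + 1}"
            shift = 0
            if rng.random() < shift_prob:
                shift = int(rng.choice([-3, -2, -1, 1, 2, 3]))
            start = MAX_SHIFT + shift
            mature = list(locus[start:start + MATURE_LEN])
            mutated = False
            if rng.random() < point_mut_prob:
                pos = SEED_START + int(rng.integers(SEED_LEN))
                mature[pos] = _substitute(rng, mature[pos])
                mutated = True
            mature_s = "".join(mature)
            relation = ("shifted+mutated" if shift and mutated
                        else "shifted" if shift
                        else "mutated" if mutated else "identical")
            truth.member_relations[mid] = (relation, shift)
            mean = float(rng.lognormal(np.log(40), 1.2))
            counts = {s: int(rng.negative_binomial(5, 5 / (5 + mean)))
                      for s in sample_ids}
            records.append(MiRNARecord(
                mirna_id=mid, mature_seq=mature_s,
                hairpin_seq=_build_hairpin(rng, mature_s),
                counts=counts))
    return records, truth


def catalog_count_table(records: Sequence[MiRNARecord],
                        mapped_total: int = 30_000_000) -> CountTable:
    """Assemble the per-miRNA counts of a generated catalog into a
    CountTable with a uniform mapped-read total per sample."""
    samples = sorted({s for r in records for s in (r.counts or {})})
    df = pd.DataFrame([[r.counts[s] for s in samples] for r in records],
                      index=[r.mirna_id for r in records], columns=samples)
    return CountTable(df, {s: mapped_total for s in samples})


# ---------------------------------------------------------------------------
# Comparison-species genomes

def _scrub_near_matches(rng: np.random.Generator, genome: list[str],
                        matures_dna: Sequence[str], protected: list[tuple[int, int]],
                        max_mm: int = 2) -> None:
    """Mutate the random background until no window outside the protected
    intervals is within ``max_mm`` mismatches of any listed mature (either
    strand). Chance near-matches are rare, so few rounds are needed."""
    from .homology import mature_match  # scan reused for scrubbing only

    def in_protected(pos: int, length: int) -> bool:
        return any(pos < e and s < pos + length for s, e in protected)

    for _ in range(20):
        dirty = False
        g = "".join(genome)
        for mat in matures_dna:
            for hit in mature_match(mat, g, max_mm):
                if in_protected(hit.pos, len(mat)):
                    continue
                dirty = True
                for off in rng.choice(len(mat), size=max_mm + 1, replace=False):
                    i = hit.pos + int(off)
                    if not in_protected(i, 1):
                        genome[i] = _substitute(rng, genome[i]).replace("U", "T")
        if not dirty:
            return
    raise RuntimeError("could not scrub chance near-matches from background")


def gen_species_genomes(catalog: Sequence[MiRNARecord],
                        species_specs: Sequence[tuple[str, set[str], int, float]],
                        genome_len: int, rng_seed: int
                        ) -> tuple[dict[str, str], SimTruth]:
    """Random genomes with planted precursor homologs.

    ``species_specs`` entries are (species id, homolog-carrier miRNA ids,
    mismatch level, decoy rate). Carriers receive the full hairpin (as DNA)
    with exactly ``mismatch level`` substitutions confined to the mature
    region; per non-carrier miRNA a shuffled hairpin is planted with
    probability ``decoy rate``; the random background is scrubbed of chance
    windows within 2 mismatches of any non-carrier mature.
    """
    rng = np.random.default_rng(rng_seed)
    by_id = {r.mirna_id: r for r in catalog}
    max_hp = max((len(r.hairpin_seq) for r in catalog), default=0)
    if max_hp > genome_len:
        raise ValueError(f"hairpin of length {max_hp} longer than genome ({genome_len})")
    genomes: dict[str, str] = {}
    truth = SimTruth()
    for species, carriers, mismatch_level, decoy_rate in species_specs:
        if mismatch_level < 0:
            raise ValueError("mismatch level must be >= 0")
        unknown = set(carriers) - set(by_id)
        if unknown:
            raise ValueError(f"unknown carrier ids {sorted(unknown)}")
        inserts: list[tuple[str, str]] = []  # (mirna id or decoy tag, DNA)
        for mid in sorted(carriers):
            rec = by_id[mid]
            hp = list(to_dna(rec.hairpin_seq))
            mstart = rec.hairpin_seq.find(rec.mature_seq)
            mlen = len(rec.mature_seq)
            if mismatch_level > mlen:
                raise ValueError("mismatch level exceeds mature length")
            for off in rng.choice(mlen, size=mismatch_level, replace=False):
                i = mstart + int(off)
                hp[i] = to_dna(_substitute(rng, hp[i].replace("T", "U")))
            inserts.append((mid, "".join(hp)))
            identity = (len(hp) - mismatch_level) / len(hp)
            truth.planted_homologs.append((mid, species, mismatch_level, identity))
        for rec in catalog:
            if rec.mirna_id in carriers or rng.random() >= decoy_rate:
                continue
            shuffled = "".join(rng.permutation(list(to_dna(rec.hairpin_seq))))
            inserts.append((f"decoy:{rec.mirna_id}", shuffled))

        total_insert = sum(len(s) for _, s in inserts)
        if inserts and genome_len < total_insert + 20 * len(inserts):
            raise ValueError(f"genome_len {genome_len} too small to host "
                             f"{len(inserts)} inserts without overlap")
        genome = list("".join(rng.choice(np.array(list("ACGT")), size=genome_len)))
        protected: list[tuple[int, int]] = []
        slot = genome_len // max(1, len(inserts)) if inserts else genome_len
        for i, (tag, seq) in enumerate(inserts):
            start = i * slot + int(rng.integers(max(1, slot - len(seq) - 10)))
            genome[start:start + len(seq)] = list(seq)
            protected.append((start, start + len(seq)))
            if not tag.startswith("decoy:"):
                truth.planted_positions.append(
                    (tag, species, species, start, start + len(seq), "+"))
        non_carrier_matures = [to_dna(r.mature_seq) for r in catalog
                               if r.mirna_id not in carriers]
        _scrub_near_matches(rng, genome, non_carrier_matures, protected)
        genomes[species] = "".join(genome)
    return genomes, truth


# ---------------------------------------------------------------------------
# UTR alignments

def _site_pattern(rng: np.random.Generator, seed: str, site_type: str) -> str:
    if site_type == "8mer":
        return revcomp_rna(seed) + "A"
    if site_type == "7mer-m8":
        return revcomp_rna(seed)
    raise ValueError(site_type)


def gen_utr_alignment_set(n_genes: int, species_list: Sequence[str],
                          catalog: Sequence[MiRNARecord],
                          site_plant_spec: tuple[float, float],
                          site_sub_rate: float, flank_sub_rate: float,
                          indel_rate: float, utr_len: int, rng_seed: int,
                          ) -> tuple[list, SimTruth]:
    """Multi-species gapped UTR alignments with planted seed sites.

    The first species in ``species_list`` is the reference; its UTRs are
    ungapped and contain planted exact sites for random catalog miRNAs in a
    ``site_frac`` fraction of genes. In every other species, site bases that
    are *retained* (probability ``retention_p`` per species) substitute at
    ``site_sub_rate`` per base like the rest of the sequence; a site that is
    not retained is forcibly disrupted (>= 1 substitution). Non-site bases
    substitute at ``flank_sub_rate`` and single-column deletions appear at
    ``indel_rate`` per base in non-reference rows only, keeping reference
    coordinates contiguous. Truth records each planted site's realised
    per-species conservation (identical over all site columns, no gap).
    """
    from .io_formats import UTRAlignmentBlock

    site_frac, retention_p = site_plant_spec
    for r in (site_frac, retention_p, site_sub_rate, flank_sub_rate, indel_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
    max_flank = max(FLANK_TOTAL.values())
    if utr_len < 8 + max_flank:
        raise ValueError(f"utr_len {utr_len} too short for a site plus flanks")
    if len(species_list) < 2:
        raise ValueError("need a reference plus at least one other species")
    rng = np.random.default_rng(rng_seed)
    ref_species, others = species_list[0], list(species_list[1:])
    truth = SimTruth(site_sub_rate=site_sub_rate, flank_sub_rate=flank_sub_rate)
    blocks = []
    for g in range(n_genes):
        gene = f"g{g + 1:05d}"
        ref = list(_random_rna(rng, utr_len))
        site_span: tuple[int, int] | None = None
        planted: tuple[str, str] | None = None
        if catalog and rng.random() < site_frac:
            rec = catalog[int(rng.integers(len(catalog)))]
            site_type = "8mer" if rng.random() < 0.5 else "7mer-m8"
            pattern = _site_pattern(rng, extract_seed(rec.mature_seq), site_type)
            half = FLANK_TOTAL[len(pattern)] // 2
            start = int(rng.integers(half, utr_len - len(pattern) - half + 1))
            ref[start:start + len(pattern)] = list(pattern)
            if site_type == "7mer-m8" and ref[start + 7] == "A":
                # a trailing A would upgrade the planted site to an 8mer
                ref[start + 7] = _substitute(rng, "A")
            site_span = (start, start + len(pattern))
            planted = (rec.mirna_id, site_type)
        rows = [(ref_species, "".join(ref))]
        conserved_by_species: dict[str, bool] = {}
        for sp in others:
            row = list(ref)
            in_site = np.zeros(utr_len, dtype=bool)
            if site_span is not None:
                in_site[site_span[0]:site_span[1]] = True
            subs = rng.random(utr_len) < np.where(in_site, site_sub_rate, flank_sub_rate)
            if site_span is not None and rng.random() >= retention_p:
                # site lost in this species: guarantee disruption
                if not subs[site_span[0]:site_span[1]].any():
                    subs[int(rng.integers(site_span[0], site_span[1]))] = True
            for i in np.nonzero(subs)[0]:
                row[i] = _substitute(rng, row[i])
            gaps = rng.random(utr_len) < indel_rate
            for i in np.nonzero(gaps)[0]:
                row[i] = "-"
            if site_span is not None:
                s, e = site_span
                conserved_by_species[sp] = all(
                    row[i] == ref[i] and row[i] != "-" for i in range(s, e))
            rows.append((sp, "".join(row)))
        if planted is not None:
            truth.planted_sites.append(
                (gene, planted[0], planted[1], site_span[0],
                 site_span[1] - site_span[0], conserved_by_species))
        blocks.append(UTRAlignmentBlock(gene_id=gene, rows=tuple(rows),
                                        ref_species=ref_species))
    return blocks, truth


# ---------------------------------------------------------------------------
# Expression tables

def gen_expression_tables(n_genes: int, target_ids: set[str], effect_log2: float,
                          dispersion: float,
                          library_sizes: tuple[Sequence[int], Sequence[int]] =
                          ((20_000_000,) * 3, (20_000_000,) * 3),
                          rng_seed: int = 0
                          ) -> tuple[CountTable, CountTable, list[tuple[str, str]], SimTruth]:
    """Orthologue count tables for two species under a negative-binomial model.

    Gene-level relative abundances are lognormal and shared between species;
    the designated target genes' species-A abundance is scaled by
    2**(-effect_log2). Counts for each sample are NB-distributed with
    variance mu + dispersion * mu^2 around library-scaled means. The
    orthologue map is the identity on gene ids. Gene ids follow ``g%05d``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if any(l <= 0 for libs in library_sizes for l in libs):
        raise ValueError("library sizes must be positive")
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    unknown = set(target_ids) - set(genes)
    if unknown:
        raise ValueError(f"target ids outside the gene universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(rng_seed)
    theta = rng.lognormal(mean=np.log(50.0), sigma=1.3, size=n_genes)
    is_target = np.array([g in target_ids for g in genes])
    theta_a = theta * np.where(is_target, 2.0 ** (-effect_log2), 1.0)
    size = 1.0 / dispersion  # NB shape: var = mu + dispersion * mu^2

    def draw(abund: np.ndarray, libs: Sequence[int], prefix: str) -> CountTable:
        frac = abund / abund.sum()
        data = {}
        for i, lib in enumerate(libs):
            mu = frac * lib
            data[f"{prefix}{i + 1}"] = rng.negative_binomial(size, size / (size + mu))
        df = pd.DataFrame(data, index=genes)
        return CountTable(df, {f"{prefix}{i + 1}": int(l) for i, l in enumerate(libs)})

    table_a = draw(theta_a, library_sizes[0], "a")
    table_b = draw(theta, library_sizes[1], "b")
    truth = SimTruth(target_effect=effect_log2, target_ids=sorted(target_ids))
    return table_a, table_b, [(g, g) for g in genes], truth


# ---------------------------------------------------------------------------
# Gene sets

def gen_gene_sets(universe: Sequence[str], n_sets: int, set_size: int,
                  planted_overlap: int, target_ids: set[str], rng_seed: int
                  ) -> tuple[dict[str, set[str]], SimTruth]:
    """Gene-set annotation with one deliberately enriched set.

    ``set_enriched`` contains exactly ``planted_overlap`` target genes plus
    fillers from outside the target set; the remaining sets are uniform
    samples from the universe.
    """
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")
    if planted_overlap > min(set_size, len(target_ids)):
        raise ValueError("planted_overlap exceeds set_size or the target set")
    rng = np.random.default_rng(rng_seed)
    sets: dict[str, set[str]] = {}
    truth = SimTruth(target_ids=sorted(target_ids))
    if n_sets > 0:
        targets = sorted(set(target_ids) & set(universe))
        non_targets = sorted(set(universe) - set(target_ids))
        if len(non_targets) < set_size - planted_overlap:
            raise ValueError("not enough non-target genes to fill the planted set")
        planted = set(rng.choice(targets, size=planted_overlap, replace=False))
        planted |= set(rng.choice(non_targets, size=set_size - planted_overlap,
                                  replace=False))
        sets["set_enriched"] = planted
        truth.enriched_set_id = "set_enriched"
        for i in range(1, n_sets):
            sets[f"set_{i}"] = set(rng.choice(universe, size=set_size, replace=False))
    return sets, truth
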