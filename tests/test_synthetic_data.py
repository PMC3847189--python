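import numpy as np
import pytest
from scipy import stats

from mirdiverge import synthetic_data as sd
from mirdiverge.expression_divergence import build_ratio_table, cdf_shift_test
from mirdiverge.homology import mature_match
from mirdiverge.mirna_catalog import family_seed_analysis
from mirdiverge.targeting import (TargetSiteCall, classify_site_conservation,
                                  find_seed_sites, normalized_site_divergence)


def planted_call(entry):
    gene, mirna, site_type, start, length, _ = entry
    return TargetSiteCall(gene, mirna, site_type, start, length)


class TestCatalogGenerator:
    def test_no_mutation_process_shares_one_seed(self):
        records, truth = sd.gen_mirna_catalog(1, 5, 0.0, 0.0, rng_seed=1)
        assert len({r.seed for r in records}) == 1
        assert all(rel == ("identical", 0) for rel in truth.member_relations.values())

    def test_determinism(self):
        a, _ = sd.gen_mirna_catalog(3, 4, 0.5, 0.5, rng_seed=9)
        b, _ = sd.gen_mirna_catalog(3, 4, 0.5, 0.5, rng_seed=9)
        assert a == b

    def test_all_shifted_family_recovered_by_seed_analysis(self):
        records, truth = sd.gen_mirna_catalog(1, 10, 1.0, 0.0, rng_seed=5)
        n_seeds, relations = family_seed_analysis(records)
        assert n_seeds >= 2
        shifts = {mid: s for mid, (rel, s) in truth.member_relations.items()}
        for rel in relations:
            delta = shifts[rel.member_b] - shifts[rel.member_a]
            if delta == 0:
                assert rel.relation == "identical"
            elif abs(delta) <= 3:
                assert rel.relation == f"shift({delta:+d})"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sd.gen_mirna_catalog(0, 5, 0.0, 0.0, rng_seed=1)
        with pytest.raises(ValueError):
            sd.gen_mirna_catalog(1, 5, 1.5, 0.0, rng_seed=1)


@pytest.fixture(scope="module")
def singleton_catalog():
    records, _ = sd.gen_mirna_catalog(3, 1, 0.0, 0.0, rng_seed=21)
    return records


class TestGenomeGenerator:

    def test_planted_mismatch_level_visible_to_hamming_scan(self, singleton_catalog):
        target = singleton_catalog[0]
        for level in (0, 1, 2):
            genomes, _ = sd.gen_species_genomes(
                singleton_catalog, [("sp", {target.mirna_id}, level, 0.0)],
                genome_len=6000, rng_seed=100 + level)
            hits = mature_match(target.mature_seq, genomes["sp"], 2)
            assert min(h.mismatches for h in hits) == level

    def test_level_three_rejected_by_step1(self, singleton_catalog):
        target = singleton_catalog[0]
        genomes, _ = sd.gen_species_genomes(
            singleton_catalog, [("sp", {target.mirna_id}, 3, 0.0)],
            genome_len=6000, rng_seed=103)
        assert mature_match(target.mature_seq, genomes["sp"], 2) == []

    def test_non_carriers_have_no_near_match(self, singleton_catalog):
        genomes, _ = sd.gen_species_genomes(
            singleton_catalog, [("sp", {singleton_catalog[0].mirna_id}, 0, 0.5)],
            genome_len=6000, rng_seed=104)
        for rec in singleton_catalog[1:]:
            assert mature_match(rec.mature_seq, genomes["sp"], 2) == []

    def test_truth_positions_resolve_to_planted_hairpins(self, singleton_catalog):
        genomes, truth = sd.gen_species_genomes(
            singleton_catalog, [("sp", {singleton_catalog[0].mirna_id}, 0, 0.0)],
            genome_len=6000, rng_seed=105)
        mid, species, chrom, start, end, strand = truth.planted_positions[0]
        from mirdiverge._seq import to_dna
        assert genomes[species][start:end] == to_dna(singleton_catalog[0].hairpin_seq)

    def test_hairpin_longer_than_genome_rejected(self, singleton_catalog):
        with pytest.raises(ValueError):
            sd.gen_species_genomes(singleton_catalog, [("sp", set(), 0, 0.0)],
                                   genome_len=10, rng_seed=1)

    def test_determinism(self, singleton_catalog):
        spec = [("sp", {singleton_catalog[0].mirna_id}, 1, 0.5)]
        g1, _ = sd.gen_species_genomes(singleton_catalog, spec, 6000, rng_seed=7)
        g2, _ = sd.gen_species_genomes(singleton_catalog, spec, 6000, rng_seed=7)
        assert g1 == g2


class TestUTRGenerator:

    def test_zero_rates_identical_rows_and_conserved_sites(self, singleton_catalog):
        blocks, truth = sd.gen_utr_alignment_set(
            30, ["cow", "human", "mouse"], singleton_catalog, (1.0, 1.0),
            0.0, 0.0, 0.0, utr_len=140, rng_seed=41)
        for b in blocks:
            assert len({seq for _, seq in b.rows}) == 1
        for entry in truth.planted_sites:
            block = next(b for b in blocks if b.gene_id == entry[0])
            assert classify_site_conservation(planted_call(entry), block,
                                              ("human", "mouse")) == "conserved"
            assert all(entry[5].values())

    def test_zero_retention_all_reference_specific(self, singleton_catalog):
        blocks, truth = sd.gen_utr_alignment_set(
            30, ["cow", "human"], singleton_catalog, (1.0, 0.0),
            0.0, 0.0, 0.0, utr_len=140, rng_seed=42)
        assert truth.planted_sites
        for entry in truth.planted_sites:
            block = next(b for b in blocks if b.gene_id == entry[0])
            assert classify_site_conservation(planted_call(entry), block,
                                              ("human",)) == "reference_specific"

    def test_planted_sites_found_by_site_scan(self, singleton_catalog):
        blocks, truth = sd.gen_utr_alignment_set(
            40, ["cow", "human"], singleton_catalog, (1.0, 1.0),
            0.0, 0.0, 0.0, utr_len=140, rng_seed=43)
        seeds = {r.mirna_id: r.seed for r in singleton_catalog}
        for gene, mirna, site_type, start, length, _ in truth.planted_sites:
            block = next(b for b in blocks if b.gene_id == gene)
            calls = find_seed_sites(seeds[mirna], block.ref_ungapped,
                                    mirna_id=mirna)
            assert any(c.ref_start == start and c.site_type == site_type
                       for c in calls)

    def test_alignments_rectangular_with_indels(self, singleton_catalog):
        blocks, _ = sd.gen_utr_alignment_set(
            20, ["cow", "human", "rat"], singleton_catalog, (0.5, 0.8),
            0.2, 0.1, 0.05, utr_len=140, rng_seed=44)
        for b in blocks:
            assert len({len(seq) for _, seq in b.rows}) == 1
            assert "-" not in b.ref_seq  # reference stays contiguous

    def test_empirical_rates_converge(self, singleton_catalog):
        """Substitution fractions over many sites approach the configured
        rates; mean normalized divergence ~ p_site - p_flank (3 SE)."""
        p_site, p_flank = 0.3, 0.1
        blocks, truth = sd.gen_utr_alignment_set(
            600, ["cow", "human"], singleton_catalog, (1.0, 1.0),
            p_site, p_flank, 0.0, utr_len=150, rng_seed=45)
        vals = []
        for entry in truth.planted_sites:
            block = next(b for b in blocks if b.gene_id == entry[0])
            vals.append(normalized_site_divergence(
                planted_call(entry), block, "human").normalized)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (p_site - p_flank)) < 3 * se

    def test_bad_rate_rejected(self, singleton_catalog):
        with pytest.raises(ValueError):
            sd.gen_utr_alignment_set(5, ["cow", "human"], singleton_catalog, (1.0, 1.0),
                                     1.2, 0.0, 0.0, 140, rng_seed=1)


class TestExpressionGenerator:
    def test_determinism(self):
        t = {f"g{i + 1:05d}" for i in range(50)}
        a1, b1, m1, _ = sd.gen_expression_tables(500, t, 1.0, 0.1, rng_seed=3)
        a2, b2, m2, _ = sd.gen_expression_tables(500, t, 1.0, 0.1, rng_seed=3)
        assert a1.counts.equals(a2.counts) and b1.counts.equals(b2.counts)
        assert m1 == m2

    def test_unknown_targets_rejected(self):
        with pytest.raises(ValueError):
            sd.gen_expression_tables(10, {"nope"}, 1.0, 0.1, rng_seed=1)

    def test_null_effect_rarely_significant(self):
        """With no planted effect the target-vs-background KS test should
        behave like a null test (alpha 0.01, 40 replicates)."""
        rejections = 0
        targets = {f"g{i + 1:05d}" for i in range(200)}
        for seed in range(40):
            a, b, omap, truth = sd.gen_expression_tables(
                1500, targets, 0.0, 0.1,
                library_sizes=((20_000_000,), (20_000_000,)), rng_seed=seed)
            table = build_ratio_table(a, b, omap)
            _, p, _ = cdf_shift_test(table.ratios(truth.target_ids),
                                     table.ratios())
            rejections += p < 0.01
        assert rejections <= 3  # far above the binomial upper band already

    def test_planted_effect_detected(self):
        targets = {f"g{i + 1:05d}" for i in range(500)}
        detections = 0
        for seed in range(10):
            a, b, omap, truth = sd.gen_expression_tables(
                3000, targets, 1.0, 0.1,
                library_sizes=((20_000_000,), (20_000_000,)), rng_seed=seed)
            table = build_ratio_table(a, b, omap)
            _, p, direction = cdf_shift_test(table.ratios(truth.target_ids),
                                             table.ratios())
            detections += p < 0.01 and direction == -1
        assert detections == 10

    def test_overdispersion_visible(self):
        # NB variance should exceed Poisson at high means
        a, _, _, _ = sd.gen_expression_tables(
            2000, set(), 0.0, 0.5,
            library_sizes=((10**7,) * 3, (10**7,)), rng_seed=8)
        counts = a.counts.to_numpy(dtype=float)
        means = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        big = means > 200
        assert (var[big] > means[big]).mean() > 0.9


class TestGeneSetGenerator:
    def test_planted_overlap_exact(self):
        uni = [f"g{i}" for i in range(500)]
        targets = set(uni[:60])
        sets, truth = sd.gen_gene_sets(uni, 6, 25, 15, targets, rng_seed=9)
        assert len(sets[truth.enriched_set_id] & targets) == 15
        assert all(len(s) == 25 for s in sets.values())

    def test_zero_sets(self):
        sets, truth = sd.gen_gene_sets(["g1", "g2"], 0, 1, 0, set(), rng_seed=1)
        assert sets == {} and truth.enriched_set_id is None

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            sd.gen_gene_sets(["g1"], 1, 5, 0, set(), rng_seed=1)

    def test_determinism(self):
        uni = [f"g{i}" for i in range(100)]
        s1, _ = sd.gen_gene_sets(uni, 4, 10, 5, set(uni[:20]), rng_seed=2)
        s2, _ = sd.gen_gene_sets(uni, 4, 10, 5, set(uni[:20]), rng_seed=2)
        assert s1 == s2
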