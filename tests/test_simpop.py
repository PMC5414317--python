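import numpy as np
import pytest
from scipy import stats

from rdnakit.iocore import ValidationError
from rdnakit import simpop
from rdnakit.simpop import (
    RDNA2,
    RDNA4,
    ClusterHaplotype,
    DominanceRuleTable,
    GenomeMap,
    apply_dominance,
    codominant_rules,
    expected_fractions,
    inbred_silencing_rules,
    make_cluster_haplotype,
    make_founder_panel,
    simulate_counts,
    simulate_cross,
    simulate_rnaseq_snp_counts,
    two_locus_recessive_rules,
)


class TestMakeClusterHaplotype:
    def test_zero_variants_empty_composition(self):
        hap = make_cluster_haplotype("h", RDNA2, 0, 100, seed=1)
        assert hap.composition == {}

    def test_deterministic_given_seed(self):
        h1 = make_cluster_haplotype("h", RDNA4, 5, 100, seed=42)
        h2 = make_cluster_haplotype("h", RDNA4, 5, 100, seed=42)
        assert h1 == h2

    def test_point_mass_distribution_fully_homogenized(self):
        hap = make_cluster_haplotype(
            "h", RDNA2, 4, 100, fraction_distribution=lambda r: 1.0, seed=3
        )
        assert all(f == 1.0 for f in hap.composition.values())

    def test_too_many_variants_rejected(self):
        with pytest.raises(ValidationError):
            make_cluster_haplotype("h", RDNA2, 100, 10, seed=1, span=(300, 350))

    def test_positions_unique_and_in_span(self):
        from rdnakit.iocore import parse_variant_name

        hap = make_cluster_haplotype("h", RDNA2, 50, 100, seed=9)
        positions = [parse_variant_name(v)[0] for v in hap.composition]
        assert len(set(positions)) == 50
        assert all(300 <= p <= 8009 for p in positions)


class TestFounderPanel:
    def test_variants_are_founder_private(self):
        from rdnakit.iocore import parse_variant_name

        founders = make_founder_panel(5, n_variants_per_haplotype=3, seed=2)
        positions = [
            parse_variant_name(v)[0]
            for f in founders
            for hap in (f.rdna2, f.rdna4)
            for v in hap.composition
        ]
        assert len(positions) == len(set(positions))


class TestSimulateCross:
    def test_f1_all_heterozygous(self, two_founders, small_gmap):
        genomes = simulate_cross("f1", two_founders, 10, seed=1, genome_map=small_gmap)
        p, q = two_founders
        for g in genomes:
            assert set(g.rdna2) == {p.rdna2.id, q.rdna2.id}
            assert set(g.rdna4) == {p.rdna4.id, q.rdna4.id}

    def test_f2_segregates_1_2_1(self, two_founders, small_gmap):
        genomes = simulate_cross("f2", two_founders, 4000, seed=7, genome_map=small_gmap)
        p = two_founders[0]
        hom_a = sum(1 for g in genomes if g.rdna2 == (p.rdna2.id, p.rdna2.id))
        # binomial SE for p=0.25 at n=4000 is ~0.0068; spec tolerance 0.02
        assert abs(hom_a / 4000 - 0.25) < 0.02

    def test_two_locus_independence(self, two_founders, small_gmap):
        genomes = simulate_cross("f2", two_founders, 4000, seed=8, genome_map=small_gmap)
        p = two_founders[0]

        def cls(pair, hap):
            n = sum(1 for h in pair if h == hap)
            return n

        table = np.zeros((3, 3))
        for g in genomes:
            table[cls(g.rdna2, p.rdna2.id), cls(g.rdna4, p.rdna4.id)] += 1
        _, pval, _, _ = stats.chi2_contingency(table)
        assert pval > 0.05

    def test_magic_needs_three_founders(self, two_founders, small_gmap):
        with pytest.raises(ValidationError):
            simulate_cross("magic_mosaic", two_founders, 5, seed=1, genome_map=small_gmap)

    def test_magic_rdna_matches_flanking_founder(self, small_gmap):
        founders = make_founder_panel(5, seed=3)
        genomes = simulate_cross("magic_mosaic", founders, 30, seed=4, genome_map=small_gmap)
        by_id = {f.id: f for f in founders}
        for g in genomes:
            f2 = str(g.markers["2"][0])
            f4 = str(g.markers["4"][0])
            assert g.rdna2 == (by_id[f2].rdna2.id,) * 2
            assert g.rdna4 == (by_id[f4].rdna4.id,) * 2

    def test_mosaic_labels_are_founders(self, small_gmap):
        founders = make_founder_panel(4, seed=5)
        fids = {f.id for f in founders}
        genomes = simulate_cross("magic_mosaic", founders, 10, seed=6, genome_map=small_gmap)
        for g in genomes:
            for labels in g.markers.values():
                assert set(map(str, labels)) <= fids

    def test_unknown_design(self, two_founders):
        with pytest.raises(ValidationError):
            simulate_cross("backcross", two_founders, 5, seed=1)


class TestDominance:
    def test_col0_like_reference_rule(self, two_founders):
        p, _ = two_founders
        rules = inbred_silencing_rules([p], {p.id: RDNA4})
        genome = simpop.IndividualGenome(
            "i", (p.rdna2.id, p.rdna2.id), (p.rdna4.id, p.rdna4.id)
        )
        acts = apply_dominance(genome, rules)
        assert acts[p.rdna2.id] == 0.0
        assert acts[p.rdna4.id] == 1.0

    def test_heterozygote_dominance_rule(self, two_founders):
        # one founder's rDNA-2 silenced when combined with the other's rDNA-4
        p, q = two_founders
        rules = DominanceRuleTable()
        ids = [p.rdna2.id, p.rdna2.id, q.rdna4.id, q.rdna4.id]
        rules.set_rule(ids, {p.rdna2.id: 0.0, q.rdna4.id: 1.0})
        genome = simpop.IndividualGenome("i", (p.rdna2.id, p.rdna2.id), (q.rdna4.id, q.rdna4.id))
        acts = apply_dominance(genome, rules)
        assert acts[p.rdna2.id] == 0.0
        assert acts[q.rdna4.id] == 1.0

    def test_codominant_f1(self, two_founders):
        p, q = two_founders
        genome = simpop.IndividualGenome("i", (p.rdna2.id, q.rdna2.id), (p.rdna4.id, q.rdna4.id))
        acts = apply_dominance(genome, codominant_rules())
        assert all(a == 1.0 for a in acts.values())

    def test_uncovered_genotype_raises(self, two_founders):
        p, q = two_founders
        genome = simpop.IndividualGenome("i", (p.rdna2.id, q.rdna2.id), (p.rdna4.id, q.rdna4.id))
        with pytest.raises(KeyError):
            apply_dominance(genome, DominanceRuleTable())

    def test_all_silent_rule_rejected(self, two_founders):
        p, _ = two_founders
        rules = DominanceRuleTable()
        with pytest.raises(ValidationError):
            rules.set_rule(
                [p.rdna2.id, p.rdna2.id, p.rdna4.id, p.rdna4.id],
                {p.rdna2.id: 0.0, p.rdna4.id: 0.0},
            )


class TestExpectedFractions:
    def _setup(self, frac=1.0, cn=(100, 100, 100, 100)):
        h2a = ClusterHaplotype("a.rDNA2", RDNA2, cn[0], {"X1000.A.G": frac})
        h2b = ClusterHaplotype("b.rDNA2", RDNA2, cn[1], {"X1000.A.G": frac})
        h4a = ClusterHaplotype("a.rDNA4", RDNA4, cn[2], {})
        h4b = ClusterHaplotype("b.rDNA4", RDNA4, cn[3], {})
        haps = {h.id: h for h in (h2a, h2b, h4a, h4b)}
        genome = simpop.IndividualGenome("i", ("a.rDNA2", "b.rDNA2"), ("a.rDNA4", "b.rDNA4"))
        return genome, haps

    def test_dna_fraction_copy_weighted(self):
        genome, haps = self._setup()
        acts = {h: 1.0 for h in haps}
        exp = expected_fractions(genome, acts, haps)
        assert exp.loc[0, "dna_fraction"] == pytest.approx(0.5)

    def test_silenced_cluster_zero_rna(self):
        genome, haps = self._setup()
        acts = {"a.rDNA2": 0.0, "b.rDNA2": 0.0, "a.rDNA4": 1.0, "b.rDNA4": 1.0}
        exp = expected_fractions(genome, acts, haps)
        assert exp.loc[0, "rna_fraction"] == 0.0

    def test_fully_active_rna_equals_dna(self):
        genome, haps = self._setup(frac=0.7, cn=(80, 120, 150, 50))
        acts = {h: 1.0 for h in haps}
        exp = expected_fractions(genome, acts, haps)
        assert exp.loc[0, "rna_fraction"] == pytest.approx(exp.loc[0, "dna_fraction"])


class TestSimulateCounts:
    def test_empirical_fraction_matches_expectation(self):
        # >= 200 replicates within 3 Monte-Carlo SE of the analytic value
        h2 = ClusterHaplotype("p.rDNA2", RDNA2, 100, {"X1000.A.G": 0.6})
        h4 = ClusterHaplotype("p.rDNA4", RDNA4, 100, {})
        haps = {h.id: h for h in (h2, h4)}
        genome = simpop.IndividualGenome("i", ("p.rDNA2",) * 2, ("p.rDNA4",) * 2)
        acts = {h: 1.0 for h in haps}
        cfg = simpop.SimConfig(coverage_dna=200, coverage_rna=50, seed=0)
        rng = np.random.default_rng(12)
        fractions, depths = [], []
        for _ in range(250):
            dna, _ = simulate_counts(genome, acts, cfg, haps, rng=rng)
            alt = dna.data[dna.data["allele"] == "G"]
            tot = dna.data[["fwd", "rev"]].to_numpy().sum()
            fractions.append((alt["fwd"].sum() + alt["rev"].sum()) / tot)
            depths.append(tot)
        f_true = 0.3  # 0.6 on both rDNA-2 copies, half the copy pool
        se = np.sqrt(f_true * (1 - f_true) / np.mean(depths) / len(fractions))
        assert abs(np.mean(fractions) - f_true) < 3 * se

    def test_strand_artifact_collapses_minor_strand(self):
        h2 = ClusterHaplotype("p.rDNA2", RDNA2, 100, {"X1000.A.G": 0.8})
        h4 = ClusterHaplotype("p.rDNA4", RDNA4, 100, {})
        haps = {h.id: h for h in (h2, h4)}
        genome = simpop.IndividualGenome("i", ("p.rDNA2",) * 2, ("p.rDNA4",) * 2)
        acts = {h: 1.0 for h in haps}
        cfg = simpop.SimConfig(coverage_dna=200, strand_artifact_rate=1.0, seed=1)
        dna, _ = simulate_counts(genome, acts, cfg, haps)
        alt = dna.data[dna.data["allele"] == "G"].iloc[0]
        assert alt["fwd"] == 0 or alt["rev"] == 0

    def test_determinism(self):
        h2 = ClusterHaplotype("p.rDNA2", RDNA2, 100, {"X1000.A.G": 0.5})
        h4 = ClusterHaplotype("p.rDNA4", RDNA4, 100, {})
        haps = {h.id: h for h in (h2, h4)}
        genome = simpop.IndividualGenome("i", ("p.rDNA2",) * 2, ("p.rDNA4",) * 2)
        acts = {h: 1.0 for h in haps}
        cfg = simpop.SimConfig(seed=77)
        d1, r1 = simulate_counts(genome, acts, cfg, haps)
        d2, r2 = simulate_counts(genome, acts, cfg, haps)
        assert d1.data.equals(d2.data) and r1.data.equals(r2.data)


class TestSnpCounts:
    def test_hom_sites_read_one_parent(self, two_founders, small_gmap):
        genomes = simulate_cross("f2", two_founders, 1, seed=3, genome_map=small_gmap)
        genomes[0].markers = {c: np.full(len(p), "A", dtype=object) for c, p in small_gmap.positions.items()}
        counts = simulate_rnaseq_snp_counts(genomes, small_gmap, error_rate=0.0, seed=1)
        df = counts[genomes[0].id]
        assert (df["nB"] == 0).all()
        assert (df["nA"] >= 1).all()

    def test_het_sites_half_and_half(self, two_founders, small_gmap):
        gmap = simpop.GenomeMap.regular(n_chromosomes=5, n_markers=2000)
        genomes = simulate_cross("f1", two_founders, 1, seed=3, genome_map=gmap)
        counts = simulate_rnaseq_snp_counts(genomes, gmap, seed=2)
        df = counts[genomes[0].id]
        frac_a = df["nA"].sum() / (df["nA"] + df["nB"]).sum()
        assert abs(frac_a - 0.5) < 0.01

    def test_determinism(self, two_founders, small_gmap):
        genomes = simulate_cross("f2", two_founders, 3, seed=3, genome_map=small_gmap)
        c1 = simulate_rnaseq_snp_counts(genomes, small_gmap, seed=9)
        c2 = simulate_rnaseq_snp_counts(genomes, small_gmap, seed=9)
        for ind in c1:
            assert c1[ind].equals(c2[ind])


class TestTwoLocusRecessiveRules:
    def test_recessives_active_only_in_double_homozygote(self, two_founders):
        p, q = two_founders
        rules = two_locus_recessive_rules(p, q)
        double = simpop.IndividualGenome("d", (p.rdna2.id,) * 2, (q.rdna4.id,) * 2)
        acts = apply_dominance(double, rules)
        assert acts[p.rdna2.id] == 1.0 and acts[q.rdna4.id] == 1.0
        single = simpop.IndividualGenome("s", (p.rdna2.id,) * 2, (p.rdna4.id, q.rdna4.id))
        acts = apply_dominance(single, rules)
        assert acts[p.rdna2.id] == 0.0 and acts[q.rdna4.id] == 0.0
        assert acts[p.rdna4.id] == 1.0

    def test_all_nine_classes_covered(self, two_founders):
        p, q = two_founders
        rules = two_locus_recessive_rules(p, q)
        for g2 in [(p.rdna2.id,) * 2, (p.rdna2.id, q.rdna2.id), (q.rdna2.id,) * 2]:
            for g4 in [(p.rdna4.id,) * 2, (p.rdna4.id, q.rdna4.id), (q.rdna4.id,) * 2]:
                genome = simpop.IndividualGenome("i", g2, g4)
                assert apply_dominance(genome, rules)


class TestTruthRoundTrip:
    def test_round_trip(self, tmp_path, two_founders, small_gmap):
        genomes = simulate_cross("f2", two_founders, 3, seed=5, genome_map=small_gmap)
        haps = {h.id: h for f in two_founders for h in (f.rdna2, f.rdna4)}
        path = tmp_path / "truth.json"
        simpop.write_truth(genomes, haps, path, genome_map=small_gmap)
        back_genomes, back_haps, gmap, _ = simpop.read_truth(path)
        assert [g.id for g in back_genomes] == [g.id for g in genomes]
        assert set(back_haps) == set(haps)
        assert gmap is not None
        for g1, g2 in zip(genomes, back_genomes):
            assert tuple(g1.rdna2) == tuple(g2.rdna2)
            for c in g1.markers:
                assert list(map(str, g1.markers[c])) == list(map(str, g2.markers[c]))
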