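"""Generator behaviour: determinism, allele conservation, event sampling,
tract mechanics, Mendelian segregation, marker selection, and read emission."""

import numpy as np
import pytest
from scipy.stats import chisquare

from ihrkit.markers import DsbTarget
from ihrkit.simulate import (
    F2Plant,
    Gamete,
    GenotypeObservations,
    SimulationConfig,
    TractModel,
    apply_marker_selection,
    apply_repair_event,
    emit_amplicon_molecules,
    emit_observations,
    make_f1,
    make_marker_map,
    make_tract_f2_plant,
    read_molecules_tsv,
    read_observations_tsv,
    simulate_conversion_tract,
    simulate_f2_population,
    simulate_repair_event,
    write_molecules_tsv,
    write_observations_tsv,
)


def small_config(**kw):
    defaults = dict(seed=7, chromosomes=(("Chr3", 100_000),), marker_density_per_kb=1.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestMarkerMap:
    def test_count_order_uniqueness(self):
        mm = make_marker_map(small_config())
        chrom = mm["Chr3"]
        assert chrom.n_markers == 100
        assert np.all(np.diff(chrom.positions) > 0)
        assert np.all(chrom.allele_p1 != chrom.allele_p2)
        assert chrom.positions[0] >= 1 and chrom.positions[-1] <= 100_000

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            small_config(marker_density_per_kb=0.0)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            small_config(chromosomes=(("Chr3", 0),))

    def test_deterministic_given_seed(self):
        a = make_marker_map(small_config())
        b = make_marker_map(small_config())
        assert np.array_equal(a["Chr3"].positions, b["Chr3"].positions)
        assert np.array_equal(a["Chr3"].allele_p2, b["Chr3"].allele_p2)


class TestRepairEvents:
    def test_p2_only_guide_never_hits_p1(self, rng):
        """Allele-specific cutting: with a PAM SNP on P1, every event sits on
        the P2 homolog — the in-silico analogue of finding no indel
        footprints on the Col chromosome."""
        cfg = small_config(p_nhej=0.5, p_nco=0.3, p_co=0.1)
        mm = make_marker_map(cfg)
        target = DsbTarget(id="t", chromosome="Chr3", cut_position=50_000, allele_specificity="P2_only")
        events = [simulate_repair_event(target, mm, cfg, rng) for _ in range(10_000)]
        assert all(e.affected_haplotype == "P2" for e in events)

    def test_zero_probabilities_give_no_events(self, rng):
        cfg = small_config(p_nhej=0.0, p_nco=0.0, p_co=0.0)
        mm = make_marker_map(cfg)
        target = DsbTarget(id="t", chromosome="Chr3", cut_position=50_000)
        assert all(
            simulate_repair_event(target, mm, cfg, rng).kind == "none" for _ in range(200)
        )

    def test_point_mass_spectrum(self, rng):
        cfg = small_config(p_nhej=1.0, p_nco=0.0, p_co=0.0, indel_spectrum={"+1": 1.0})
        mm = make_marker_map(cfg)
        target = DsbTarget(id="t", chromosome="Chr3", cut_position=50_000)
        for _ in range(50):
            ev = simulate_repair_event(target, mm, cfg, rng)
            assert ev.kind == "nhej"
            assert ev.indel.startswith("+") and len(ev.indel) == 2


class TestConversionTract:
    def test_full_conversion_is_simple(self, rng):
        cfg = small_config()
        chrom = make_marker_map(cfg)["Chr3"]
        tr = simulate_conversion_tract(50_000, TractModel(mean_side_bp=2000, p_conv=1.0), chrom, rng)
        assert tr.converted.all()
        assert tr.is_simple

    def test_no_conversion_at_p_zero(self, rng):
        cfg = small_config()
        chrom = make_marker_map(cfg)["Chr3"]
        tr = simulate_conversion_tract(50_000, TractModel(mean_side_bp=2000, p_conv=0.0), chrom, rng)
        assert not tr.converted.any()

    def test_per_marker_conversion_probability(self, rng):
        """Binomial oracle: pooled over tracts with >= 3 in-tract markers, the
        converted fraction sits within 3 SE of p_conv."""
        cfg = small_config(chromosomes=(("Chr3", 200_000),), marker_density_per_kb=2.0)
        chrom = make_marker_map(cfg)["Chr3"]
        model = TractModel(mean_side_bp=1500, p_conv=0.7)
        total = conv = 0
        for _ in range(5000):
            tr = simulate_conversion_tract(100_000, model, chrom, rng)
            if tr.marker_indices.size >= 3:
                total += tr.marker_indices.size
                conv += int(tr.converted.sum())
        se = np.sqrt(0.7 * 0.3 / total)
        assert abs(conv / total - 0.7) < 3 * se

    def test_converted_markers_inside_interval(self, rng):
        cfg = small_config()
        chrom = make_marker_map(cfg)["Chr3"]
        for _ in range(200):
            tr = simulate_conversion_tract(50_000, TractModel(mean_side_bp=800, p_conv=0.5), chrom, rng)
            pos = chrom.positions[tr.converted_indices]
            assert np.all((pos >= tr.interval[0]) & (pos <= tr.interval[1]))


class TestF2Population:
    def test_mendelian_segregation_without_recombination(self):
        """No meiotic COs and no induced events: marker genotypes across
        plants follow the 1:2:1 Mendelian ratio (chi-square oracle)."""
        cfg = small_config(seed=3, marker_density_per_kb=0.05, meiotic_co_rate=0.0)
        rng = np.random.default_rng(cfg.seed)
        mm = make_marker_map(cfg, rng)
        f1 = make_f1(mm)
        plants = simulate_f2_population(f1, mm, cfg, rng, n=2000)
        genos = np.array([p.genotype("Chr3")[0] for p in plants])
        counts = [np.sum(genos == g) for g in (0, 1, 2)]
        _, p = chisquare(counts, f_exp=[500, 1000, 500])
        assert p > 1e-3

    def test_two_alleles_per_marker_and_no_novel_alleles(self, rng):
        cfg = small_config()
        mm = make_marker_map(cfg, rng)
        f1 = make_f1(mm)
        for plant in simulate_f2_population(f1, mm, cfg, rng, n=20):
            g = plant.genotype("Chr3")
            assert g.min() >= 0 and g.max() <= 2

    def test_homozygous_converted_tract_breeds_true(self, rng):
        """If the F1 carries the conversion on both haplotypes, every F2 is
        homozygous donor across the tract."""
        cfg = small_config(p_nco=1.0, p_nhej=0.0, p_co=0.0)
        mm = make_marker_map(cfg, rng)
        target = DsbTarget(id="t", chromosome="Chr3", cut_position=50_000)
        f1 = make_f1(mm)
        ev = simulate_repair_event(target, mm, cfg, rng)
        apply_repair_event(f1, ev, mm, target)
        idx = ev.tract.converted_indices
        # conversion copies the donor allele, so both haplotypes now agree at idx
        donor_allele = f1.haplotypes[1].alleles["Chr3"][idx]
        for plant in simulate_f2_population(f1, mm, cfg, rng, n=10):
            assert np.array_equal(plant.genotype("Chr3")[idx], 2 * donor_allele.astype(np.int64))

    def test_seeded_run_reproducible(self):
        def run():
            cfg = small_config(seed=11)
            rng = np.random.default_rng(cfg.seed)
            mm = make_marker_map(cfg, rng)
            plants = simulate_f2_population(make_f1(mm), mm, cfg, rng, n=5)
            return np.concatenate([p.genotype("Chr3") for p in plants])

        assert np.array_equal(run(), run())


class TestMarkerSelection:
    def _plant(self, origins_g1, origins_g2, bps1=(), bps2=()):
        def gamete(start, bps):
            return Gamete(
                alleles={"Chr3": np.zeros(1, dtype=np.int8)},
                source_start={"Chr3": start},
                breakpoints={"Chr3": np.array(bps, dtype=np.int64)},
            )

        return F2Plant("p", (gamete(origins_g1, bps1), gamete(origins_g2, bps2)))

    MARKERS = (("Chr3", 256_516), ("Chr3", 5_361_637))

    def test_all_mode_is_identity(self):
        pop = [self._plant(0, 1)]
        assert apply_marker_selection(pop, "all", self.MARKERS) == pop

    def test_without_recombination_selection_is_empty(self):
        """Non-recombinant gametes carry both transgenes or neither, so the
        single-fluorophore classes are empty (enumerated genotypes)."""
        pop = [self._plant(a, b) for a in (0, 1) for b in (0, 1)]
        assert apply_marker_selection(pop, "RFP_only", self.MARKERS) == []
        assert apply_marker_selection(pop, "GFP_only", self.MARKERS) == []

    def test_co_between_markers_passes_exactly_one_mode(self):
        # gamete 1 switches P1 -> P2 between the transgenes; gamete 2 is P2
        plant = self._plant(0, 1, bps1=(1_000_000,))
        rfp = apply_marker_selection([plant], "RFP_only", self.MARKERS)
        gfp = apply_marker_selection([plant], "GFP_only", self.MARKERS)
        assert len(rfp) + len(gfp) == 1

    def test_markers_on_different_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            apply_marker_selection([], "RFP_only", (("Chr1", 10), ("Chr3", 20)))


class TestEmitObservations:
    def _hom_p1_plant(self, mm):
        z = np.zeros(mm["Chr3"].n_markers, dtype=np.int8)
        e = np.array([], dtype=np.int64)
        g = Gamete(alleles={"Chr3": z}, source_start={"Chr3": 0}, breakpoints={"Chr3": e})
        g2 = Gamete(alleles={"Chr3": z.copy()}, source_start={"Chr3": 0}, breakpoints={"Chr3": e})
        return F2Plant("p", (g, g2))

    def test_error_free_homozygote_has_no_opposite_reads(self, rng):
        mm = make_marker_map(small_config())
        obs = emit_observations(self._hom_p1_plant(mm), mm, 20.0, 0.0, rng)
        assert obs.counts["Chr3"][1].sum() == 0

    def test_heterozygote_allele_balance(self, rng):
        """Binomial oracle: pooled P1 read fraction at het markers within
        3 SE of 0.5 at coverage 30."""
        cfg = small_config(chromosomes=(("Chr3", 10_000_000),))
        mm = make_marker_map(cfg, rng)
        m = mm["Chr3"].n_markers
        e = np.array([], dtype=np.int64)
        g1 = Gamete(alleles={"Chr3": np.zeros(m, dtype=np.int8)}, source_start={"Chr3": 0}, breakpoints={"Chr3": e})
        g2 = Gamete(alleles={"Chr3": np.ones(m, dtype=np.int8)}, source_start={"Chr3": 1}, breakpoints={"Chr3": e})
        obs = emit_observations(F2Plant("p", (g1, g2)), mm, 30.0, 0.0, rng)
        n1, n2 = obs.counts["Chr3"]
        total = (n1 + n2).sum()
        se = np.sqrt(0.25 / total)
        assert abs(n1.sum() / total - 0.5) < 3 * se

    def test_zero_coverage_gives_zero_counts(self, rng):
        mm = make_marker_map(small_config())
        obs = emit_observations(self._hom_p1_plant(mm), mm, 0.0, 0.0, rng)
        assert obs.counts["Chr3"][0].sum() == 0 and obs.counts["Chr3"][1].sum() == 0

    def test_observations_tsv_round_trip(self, rng, tmp_path):
        mm = make_marker_map(small_config())
        obs = emit_observations(self._hom_p1_plant(mm), mm, 10.0, 0.01, rng)
        path = tmp_path / "obs.tsv"
        write_observations_tsv([obs], mm, path)
        (back,) = read_observations_tsv(path, mm)
        assert np.array_equal(back.counts["Chr3"][0], obs.counts["Chr3"][0])
        assert np.array_equal(back.counts["Chr3"][1], obs.counts["Chr3"][1])


class TestAmpliconMolecules:
    def test_error_free_parental_mixture_has_two_patterns(self, rng):
        mol = emit_amplicon_molecules(
            [("1111", "", 0.5), ("2222", "", 0.5)], 500, rng, miscall_rate=0.0
        )
        assert set(mol["haplotype_pattern"]) == {"1111", "2222"}

    def test_minor_class_frequency_recovered(self, rng):
        """Binomial oracle at n = 5000 for a 12% exchange+indel class."""
        mix = [("1111111", "", 0.5), ("2222222", "", 0.38), ("2221111", "+T", 0.12)]
        mol = emit_amplicon_molecules(mix, 5000, rng, miscall_rate=0.0)
        f = (mol["indel_signature"] == "+T").mean()
        se = np.sqrt(0.12 * 0.88 / 5000)
        assert abs(f - 0.12) < 3 * se

    def test_zero_molecules_gives_empty_table(self, rng):
        mol = emit_amplicon_molecules([("11", "", 1.0)], 0, rng)
        assert len(mol) == 0

    def test_molecules_tsv_round_trip(self, rng, tmp_path):
        mol = emit_amplicon_molecules([("12", "", 0.5), ("21", "+T", 0.5)], 100, rng)
        path = tmp_path / "mol.tsv"
        write_molecules_tsv(mol, path)
        back = read_molecules_tsv(path)
        assert list(back["indel_signature"]) == list(mol["indel_signature"])
        assert list(back["haplotype_pattern"]) == list(mol["haplotype_pattern"])


class TestP2OnlyInvariant:
    def test_p1_haplotype_untouched_across_population(self, rng):
        """With an allele-specific guide the P1 haplotype is invariant: no
        marker allele on haplotype 0 ever changes."""
        cfg = small_config(p_nhej=0.3, p_nco=0.5, p_co=0.2)
        mm = make_marker_map(cfg, rng)
        target = DsbTarget(id="t", chromosome="Chr3", cut_position=50_000, allele_specificity="P2_only")
        for _ in range(100):
            f1 = make_f1(mm)
            ev = simulate_repair_event(target, mm, cfg, rng)
            apply_repair_event(f1, ev, mm, target)
            if ev.kind != "co":  # a CO legitimately exchanges arms
                assert f1.haplotypes[0].alleles["Chr3"].sum() == 0
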