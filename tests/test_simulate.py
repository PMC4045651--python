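import numpy as np
import pytest

from duoburden.duos import attribute_origin, detect_compound_het
from duoburden.filtering import filter_variants
from duoburden.model import Role, validate_duo_pairing
from duoburden.simulate import (
    SimulationConfig,
    filtered_profiles,
    generate_cohort,
    write_fixture_bundle,
)
from duoburden.variant_io import read_gene_set, read_vcf


def tiny_config(**kw):
    defaults = dict(
        seed=5,
        n_duos_all=2,
        n_duos_aml=1,
        n_controls=2,
        n_genes=100,
        candidate_fraction=0.1,
        baseline_rate=0.6,
        planted_compound_het_genes=(("G0001", 1.0),),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = generate_cohort(tiny_config())
        b = generate_cohort(tiny_config())
        assert a.variants == b.variants
        assert a.truth.origin == b.truth.origin

    def test_different_seeds_differ(self):
        a = generate_cohort(tiny_config(seed=1))
        b = generate_cohort(tiny_config(seed=2))
        assert a.variants != b.variants

    def test_sample_layout_and_pairing(self):
        cohort = generate_cohort(tiny_config())
        duos = validate_duo_pairing(cohort.samples)
        assert len(duos) == 3
        assert sum(s.role is Role.CONTROL for s in cohort.samples) == 2

    def test_transmitted_variants_verbatim_in_mother(self):
        cohort = generate_cohort(tiny_config())
        for duo_id in ("ALL01", "ALL02", "AML01"):
            mother_keys = {v.key for v in cohort.variants[f"{duo_id}-M"]}
            for v in cohort.variants[f"{duo_id}-I"]:
                origin = cohort.truth.origin[(f"{duo_id}-I", v.key)]
                assert (v.key in mother_keys) == (origin == "maternal")

    def test_full_transmission_degenerate(self):
        """transmission_prob=1 leaves no non-maternal variant, so no calls."""
        cohort = generate_cohort(
            tiny_config(transmission_prob=1.0, planted_compound_het_genes=())
        )
        profiles = filtered_profiles(cohort)
        for smp in cohort.samples:
            if smp.role is not Role.INFANT:
                continue
            avs = attribute_origin(
                profiles[smp.sample_id], profiles[smp.sample_id.replace("-I", "-M")]
            )
            assert all(a.origin.value == "maternal" for a in avs)
            assert detect_compound_het(avs, smp.duo_id) == []

    def test_null_multiplier_equalizes_per_kb_rates(self):
        """With multipliers at 1 candidate and background per-kb rates agree."""
        config = SimulationConfig(
            seed=11, n_duos_all=6, n_duos_aml=6, n_controls=0, n_genes=800,
            baseline_rate=0.5,
            enrichment_multiplier_infant=1.0, enrichment_multiplier_mother=1.0,
            planted_compound_het_genes=(),
        )
        cohort = generate_cohort(config)
        lengths = {m.gene: m.coding_length for m in cohort.gene_models}
        cand = cohort.truth.candidate_genes
        kb_c = sum(lengths[g] for g in cand) / 1000
        kb_n = sum(l for g, l in lengths.items() if g not in cand) / 1000
        n_c = n_n = 0
        for smp in cohort.samples:
            if smp.role is not Role.INFANT:
                continue
            for v in cohort.variants[smp.sample_id]:
                if v.gene in cand:
                    n_c += 1
                else:
                    n_n += 1
        rate_c, rate_n = n_c / kb_c, n_n / kb_n
        se = rate_n * ((1 / max(n_c, 1)) + (1 / max(n_n, 1))) ** 0.5
        assert abs(rate_c - rate_n) < 4 * se

    def test_enrichment_multiplier_shows_up_in_rates(self):
        config = SimulationConfig(
            seed=13, n_duos_all=6, n_duos_aml=0, n_controls=0, n_genes=600,
            baseline_rate=0.5,
            enrichment_multiplier_infant=3.0, enrichment_multiplier_mother=1.0,
            planted_compound_het_genes=(),
        )
        cohort = generate_cohort(config)
        lengths = {m.gene: m.coding_length for m in cohort.gene_models}
        cand = cohort.truth.candidate_genes
        kb_c = sum(lengths[g] for g in cand) / 1000
        kb_n = sum(l for g, l in lengths.items() if g not in cand) / 1000
        n_c = n_n = 0
        for smp in cohort.samples:
            if smp.role is Role.INFANT:
                for v in cohort.variants[smp.sample_id]:
                    if v.gene in cand:
                        n_c += 1
                    else:
                        n_n += 1
        ratio = (n_c / kb_c) / (n_n / kb_n)
        assert ratio == pytest.approx(3.0, rel=0.25)

    def test_planted_gene_recovered_in_designated_infants(self):
        config = tiny_config(
            n_duos_all=4, n_duos_aml=4, planted_compound_het_genes=(("G0002", 1.0),)
        )
        cohort = generate_cohort(config)
        assert len(cohort.truth.planted_compound_het["G0002"]) == 8
        profiles = filtered_profiles(cohort)
        for infant_id in cohort.truth.planted_compound_het["G0002"]:
            avs = attribute_origin(
                profiles[infant_id], profiles[infant_id.replace("-I", "-M")]
            )
            called = {c.gene for c in detect_compound_het(avs, infant_id)}
            assert "G0002" in called

    def test_unknown_planted_gene_rejected(self):
        with pytest.raises(ValueError, match="not among generated genes"):
            generate_cohort(tiny_config(planted_compound_het_genes=(("NOPE", 1.0),)))

    def test_quality_decoys_fail_each_stage(self, small_cohort):
        """Every filter stage removes something on a default-noise cohort."""
        profiles = filtered_profiles(small_cohort)
        drops = {stage: 0 for stage in
                 ("allele_depth", "position_depth", "genotype_quality",
                  "mapping_quality", "consequence", "rarity")}
        for p in profiles.values():
            keys = ["input"] + list(drops)
            for prev, cur in zip(keys, keys[1:]):
                drops[cur] += p.counts[prev] - p.counts[cur]
        assert all(n > 0 for n in drops.values()), drops

    def test_truth_qualifying_matches_filter_cascade(self, small_cohort):
        """The generator's intent agrees with the default filter outcome."""
        for sid, variants in small_cohort.variants.items():
            retained = {v.key for v in filter_variants(variants).variants}
            for v in variants:
                assert small_cohort.truth.qualifying[(sid, v.key)] == (v.key in retained)


class TestFixtureBundle:
    def test_round_trip_through_vcf(self, tmp_path):
        cohort = generate_cohort(tiny_config(n_duos_all=1, n_duos_aml=0, n_controls=1))
        paths = write_fixture_bundle(cohort, tmp_path)
        for sid in ("ALL01-I", "ALL01-M", "CTRL01"):
            back = read_vcf(paths[f"vcf_{sid}"], sid, paths["annotation"])
            assert sorted(back, key=lambda v: v.key) == sorted(
                cohort.variants[sid], key=lambda v: v.key
            )

    def test_gene_set_round_trip(self, tmp_path):
        cohort = generate_cohort(tiny_config())
        paths = write_fixture_bundle(cohort, tmp_path)
        gs = read_gene_set(paths["gene_set_candidates"], "candidates")
        assert gs.genes == cohort.gene_sets["candidates"].genes

    def test_same_seed_identical_bytes(self, tmp_path):
        c1 = generate_cohort(tiny_config())
        c2 = generate_cohort(tiny_config())
        p1 = write_fixture_bundle(c1, tmp_path / "a")
        p2 = write_fixture_bundle(c2, tmp_path / "b")
        assert p1["annotation"].read_bytes() == p2["annotation"].read_bytes()
        assert p1["truth"].read_bytes() == p2["truth"].read_bytes()

    def test_regenerated_counts_identical(self, tmp_path):
        """generate -> write -> read -> counts match the in-memory cohort."""
        from duoburden.ranking import build_matrix

        cohort = generate_cohort(tiny_config(n_duos_all=1, n_duos_aml=0, n_controls=0))
        paths = write_fixture_bundle(cohort, tmp_path)
        gene_set = cohort.gene_sets["candidates"]
        sids = ["ALL01-I", "ALL01-M"]
        mem = build_matrix(
            [filter_variants(cohort.variants[s]) for s in sids], gene_set, cohort.samples
        )
        disk = build_matrix(
            [filter_variants(read_vcf(paths[f"vcf_{s}"], s, paths["annotation"]))
             for s in sids],
            gene_set,
            cohort.samples,
        )
        assert np.array_equal(mem.counts, disk.counts)


class TestConfigValidation:
    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError, match="enrichment_multiplier_infant"):
            SimulationConfig(enrichment_multiplier_infant=0.5)

    def test_duplicate_planted_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SimulationConfig(
                planted_compound_het_genes=(("G0001", 1.0), ("G0001", 0.5))
            )

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="candidate_fraction"):
            SimulationConfig(candidate_fraction=1.5)
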