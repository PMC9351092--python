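"""Synthetic spike-in generator: placement, source mix, library simulation."""

import numpy as np
import pytest

from gdnacontam import (
    SimulationConfig,
    expected_mapping_ratio,
    expected_source_mix,
    generate_annotation,
    simulate_experiment,
    simulate_library,
)
from gdnacontam.pipeline import regression_points
from gdnacontam.synthetic_data import SizingError, library_rng
import gdnacontam.contamination_model as cm


def small_config(**kw):
    base = dict(
        seed=5,
        genome_length=1_000_000,
        n_chromosomes=2,
        n_coding=40,
        n_noncoding=10,
        gene_length_range=(10_000, 10_000),
        target_p_ir=0.5,
        fragments_per_library=100_000,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateAnnotation:
    def test_no_genes_means_all_intergenic(self):
        ann = generate_annotation(small_config(n_coding=0, n_noncoding=0))
        assert ann.genes == [] and ann.realized_p_ir == 1.0

    def test_fixed_lengths_hit_target_exactly(self):
        """1 Mb genome, 50 x 10 kb genes, target p_IR 0.5 -> realized 0.5,
        verified against a per-base mask over the emitted intervals."""
        ann = generate_annotation(small_config())
        assert ann.realized_p_ir == pytest.approx(0.5, abs=1e-9)
        masks = {c: np.zeros(s, dtype=bool) for c, s in ann.chrom_sizes.items()}
        for g in ann.genes:
            assert not masks[g.chrom][g.start : g.end].any(), "genes overlap"
            masks[g.chrom][g.start : g.end] = True
        covered = sum(int(m.sum()) for m in masks.values())
        assert 1.0 - covered / sum(ann.chrom_sizes.values()) == pytest.approx(
            ann.realized_p_ir, abs=1e-12
        )

    def test_realized_fraction_near_target_for_random_lengths(self):
        ann = generate_annotation(small_config(gene_length_range=(5000, 15000)))
        assert abs(ann.realized_p_ir - 0.5) < 0.05

    def test_seed_changes_coordinates_not_counts(self):
        a1 = generate_annotation(small_config(seed=1))
        a2 = generate_annotation(small_config(seed=2))
        assert len(a1.genes) == len(a2.genes) == 50
        assert [g.biotype for g in a1.genes].count("coding") == 40
        assert [(g.chrom, g.start) for g in a1.genes] != [
            (g.chrom, g.start) for g in a2.genes
        ]

    def test_genome_too_small_raises(self):
        with pytest.raises(SizingError):
            generate_annotation(
                small_config(genome_length=100_000, target_p_ir=0.9999)
            )


class TestSourceMix:
    def test_fractions_sum_to_one(self):
        cfg = small_config()
        for method in ("PA", "RZ"):
            for dna_a in cfg.spike_fractions:
                mix = expected_source_mix(cfg, method, dna_a)
                assert sum(mix.values()) == pytest.approx(1.0, abs=1e-12)
                assert all(v >= 0 for v in mix.values())

    def test_no_contamination_sources(self):
        cfg = small_config(dna_r_true=0.0, cdna_ir_pa_true=0.0)
        mix = expected_source_mix(cfg, "RZ", 0.0)
        assert mix["gdna"] == 0.0 and mix["cdna_intergenic"] == 0.0

    def test_rz_background_doubles_at_unit_gene_ratio(self):
        cfg = small_config(n_coding=25, n_noncoding=25, cdna_ir_pa_true=0.01)
        mix = expected_source_mix(cfg, "RZ", 0.0)
        assert mix["cdna_intergenic"] == pytest.approx(0.02, abs=1e-15)

    def test_rz_scaling_without_coding_genes_raises(self):
        cfg = small_config(n_coding=0, n_noncoding=10)
        with pytest.raises(ZeroDivisionError):
            expected_source_mix(cfg, "RZ", 0.0)

    def test_expected_ratio_strictly_increasing_in_dna_a(self):
        cfg = small_config()
        ratios = [
            expected_mapping_ratio(cfg, "RZ", a, 0.5)
            for a in (0.0, 1e-4, 1e-3, 0.01, 0.1)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


class TestSimulateLibrary:
    def test_counts_sum_to_n_exactly(self):
        cfg = small_config()
        ann = generate_annotation(cfg)
        rng = np.random.default_rng(0)
        profile, gene_counts, _ = simulate_library(ann, "RZ", 0.01, cfg, rng=rng)
        assert gene_counts.sum() + profile.intergenic_mapped == profile.total_mapped
        assert float(gene_counts.sum() % 1) == 0.0  # multinomial counts integral

    def test_noisefree_ratio_matches_model_closed_form(self):
        cfg = small_config(noise="none")
        ann = generate_annotation(cfg)
        for dna_a in (0.0, 0.01, 0.1):
            profile, gene_counts, _ = simulate_library(ann, "RZ", dna_a, cfg)
            expect = expected_mapping_ratio(cfg, "RZ", dna_a, ann.realized_p_ir)
            assert profile.mapping_ratio_ir == pytest.approx(expect, abs=1e-9)
            assert gene_counts.sum() + profile.intergenic_mapped == profile.total_mapped

    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        ann = generate_annotation(cfg)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            _, counts, _ = simulate_library(ann, "PA", 0.1, cfg, rng=rng)
            runs.append(counts)
        assert np.array_equal(*runs)

    def test_no_intergenic_sources_yields_zero_intergenic(self):
        cfg = small_config(dna_r_true=0.0, cdna_ir_pa_true=0.0, noise="none")
        ann = generate_annotation(cfg)
        profile, _, _ = simulate_library(ann, "RZ", 0.0, cfg)
        assert profile.intergenic_mapped == 0.0

    def test_invalid_fragment_count_raises(self):
        cfg = small_config()
        ann = generate_annotation(cfg)
        with pytest.raises(ValueError):
            simulate_library(ann, "RZ", 0.0, small_config(fragments_per_library=-5))

    def test_fragment_placement_respects_sources(self):
        cfg = small_config(fragments_per_library=5000)
        ann = generate_annotation(cfg)
        rng = np.random.default_rng(3)
        profile, gene_counts, frags = simulate_library(
            ann, "RZ", 0.1, cfg, rng=rng, with_fragments=True
        )
        assert len(frags) == int(gene_counts.sum() + profile.intergenic_mapped)
        for chrom, start, end in frags[:100]:
            assert 0 <= start < end <= ann.chrom_sizes[chrom]


class TestSimulateExperiment:
    def test_default_design_has_thirty_libraries(self, default_experiment):
        assert len(default_experiment.library_ids) == 30
        assert set(default_experiment.design["method"]) == {"PA", "RZ"}
        assert default_experiment.counts.shape == (300, 30)

    def test_truth_echoes_config(self, default_experiment):
        truth = default_experiment.truth
        cfg = default_experiment.config
        assert truth.dna_r_true == cfg.dna_r_true
        assert truth.cdna_term_rz == pytest.approx(
            (1 + cfg.n_noncoding / cfg.n_coding) * cfg.cdna_ir_pa_true
        )

    def test_noisefree_regression_recovers_residual_dna(self, noisefree_experiment):
        exp = noisefree_experiment
        est = cm.estimate_contamination(
            regression_points(exp.profiles, "PA"),
            regression_points(exp.profiles, "RZ"),
            exp.config.n_coding,
            exp.config.n_noncoding,
        )
        assert est.dna_r_hat == pytest.approx(exp.config.dna_r_true, abs=1e-6)

    def test_byte_identical_outputs_under_same_seed(self, tmp_path):
        cfg = small_config()
        for d in ("a", "b"):
            simulate_experiment(cfg, out_dir=tmp_path / d)
        for name in (
            "annotation.gtf",
            "chrom.sizes",
            "design.tsv",
            "counts.tsv",
            "fpkm.tsv",
            "profiles.tsv",
            "truth.json",
            "truth_rna_fpkm.tsv",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_library_substreams_independent_of_design_growth(self):
        """Adding spike levels must not perturb earlier libraries' draws."""
        cfg = small_config()
        r1 = library_rng(cfg, 1, 0, 0).integers(0, 1 << 30, 4)
        cfg2 = small_config(spike_fractions=(0.0, 1e-4, 1e-3, 0.01, 0.1, 0.5))
        r2 = library_rng(cfg2, 1, 0, 0).integers(0, 1 << 30, 4)
        assert np.array_equal(r1, r2)
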