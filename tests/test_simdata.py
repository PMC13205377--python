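"""Synthetic-cohort generator: genotypes, traits, clearance, geometry, rendering."""

import numpy as np
import pytest

from pigtme import quantgen, simdata


class TestGenotypes:
    def test_forced_frequency_and_support(self):
        cfg = simdata.SimConfig(
            seed=1, n_individuals=10_000, n_markers=1, maf_low=0.5, maf_high=0.5,
            n_qtl=1, n_sires=None,
        )
        geno = simdata.simulate_genotypes(cfg)
        assert np.isin(geno.codes, (0, 1, 2)).all()
        assert 0.48 <= geno.allele_freq[0] <= 0.52

    def test_family_structure_support(self):
        geno = simdata.simulate_genotypes(simdata.SimConfig(seed=3, n_individuals=200,
                                                            n_markers=300))
        assert np.isin(geno.codes, (0, 1, 2)).all()

    def test_empirical_frequencies_match_drawn(self):
        """Unrelated sampling: observed p within 3 binomial SDs of drawn p for >=95%."""
        cfg = simdata.SimConfig(seed=11, n_individuals=2000, n_markers=200, n_sires=None)
        geno = simdata.simulate_genotypes(cfg)
        # the drawn frequencies are the first draws from the generator stream
        p = np.random.default_rng(cfg.seed).uniform(cfg.maf_low, cfg.maf_high, cfg.n_markers)
        sd = np.sqrt(p * (1 - p) / (2 * cfg.n_individuals))
        within = np.abs(geno.allele_freq - p) <= 3 * sd
        assert within.mean() >= 0.95

    def test_half_sib_relatedness(self):
        """Within-family genomic relatedness is near 0.25, across-family near 0."""
        cfg = simdata.SimConfig(seed=5, n_individuals=400, n_markers=4000, n_sires=10)
        geno = simdata.simulate_genotypes(cfg)
        _, grm = quantgen.build_grm(quantgen.maf_filter(geno))
        G = grm.values
        fam = np.arange(cfg.n_individuals) % 10
        same = fam[:, None] == fam[None, :]
        off = ~np.eye(len(G), dtype=bool)
        # observed-frequency centering makes off-family entries slightly
        # negative, so test the within-vs-between contrast
        assert G[same & off].mean() - G[~same].mean() == pytest.approx(0.25, abs=0.05)

    def test_invalid_maf_rejected(self):
        with pytest.raises(simdata.ConfigError):
            simdata.SimConfig(seed=1, maf_low=0.0)
        with pytest.raises(simdata.ConfigError):
            simdata.SimConfig(seed=1, maf_low=0.3, maf_high=0.2)


class TestTrait:
    def test_zero_heritability_gives_zero_breeding_values(self, small_geno, small_cfg):
        from dataclasses import replace

        cfg = replace(small_cfg, h2_bw=0.0)
        arch, pheno = simdata.simulate_trait(small_geno, cfg, np.random.default_rng(0))
        assert np.all(arch.breeding_values == 0.0)

    def test_phenotype_regression_on_breeding_values(self):
        """After removing fixed effects, slope of y on true BV is ~1."""
        cfg = simdata.SimConfig(seed=21, n_individuals=2000, n_markers=2000, h2_bw=0.5)
        geno = simdata.simulate_genotypes(cfg, np.random.default_rng(21))
        arch, pheno = simdata.simulate_trait(geno, cfg, np.random.default_rng(22))
        y = pheno["scale_bw"].to_numpy()
        X = simdata.design_matrix(pheno)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        bv = arch.breeding_values
        slope = (bv @ resid) / (bv @ bv)
        assert 0.8 <= slope <= 1.2
        # realized genetic variance is scaled exactly to h2 * sd^2
        assert bv.var() == pytest.approx(cfg.h2_bw * cfg.sd_bw**2, rel=1e-9)

    def test_t1_cohort_mean(self):
        """Mean scale BW at the first visit is 65 kg within 3 standard errors."""
        cfg = simdata.SimConfig(seed=31, n_individuals=800, n_markers=1000)
        geno = simdata.simulate_genotypes(cfg, np.random.default_rng(31))
        _, pheno = simdata.simulate_trait(
            geno, cfg, np.random.default_rng(32), time_point="T1",
            mean_bw=simdata.TIME_POINT_MEAN_BW["T1"],
        )
        y = pheno["scale_bw"]
        assert abs(y.mean() - 65.0) <= 3 * y.std() / np.sqrt(len(y))

    def test_degenerate_config_rejected(self):
        with pytest.raises(simdata.ConfigError):
            simdata.SimConfig(seed=1, h2_bw=1.0, sd_bw=0.0)


class TestClearance:
    def test_constant_without_variance(self, small_geno, small_cfg):
        from dataclasses import replace

        cfg = replace(small_cfg, sd_clearance=0.0, h2_clearance=0.0)
        _, cl = simdata.simulate_clearance(small_geno, cfg, np.random.default_rng(0))
        assert np.allclose(cl, cfg.clearance_baseline)

    def test_nonnegative_and_carrier_skew(self, small_geno, small_cfg):
        from dataclasses import replace

        cfg = replace(small_cfg, h2_clearance=0.5)
        arch, cl = simdata.simulate_clearance(small_geno, cfg, np.random.default_rng(1))
        assert (cl >= 0).all()
        # the single clearance QTL is rare and clearance-raising
        p = small_geno.allele_freq[arch.qtl_indices]
        assert (p <= cfg.clearance_qtl_maf_max + 1e-9).all()
        assert (arch.qtl_effects > 0).all()

    def test_heritability_recovery(self, cohort800):
        """REML on clearance itself recovers h2=0.5 and rejects h2=0."""
        from dataclasses import replace

        cfg, geno, fgeno, grm = cohort800
        X = np.ones((geno.n, 1))
        _, cl_null = simdata.simulate_clearance(
            geno, replace(cfg, h2_clearance=0.0), np.random.default_rng(5)
        )
        assert quantgen.reml_fit(cl_null, X, grm).h2 < 0.1
        _, cl_her = simdata.simulate_clearance(
            geno, replace(cfg, h2_clearance=0.5), np.random.default_rng(6)
        )
        assert 0.3 <= quantgen.reml_fit(cl_her, X, grm).h2 <= 0.7


class TestShape:
    def test_allometric_scaling(self):
        cfg = simdata.SimConfig(seed=0)
        s1 = simdata.shape_from_weight(50.0, cfg, clearance=0.1)
        s2 = simdata.shape_from_weight(100.0, cfg, clearance=0.1)
        k = 2.0 ** (1.0 / 3.0)
        assert s2.body_length == pytest.approx(s1.body_length * k, abs=1e-9)
        assert s2.body_width == pytest.approx(s1.body_width * k, abs=1e-9)
        assert s2.body_height == pytest.approx(s1.body_height * k, abs=1e-9)
        assert s1.clearance == 0.1

    def test_bw_range_fits_field_of_view(self):
        cfg = simdata.SimConfig(seed=0)
        for bw in (25.0, 154.0):
            shape = simdata.shape_from_weight(bw, cfg, clearance=0.17)
            video = simdata.render_depth_video(shape, cfg, 1)  # must not raise
            assert len(video) == cfg.n_frames

    def test_conformation_preserves_volume(self):
        cfg = simdata.SimConfig(seed=0)
        s0 = simdata.shape_from_weight(80.0, cfg)
        s1 = simdata.shape_from_weight(80.0, cfg, shape_dev=(0.05, -0.03))
        v0 = s0.body_length * s0.body_width * s0.body_height
        v1 = s1.body_length * s1.body_width * s1.body_height
        assert v1 == pytest.approx(v0, rel=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(simdata.ConfigError):
            simdata.shape_from_weight(0.0)


class TestRendering:
    def test_empty_scene_is_floor_plane(self):
        cfg = simdata.SimConfig(seed=0)
        frame = simdata.render_depth_frame(None, cfg, np.random.default_rng(0))
        assert np.all(frame.distance_map == cfg.camera_height)

    def test_minimum_distance_equals_camera_minus_height(self):
        """A 0.40 m body at zero clearance puts the apex at 1.00 m distance."""
        cfg = simdata.SimConfig(seed=0, jitter_px=0.0, jitter_deg=0.0,
                                head_tail=False, dropout_rate=0.0)
        shape = simdata.PigShape(body_length=1.0, body_width=0.3,
                                 body_height=0.4, clearance=0.0)
        frame = simdata.render_depth_frame(shape, cfg, np.random.default_rng(0))
        assert frame.distance_map.min() == pytest.approx(1.0, abs=1e-3)

    def test_clearance_shifts_distances_exactly(self):
        cfg = simdata.SimConfig(seed=0, jitter_px=0.0, jitter_deg=0.0,
                                head_tail=False, dropout_rate=0.0)
        s0 = simdata.shape_from_weight(80.0, cfg, clearance=0.0)
        s1 = simdata.shape_from_weight(80.0, cfg, clearance=0.1)
        f0 = simdata.render_depth_frame(s0, cfg, np.random.default_rng(1))
        f1 = simdata.render_depth_frame(s1, cfg, np.random.default_rng(1))
        on = f0.distance_map < cfg.camera_height
        assert np.allclose(f0.distance_map[on] - f1.distance_map[on], 0.1)

    def test_determinism_under_fixed_seed(self):
        cfg = simdata.SimConfig(seed=0, n_frames=2)
        shape = simdata.shape_from_weight(80.0, cfg, clearance=0.17)
        v1 = simdata.render_depth_video(shape, cfg, 9)
        v2 = simdata.render_depth_video(shape, cfg, 9)
        for a, b in zip(v1.frames, v2.frames):
            assert np.array_equal(a.distance_map, b.distance_map)
            assert np.array_equal(a.color_image, b.color_image)

    def test_oversized_shape_rejected(self):
        cfg = simdata.SimConfig(seed=0, image_shape=(30, 40))
        shape = simdata.shape_from_weight(154.0, cfg)
        with pytest.raises(simdata.RenderError):
            simdata.render_depth_frame(shape, cfg, np.random.default_rng(0))


class TestHueCodec:
    def test_roundtrip_within_quantization(self):
        """decode(encode(d)) = d within one uint8 hue quantization step."""
        cam = 1.40
        d = np.linspace(0.01, cam, 400).reshape(20, 20)
        rec = simdata.decode_distance(simdata.encode_color(d, cam), cam)
        # uint8 RGB resolves hue to ~0.24 deg -> ~1.4 mm at 240 deg over 1.4 m
        assert np.max(np.abs(rec - d)) < 0.003

    def test_hue_linear_in_distance(self):
        h = simdata.distance_to_hue(np.array([0.0, 0.7, 1.4]), 1.4)
        assert np.allclose(h, [0.0, 120.0, 240.0])
        assert np.allclose(simdata.hue_to_distance(h, 1.4), [0.0, 0.7, 1.4])


class TestFeatureSpaceMode:
    def test_analytic_matches_rendered_pipeline(self):
        """Feature-space mode agrees with render+segment within a few percent."""
        from pigtme import segment

        cfg = simdata.SimConfig(seed=0, n_frames=5)
        for bw, cl in [(45.0, 0.14), (80.0, 0.17), (130.0, 0.20)]:
            shape = simdata.shape_from_weight(bw, cfg, clearance=cl)
            video = simdata.render_depth_video(shape, cfg, 3)
            agg, _ = segment.process_video(video, camera_height=cfg.camera_height,
                                           trim_ratio=cfg.trim_ratio)
            ana = simdata.analytic_features(shape, cfg)
            assert agg.height == pytest.approx(ana["height"], rel=0.05)
            assert agg.volume == pytest.approx(ana["volume"], rel=0.08)
            assert agg.dorsal_length == pytest.approx(ana["dorsal_length"], rel=0.08)
            assert agg.abdominal_width == pytest.approx(ana["abdominal_width"], rel=0.08)

    def test_volumetric_calibration_monotone(self):
        cfg = simdata.SimConfig(seed=0)
        grid_bw, grid_vol = simdata.volumetric_calibration(cfg)
        assert np.all(np.diff(grid_vol) > 0)

    def test_feature_noise_scale(self):
        cfg = simdata.SimConfig(seed=0)
        rng = np.random.default_rng(3)
        bw = np.full(4000, 80.0)
        cl = np.full(4000, cfg.clearance_baseline)
        feats = simdata.simulate_features(bw, cl, cfg, rng)
        rel_sd = feats["volume"].std() / feats["volume"].mean()
        assert rel_sd == pytest.approx(cfg.feature_noise, rel=0.15)
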