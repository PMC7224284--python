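"""Synthetic cohort generator: structure, determinism, effects, null model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from dermaflim import synthetic as syn
from dermaflim.synthetic import (
    CohortConfig,
    ConfigError,
    EffectSizes,
    generate_cohort,
    ground_truth,
    render_decay_cube,
    render_frame,
)


def granulosum_tau_means(cohort):
    """One granulosum tau_m mean per subject (the exchangeable unit; stacks
    of one subject share its random effect and are not independent)."""
    out = {"AD": [], "healthy": []}
    for s in cohort:
        taus = [
            f.tau_m_mean
            for st in s.stacks
            for f in st.frames
            if f.layer == "granulosum"
        ]
        if taus:
            out[s.diagnosis].append(float(np.mean(taus)))
    return out


class TestCohortStructure:
    def test_study_scale_patch_count(self):
        """6 AD + 4 healthy subjects, 21 stacks of 21 frames, 3x3 patching
        -> 3,969 patches, the order of magnitude of the emulated study."""
        cfg = CohortConfig(seed=3)
        cohort = generate_cohort(cfg)
        assert sum(len(s.stacks) for s in cohort) == 21
        gt = ground_truth(cohort, cfg)
        assert len(gt) == 21 * 21 * 9 == 3969

    def test_determinism(self, tiny_cohort_config):
        a = generate_cohort(tiny_cohort_config)
        b = generate_cohort(tiny_cohort_config)
        ga = ground_truth(a, tiny_cohort_config)
        gb = ground_truth(b, tiny_cohort_config)
        pd.testing.assert_frame_equal(ga, gb)

    def test_depths_increase_and_granulosum_in_range(self, tiny_cohort):
        for s in tiny_cohort:
            for st in s.stacks:
                depths = [f.depth_um for f in st.frames]
                assert np.all(np.diff(depths) == 5.0)
                assert 0 <= st.granulosum_index < len(st.frames)
                assert st.frames[st.granulosum_index].layer == "granulosum"

    def test_diagnosis_constant_within_subject(self, tiny_cohort):
        for s in tiny_cohort:
            for st in s.stacks:
                assert all(f.diagnosis == s.diagnosis for f in st.frames)

    def test_layer_order_follows_depth(self, tiny_cohort):
        order = ["corneum", "granulosum", "spinosum", "basale", "dermis"]
        for s in tiny_cohort:
            for st in s.stacks:
                seen = [f.layer for f in st.frames]
                idx = [order.index(l) for l in seen]
                assert idx == sorted(idx)
                assert all(
                    f.has_cells == (f.layer in ("granulosum", "spinosum", "basale"))
                    for f in st.frames
                )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigError):
            generate_cohort(CohortConfig(seed=1, n_ad_subjects=0))
        with pytest.raises(ConfigError):
            generate_cohort(CohortConfig(seed=1, photon_budget=-5.0))


class TestDiseaseEffects:
    def test_ad_granulosum_tau_below_healthy(self):
        """Positive granulosum shift: AD cohort-mean granulosum tau_m is
        lower than healthy (asserted on ground truth, not fits)."""
        cfg = CohortConfig(seed=11, field_px=64, field_um=20.0)
        taus = granulosum_tau_means(generate_cohort(cfg))
        assert np.mean(taus["AD"]) < np.mean(taus["healthy"])

    def test_healthy_basale_shallower_than_ad(self):
        cfg = CohortConfig(seed=13, field_px=64, field_um=20.0)
        depths = {"AD": [], "healthy": []}
        for s in generate_cohort(cfg):
            for st in s.stacks:
                b = [f.depth_um for f in st.frames if f.layer == "basale"]
                if b:
                    depths[s.diagnosis].append(min(b))
        assert np.mean(depths["healthy"]) < np.mean(depths["AD"])
        # healthy melanin signature appears near the configured 35 um
        assert abs(np.mean(depths["healthy"]) - 35.0) <= 10.0

    def test_null_cohort_has_no_group_difference(self):
        """With all effect sizes zero, granulosum tau_m is exchangeable
        between diagnoses: pooled over replicate cohorts, a rank test does
        not reject at alpha = 0.05."""
        ps = []
        for seed in range(20):
            cfg = CohortConfig(
                seed=1000 + seed, field_px=64, field_um=20.0,
                effect_sizes=EffectSizes.null(),
            )
            taus = granulosum_tau_means(generate_cohort(cfg))
            ps.append(mannwhitneyu(taus["AD"], taus["healthy"]).pvalue)
        # under the null, p-values are ~uniform: their mean is far from 0
        assert np.mean(ps) > 0.2
        assert np.mean(np.array(ps) < 0.05) <= 0.15


class TestRendering:
    def test_render_deterministic(self, tiny_cohort, tiny_cohort_config):
        fr = tiny_cohort[0].stacks[0].frames[3]
        a = render_frame(fr, tiny_cohort_config)
        b = render_frame(fr, tiny_cohort_config)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        np.testing.assert_array_equal(a.tau_m, b.tau_m)

    def test_channels_consistent(self, tiny_cohort, tiny_cohort_config):
        cfg = tiny_cohort_config
        fr = tiny_cohort[0].stacks[0].frames[4]
        img = render_frame(fr, cfg)
        assert img.intensity.min() >= 0 and img.intensity.max() <= 1
        # a1 and tau_m describe the same decay: tau_m = a1*tau1 + (1-a1)*tau2
        np.testing.assert_allclose(
            img.a1 * cfg.tau1_ns + (1 - img.a1) * cfg.tau2_ns, img.tau_m, atol=0.05
        )
        np.testing.assert_allclose(img.ratio, img.a1 / (1 - img.a1), rtol=1e-5)

    def test_cell_mask_only_in_living_layers(self, tiny_cohort, tiny_cohort_config):
        for fr in tiny_cohort[0].stacks[0].frames:
            img = render_frame(fr, tiny_cohort_config)
            if not fr.has_cells:
                assert not img.cell_mask.any()


class TestDecayCube:
    def test_poisson_totals_match_expected_intensity(self, tiny_cohort, tiny_cohort_config):
        """Summed histogram counts agree with photon_budget * intensity
        within 3 standard errors over >= 1000 pixels."""
        cfg = tiny_cohort_config
        fr = tiny_cohort[0].stacks[0].frames[4]
        img = render_frame(fr, cfg)
        cube = render_decay_cube(fr, cfg, img)
        expected = cfg.photon_budget * img.intensity
        totals = cube.counts.sum(axis=-1)
        assert totals.size >= 1000
        diff = totals.sum() - expected.sum()
        se = np.sqrt(expected.sum())  # Poisson variance of the grand total
        assert abs(diff) <= 3 * se

    def test_zero_intensity_gives_empty_histograms(self, tiny_cohort, tiny_cohort_config):
        cfg = tiny_cohort_config
        fr = tiny_cohort[0].stacks[0].frames[0]
        img = render_frame(fr, cfg)
        img.intensity = np.zeros_like(img.intensity)
        cube = render_decay_cube(fr, cfg, img)
        assert cube.counts.sum() == 0

    def test_cube_deterministic(self, tiny_cohort, tiny_cohort_config):
        fr = tiny_cohort[0].stacks[0].frames[2]
        a = render_decay_cube(fr, tiny_cohort_config)
        b = render_decay_cube(fr, tiny_cohort_config)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_empirical_mean_arrival_time_matches_mixture(self, t_axis, rng):
        """A sampled decay's mean arrival time matches the analytic mean of
        the truncated two-exponential mixture within 2%."""
        a1, t1, t2 = 0.7, 0.4, 2.5
        shape = a1 * np.exp(-t_axis / t1) + (1 - a1) * np.exp(-t_axis / t2)
        p = shape / shape.sum()
        hist = rng.poisson(1e5 * p)
        analytic = float((p * t_axis).sum())
        empirical = float((hist * t_axis).sum() / hist.sum())
        assert empirical == pytest.approx(analytic, rel=0.02)

    def test_negative_lifetime_rejected(self, tiny_cohort, tiny_cohort_config):
        from dataclasses import replace

        cfg = replace(tiny_cohort_config, tau1_ns=-0.4)
        fr = tiny_cohort[0].stacks[0].frames[2]
        with pytest.raises(ValueError):
            render_decay_cube(fr, cfg)


class TestGroundTruth:
    def test_single_stack_count(self):
        cfg = CohortConfig(seed=2, n_ad_subjects=1, n_healthy_subjects=1,
                           stacks_per_subject=(1, 1), total_stacks=2,
                           frames_per_stack=21, field_px=512)
        cohort = generate_cohort(cfg)
        gt = ground_truth(cohort[:1], cfg)
        assert len(gt) == 21 * 9 == 189

    def test_empty_cohort_gives_header_only(self, tiny_cohort_config):
        gt = ground_truth([], tiny_cohort_config)
        assert len(gt) == 0
        assert "subject_id" in gt.columns and "tau_m_true" in gt.columns

    def test_csv_round_trip(self, tmp_path, tiny_cohort, tiny_cohort_config):
        gt = ground_truth(tiny_cohort, tiny_cohort_config)
        path = tmp_path / "gt.csv"
        gt.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(gt, back)


def test_write_cohort_round_trip(tmp_path, tiny_cohort, tiny_cohort_config):
    import tifffile

    df = syn.write_cohort(tiny_cohort, tiny_cohort_config, tmp_path)
    assert (tmp_path / "manifest.csv").exists()
    stack = tiny_cohort[0].stacks[0]
    pages = tifffile.imread(tmp_path / f"{stack.stack_id}.tif")
    assert pages.shape[0] == len(stack.frames)
    img = syn.render_frame(stack.frames[0], tiny_cohort_config)
    np.testing.assert_allclose(pages[0][..., 0], img.intensity, rtol=1e-6)


def test_config_yaml_round_trip(tmp_path, tiny_cohort_config):
    path = tmp_path / "cohort.yml"
    tiny_cohort_config.to_yaml(path)
    back = syn.CohortConfig.from_yaml(path)
    assert back == tiny_cohort_config
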