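"""Synthetic population, outline and image generation."""

import numpy as np
import pandas as pd
import pytest

from otoshape.growth import fit_vbgf, vbgf_predict
from otoshape.outline import binarize, feret_diameter, trace_outline
from otoshape.synthetic import (ConfigurationError, GrowthEffects,
                                OutlineGenerationError, ShapeEffectModel,
                                SimConfig, SizingError,
                                default_genotype_proportions,
                                generate_otolith_outline, generate_population,
                                generate_study, render_outline_to_image,
                                write_study)


def quiet_effects(**kw):
    base = dict(location={"BRE": 0.0, "FAX": 0.0, "SW": 0.0},
                cohort={}, cohort_sd=0.0,
                genotype={"AA": 0.0, "AB": 0.0, "BB": 0.0},
                individual_sd=0.0)
    base.update(kw)
    return GrowthEffects(**base)


class TestConfig:
    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(genotype_proportions={1980: (0.5, 0.4, 0.4)})

    def test_empty_locations_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(locations={})

    def test_empty_years_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(sampling_years=())

    def test_age_range_bounds(self):
        with pytest.raises(ConfigurationError):
            SimConfig(age_range=(0, 14))

    def test_default_proportions_sum_to_one_and_ab_dominant(self):
        props = default_genotype_proportions(range(1934, 1995))
        arr = np.array(list(props.values()))
        np.testing.assert_allclose(arr.sum(axis=1), 1.0)
        assert ((arr >= 0) & (arr <= 1)).all()
        assert abs(arr[:, 1].mean() - 0.60) < 0.03


class TestPopulation:
    def test_degenerate_noise_puts_lengths_on_curve(self):
        cfg = SimConfig(n_fish=200, growth_effects=quiet_effects(),
                        length_noise_sd=0.0, seed=5)
        fish = generate_population(cfg)
        pred = vbgf_predict(cfg.vbgf, fish["age"].to_numpy(float))
        np.testing.assert_allclose(fish["length"], pred, atol=1e-12)
        np.testing.assert_allclose(fish["true_G"], 0.0, atol=1e-12)

    def test_forced_ab_category(self):
        cfg = SimConfig(n_fish=150, seed=2)
        props = {int(c): (0.0, 1.0, 0.0) for c in cfg.cohorts()}
        cfg = SimConfig(n_fish=150, seed=2, genotype_proportions=props)
        fish = generate_population(cfg)
        assert (fish["genotype"] == "AB").all()

    def test_table_like_config_gives_ab_near_060(self):
        fish = generate_population(SimConfig(n_fish=826, seed=10))
        p_ab = (fish["genotype"] == "AB").mean()
        # binomial error at n = 826 around the configured mean of ~0.60
        assert abs(p_ab - 0.60) < 4 * np.sqrt(0.6 * 0.4 / 826)

    def test_cohort_identity(self):
        fish = generate_population(SimConfig(n_fish=100, seed=3))
        assert (fish["cohort"] + fish["age"] == fish["sampling_year"]).all()

    def test_genotype_draws_match_configured_proportions(self):
        cfg = SimConfig(n_fish=3000, seed=8)
        props = {int(c): (0.2, 0.5, 0.3) for c in cfg.cohorts()}
        cfg = SimConfig(n_fish=3000, seed=8, genotype_proportions=props)
        fish = generate_population(cfg)
        counts = fish["genotype"].value_counts()
        for g, p in zip(("AA", "AB", "BB"), (0.2, 0.5, 0.3)):
            se = np.sqrt(p * (1 - p) / 3000)
            assert abs(counts[g] / 3000 - p) < 4 * se, g

    def test_noise_free_lengths_invert_through_growth_fit(self):
        cfg = SimConfig(n_fish=400, growth_effects=quiet_effects(),
                        length_noise_sd=0.0, seed=4)
        fish = generate_population(cfg)
        fit = fit_vbgf(fish["age"], fish["length"])
        assert fit.params.L1 == pytest.approx(cfg.vbgf.L1, rel=1e-6)
        assert fit.params.L2 == pytest.approx(cfg.vbgf.L2, rel=1e-6)
        assert fit.params.L3 == pytest.approx(cfg.vbgf.L3, rel=1e-6)

    def test_same_seed_reproducible(self):
        f1 = generate_population(SimConfig(n_fish=120, seed=77))
        f2 = generate_population(SimConfig(n_fish=120, seed=77))
        pd.testing.assert_frame_equal(f1, f2)

    def test_seed_changes_output(self):
        f1 = generate_population(SimConfig(n_fish=120, seed=1))
        f2 = generate_population(SimConfig(n_fish=120, seed=2))
        assert not f1["length"].equals(f2["length"])


class TestOutlines:
    def test_no_effect_sources_give_identical_outlines(self):
        model = ShapeEffectModel(noise_sd=0.0)
        model.genotype_deltas = {g: np.zeros((12, 4)) for g in ("AA", "AB", "BB")}
        model.growth_slope = np.zeros((12, 4))
        model.cohort_slope = np.zeros((12, 4))
        cfg = SimConfig(n_fish=5, seed=9, shape_model=model)
        fish = generate_population(cfg)
        fish["otolith_side"] = "right"
        outs = [generate_otolith_outline(row, 0.0, model,
                                         np.random.default_rng(i))
                for i, (_, row) in enumerate(fish.iterrows())]
        for o in outs[1:]:
            np.testing.assert_allclose(o.points, outs[0].points, atol=1e-12)

    def test_growth_slope_moves_descriptors_linearly(self):
        """Two fish differing only in true G differ in measured coefficients
        by a fixed linear response proportional to growth_slope * delta-G.

        The response direction is the planted slope as seen through the
        arc-length re-parameterization of the perturbed outline (perturbing
        a curve perturbs its own parameterization), so the oracle is
        forward-computed: the map must be linear in delta-G and carry the
        planted magnitude."""
        from otoshape.fourier import elliptic_fourier
        model = ShapeEffectModel(noise_sd=0.0)
        model.genotype_deltas = {g: np.zeros((12, 4)) for g in ("AA", "AB", "BB")}
        cfg = SimConfig(n_fish=2, seed=1, shape_model=model)
        fish = generate_population(cfg)
        fish["otolith_side"] = "right"
        row = fish.iloc[0]
        outs = {dg: generate_otolith_outline(row, dg, model,
                                             np.random.default_rng(0))
                for dg in (0.0, 2.0, 4.0)}
        c = {dg: elliptic_fourier(o, 12) for dg, o in outs.items()}
        d2 = c[2.0] - c[0.0]
        d4 = c[4.0] - c[0.0]
        np.testing.assert_allclose(d4, 2.0 * d2, atol=2e-4)
        scale = np.linalg.norm(model.growth_slope * 4.0)
        assert 0.5 * scale < np.linalg.norm(d4) < 2.0 * scale

    def test_validate_accepts_default_model(self):
        ShapeEffectModel().validate()

    def test_left_side_outline_is_mirrored(self):
        model = ShapeEffectModel(noise_sd=0.0)
        cfg = SimConfig(n_fish=1, seed=6, shape_model=model)
        fish = generate_population(cfg)
        row_r = fish.iloc[0].copy()
        row_r["otolith_side"] = "right"
        row_l = fish.iloc[0].copy()
        row_l["otolith_side"] = "left"
        o_r = generate_otolith_outline(row_r, 1.0, model, np.random.default_rng(3))
        o_l = generate_otolith_outline(row_l, 1.0, model, np.random.default_rng(3))
        np.testing.assert_allclose(o_l.mirrored().points, o_r.points, atol=1e-12)

    def test_impossible_simple_outline_errors_after_retries(self):
        model = ShapeEffectModel(noise_sd=0.0)
        model.base_harmonics = model.base_harmonics.copy()
        # figure-eight-like first harmonic degenerate case
        model.base_harmonics[:] = 0.0
        model.base_harmonics[0] = [1.0, 0.0, 0.0, 0.0]   # flat segment
        cfg = SimConfig(n_fish=1, seed=6)
        fish = generate_population(cfg)
        row = fish.iloc[0]
        with pytest.raises((OutlineGenerationError, Exception)):
            generate_otolith_outline(row, 0.0, model, np.random.default_rng(0))

    def test_study_reproducible(self):
        f1, o1 = generate_study(SimConfig(n_fish=12, seed=13))
        f2, o2 = generate_study(SimConfig(n_fish=12, seed=13))
        pd.testing.assert_frame_equal(f1, f2)
        for k in o1:
            np.testing.assert_array_equal(o1[k].points, o2[k].points)


class TestRender:
    def test_unit_circle_renders_as_200px_disc(self):
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        from otoshape.outline import Outline
        o = Outline(np.column_stack([np.cos(t), np.sin(t)]))
        img = render_outline_to_image(o, 100.0, (300, 300))
        mask = binarize(img)
        rows = np.where(mask.any(axis=1))[0]
        assert rows.max() - rows.min() + 1 == pytest.approx(200, abs=3)
        assert img.dtype == np.uint8

    def test_render_extract_feret_round_trip(self, rng):
        from conftest import random_star_outline
        ppmm = 60.0
        for _ in range(3):
            o = random_star_outline(rng)
            img = render_outline_to_image(o, ppmm, (300, 300))
            o2 = trace_outline(binarize(img), ppmm)
            assert abs(feret_diameter(o2.points) - feret_diameter(o.points)) \
                <= 2.0 / ppmm

    def test_margin_violation_raises(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        from otoshape.outline import Outline
        o = Outline(np.column_stack([np.cos(t), np.sin(t)]))
        with pytest.raises(SizingError):
            render_outline_to_image(o, 100.0, (150, 150))

    def test_same_seed_byte_identical_images(self):
        fish, outs = generate_study(SimConfig(n_fish=3, seed=21))
        imgs1 = [render_outline_to_image(o, 20.0, (512, 512)).tobytes()
                 for o in outs.values()]
        fish2, outs2 = generate_study(SimConfig(n_fish=3, seed=21))
        imgs2 = [render_outline_to_image(o, 20.0, (512, 512)).tobytes()
                 for o in outs2.values()]
        assert imgs1 == imgs2


def test_write_study_outputs(tmp_path):
    cfg = SimConfig(n_fish=10, seed=30)
    fish = generate_population(cfg)
    write_study(fish, cfg, tmp_path)
    assert (tmp_path / "fish.csv").exists()
    import json
    meta = json.loads((tmp_path / "config.json").read_text())
    assert meta["seed"] == 30
    back = pd.read_csv(tmp_path / "fish.csv", index_col="id")
    assert len(back) == 10
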