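"""Synthetic texture, scene, receptor and predation-data generators."""

import numpy as np
import pytest
from scipy.stats import kstest

from camoquant import (
    PredationSimConfig,
    Spectrum,
    TextureConfig,
    gen_predation_dataset,
    gen_receptor_set,
    gen_scene,
    gen_texture,
    quantum_catch,
    texture_defaults,
)
from camoquant.errors import DomainError, UsageError
from camoquant.granularity import pattern_energy_spectrum
from camoquant.rnl import chromatic_jnd, roi_jnd
from camoquant.spectra import ReceptorSet
from camoquant.survival import logrank_pairwise
from camoquant.synthetic import flat_illuminant


class TestGenTexture:
    def test_zero_contrast_constant(self):
        cfg = TextureConfig("lichen", scale_px=8, contrast=0.0)
        tex = gen_texture(cfg, 64, seed=1)
        np.testing.assert_allclose(tex, 0.5)

    def test_deterministic_under_seed(self):
        cfg = texture_defaults("lichen", seed=7)
        np.testing.assert_array_equal(gen_texture(cfg, 160), gen_texture(cfg, 160))

    def test_different_seeds_differ(self):
        cfg = texture_defaults("lichen")
        assert not np.array_equal(
            gen_texture(cfg, 160, seed=1), gen_texture(cfg, 160, seed=2)
        )

    def test_invalid_class_and_size(self):
        with pytest.raises(UsageError):
            TextureConfig("granite")
        with pytest.raises(UsageError):
            gen_texture(texture_defaults("lichen"), 64)  # < 4× scale 32

    @pytest.mark.parametrize("kind", ["lichen", "bark", "moth"])
    def test_spectrum_peaks_within_one_octave_of_scale(self, kind):
        cfg = texture_defaults(kind)
        hits = 0
        for seed in range(20):
            tex = gen_texture(cfg, 256, seed=seed)
            spec = pattern_energy_spectrum(tex, normalize=False)
            peak = spec.scales_px[np.argmax(spec.energies)]
            hits += cfg.scale_px / 2 <= peak <= cfg.scale_px * 2
        assert hits >= 18  # ≥ 90% of seeds

    def test_bark_is_anisotropic(self):
        # vertical striations vary slowly down a column and quickly along a
        # row: the mean absolute vertical gradient is clearly smaller
        tex = gen_texture(texture_defaults("bark"), 256, seed=3)
        grad_y = np.abs(np.diff(tex, axis=0)).mean()
        grad_x = np.abs(np.diff(tex, axis=1)).mean()
        assert grad_y < 0.7 * grad_x


class TestGenReceptorSet:
    def test_default_fixture_validates(self):
        recs = gen_receptor_set()
        assert isinstance(recs, ReceptorSet)
        assert recs.luminance_channel == "dbl"
        assert len(recs.chromatic_names) == 4
        assert recs.weber["lw"] == pytest.approx(0.05)  # most abundant cone

    def test_flat_grey_equal_catches_after_von_kries(self):
        recs = gen_receptor_set()
        q = quantum_catch(Spectrum.flat(0.4), flat_illuminant(), recs)
        vals = q.array(recs.names)
        np.testing.assert_allclose(vals, 0.4, atol=1e-12)

    def test_single_chromatic_channel_rejected_downstream(self):
        with pytest.raises(UsageError):
            gen_receptor_set(lambda_max=(500.0,), widths=(40.0,),
                             abundances=(1.0,), names=("mw",))

    def test_duplicate_names_rejected(self):
        with pytest.raises(UsageError):
            gen_receptor_set(names=("uv", "uv", "mw", "lw"))

    def test_roundtrip_via_directory(self, tmp_path):
        recs = gen_receptor_set()
        recs.to_dir(tmp_path / "recs")
        back = ReceptorSet.from_dir(tmp_path / "recs")
        assert back.names == recs.names
        assert back.weber == pytest.approx(recs.weber)


class TestGenScene:
    def test_deterministic(self):
        img1, m1 = gen_scene(seed=11)
        img2, m2 = gen_scene(seed=11)
        np.testing.assert_array_equal(m1, m2)
        for n in img1.names:
            np.testing.assert_array_equal(img1.channels[n], img2.channels[n])

    def test_moth_size_matches_wingspan(self):
        # 22 mm span at 10 px/mm → mask major axis ≈ 220 px
        _, mask = gen_scene(seed=2)
        cols = np.where((mask == 1).any(axis=0))[0]
        assert cols[-1] - cols[0] + 1 == pytest.approx(220, abs=3)

    def test_identical_textures_zero_chromatic_jnd(self):
        cfg = texture_defaults("lichen")
        img, mask = gen_scene(moth_cfg=cfg, bg_cfg=cfg, seed=5)
        res = roi_jnd(img, mask)
        assert res.chromatic_jnd < 0.05

    def test_chromatic_offset_raises_jnd(self):
        cfg = texture_defaults("lichen")
        img, mask = gen_scene(moth_cfg=cfg, bg_cfg=cfg, chromatic_offset=0.2, seed=5)
        assert roi_jnd(img, mask).chromatic_jnd > 1.0

    def test_moth_must_fit(self):
        with pytest.raises(UsageError):
            gen_scene(size=(128, 128), seed=0)  # 220-px moth in a 128-px scene


class TestGenPredation:
    def test_zero_hazard_all_censored(self):
        df = gen_predation_dataset(
            PredationSimConfig(hazards={"a": 0.0}, n_per_treatment=25, seed=0)
        )
        assert (df["status"] == 0).all()
        assert (df["time_h"] == 72.0).all()

    def test_huge_hazard_all_events_first_check(self):
        df = gen_predation_dataset(
            PredationSimConfig(hazards={"a": 1e3}, n_per_treatment=25, seed=0)
        )
        assert (df["status"] == 1).all()
        assert (df["time_h"] == 24.0).all()

    def test_deterministic_and_shapes(self):
        cfg = PredationSimConfig(hazards={"a": 0.01, "b": 0.005}, n_per_treatment=40, seed=3)
        d1, d2 = gen_predation_dataset(cfg), gen_predation_dataset(cfg)
        assert d1.equals(d2)
        assert len(d1) == 80
        assert set(d1["time_h"].unique()) <= {24.0, 48.0, 72.0}

    def test_event_fraction_matches_hazard(self):
        from camoquant import hazard_for_event_fraction

        lam = hazard_for_event_fraction(0.52)
        df = gen_predation_dataset(
            PredationSimConfig(hazards={"a": lam}, n_per_treatment=20000, seed=1)
        )
        assert df["status"].mean() == pytest.approx(0.52, abs=0.01)

    def test_invalid_configs(self):
        with pytest.raises(DomainError):
            PredationSimConfig(hazards={"a": -0.1})
        with pytest.raises(DomainError):
            PredationSimConfig(hazards={"a": 0.1}, check_times=(48.0, 24.0))

    def test_null_logrank_p_uniform(self):
        # equal hazards ⇒ log-rank p-values uniform on [0, 1]
        ps = []
        for seed in range(200):
            df = gen_predation_dataset(
                PredationSimConfig(
                    hazards={"a": 0.01, "b": 0.01}, n_per_treatment=50, seed=seed
                )
            )
            ps.append(logrank_pairwise(df, adjust=None).loc[0, "p"])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestSceneGranularityDirection:
    def test_lichen_moth_matches_lichen_better_than_bark(self):
        # PED(moth on bark) > PED(moth on lichen) for a lichen-like moth
        wins = 0
        for seed in range(20):
            peds = {}
            for bg in ("lichen", "bark"):
                img, mask = gen_scene(
                    moth_cfg=texture_defaults("moth"),
                    bg_cfg=texture_defaults(bg),
                    seed=300 + seed,
                )
                from camoquant import ped as ped_op

                s1 = pattern_energy_spectrum(img, mask, roi_label=1, normalize=False)
                s2 = pattern_energy_spectrum(img, mask, roi_label=2, normalize=False)
                peds[bg] = ped_op(s1, s2, mode="mean").ped
            wins += peds["lichen"] < peds["bark"]
        assert wins >= 18
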