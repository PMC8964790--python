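import numpy as np
import pytest

from fatiguenet.data_model import DEFAULT_BANDS, default_montage
from fatiguenet.network import clustering_coefficient, fc_matrix
from fatiguenet.preprocess import roi_aggregate
from fatiguenet.synthetic import (
    CouplingSpec,
    LevelEffect,
    StudyDesign,
    apply_level_effect,
    cell_seed,
    default_coupling_spec,
    default_score_models,
    draw_mfi_items,
    generate_band_signals,
    generate_session,
    generate_study,
    read_study,
)

BAND_II = DEFAULT_BANDS[1]
BAND_V = DEFAULT_BANDS[4]
FS = 16.0


class TestGenerateBandSignals:
    def test_identity_target_uncorrelated_wide_band(self):
        """Band V is wide enough that 16,000 samples give plenty of effective
        dof; off-diagonal sample correlations stay below 0.1."""
        sig = generate_band_signals(np.eye(8), BAND_V, 16_000, FS, seed=3)
        r = np.corrcoef(sig, rowvar=False)
        off = r[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_narrow_band_correlations_converge_with_length(self):
        """Narrow-band series carry few effective samples per second, so the
        sample-correlation error is large at short lengths; it must shrink
        as the series grows (convergence-to-target contract)."""
        target = np.eye(8)
        target[0, 1] = target[1, 0] = 0.8
        errs = {}
        for n in (4096, 65536):
            per_seed = []
            for s in range(10):
                r = np.corrcoef(
                    generate_band_signals(target, BAND_II, n, FS, seed=s), rowvar=False
                )
                per_seed.append(np.abs(r - target).max())
            errs[n] = np.mean(per_seed)
        assert errs[65536] < errs[4096]

    def test_pairwise_coupling_recovered(self):
        """Mean sample correlation over 20 seeds recovers the target 0.8 in
        a wide band, where 16,000 samples carry thousands of effective dof."""
        target = np.eye(8)
        target[0, 1] = target[1, 0] = 0.8
        r12 = [
            np.corrcoef(
                generate_band_signals(target, BAND_V, 16_000, FS, seed=s), rowvar=False
            )[0, 1]
            for s in range(20)
        ]
        assert abs(np.mean(r12) - 0.8) < 0.05

    def test_same_seed_reproduces_exactly(self):
        a = generate_band_signals(np.eye(4), BAND_II, 2048, FS, seed=9)
        b = generate_band_signals(np.eye(4), BAND_II, 2048, FS, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_non_psd_target_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            generate_band_signals(bad, BAND_II, 1024, FS, seed=0)


class TestGenerateSession:
    def test_hbt_is_exact_sum(self, short_design):
        s = generate_session(short_design, "p1", "PVT", "L2", seed=5)
        np.testing.assert_array_equal(
            s.recordings["HbT"].samples,
            s.recordings["HbO"].samples + s.recordings["HbR"].samples,
        )

    def test_noiseless_channels_copy_roi_latent(self):
        """With zero sensor noise and kappa = 0, channels within an ROI are
        exact copies of their ROI latent."""
        coupling = default_coupling_spec()
        coupling = CouplingSpec(
            targets=coupling.targets,
            amplitudes=coupling.amplitudes,
            noise_sd=0.0,
            kappa=0.0,
        )
        design = StudyDesign(n_per_cell=1, duration=64.0, coupling=coupling)
        s = generate_session(design, "p1", "PVT", "L1", seed=1)
        mont = default_montage()
        hbo = s.recordings["HbO"].samples
        for roi in mont.roi_order:
            idx = mont.channel_indices(roi, s.recordings["HbO"].channel_ids)
            for j in idx[1:]:
                np.testing.assert_array_equal(hbo[:, j], hbo[:, idx[0]])

    def test_l1_mfi_below_l2_center(self):
        """Non-fatigued sessions score well under the moderate-fatigue center
        in nearly every draw."""
        models = default_score_models()
        rng = np.random.default_rng(77)
        means = [np.mean(draw_mfi_items(models["L1"], rng)) for _ in range(100)]
        frac = np.mean(np.array(means) < models["L2"].mfi_center)
        assert frac >= 0.95

    def test_unknown_level_rejected(self, short_design):
        with pytest.raises(ValueError, match="level"):
            generate_session(short_design, "p1", "PVT", "L9", seed=0)


class TestLevelEffects:
    def test_scaling_preserves_correlation_validity(self):
        spec = default_coupling_spec()
        eff = LevelEffect(global_scale={"III": 0.15}, right_scale={"II": 1.4})
        for band in ("II", "III"):
            t = apply_level_effect(spec.targets[band], band, eff)
            assert np.allclose(np.diag(t), 1.0)
            assert np.linalg.eigvalsh(t).min() >= -1e-10

    def test_right_hemisphere_scale_targets_right_pairs_only(self):
        spec = default_coupling_spec()
        base = spec.targets["II"]
        t = apply_level_effect(base, "II", LevelEffect(right_scale={"II": 1.4}))
        # R-PFC (2) ~ R-FEF (4) scaled; L-PFC (0) ~ L-FEF (3) untouched; the
        # projection restoring positive semidefiniteness may shift entries
        # by a small amount
        assert t[2, 4] == pytest.approx(base[2, 4] * 1.4, abs=0.01)
        assert t[0, 3] == pytest.approx(base[0, 3], abs=0.01)
        assert t[2, 4] > t[0, 3]

    def test_band_iii_coupling_modifier_raises_clustering(self):
        """Weakening band-III coupling lowers the downstream band-III
        weighted clustering coefficient (positive rank correlation between
        the modifier and clustering over a 5-point grid)."""
        from scipy.stats import spearmanr

        mont = default_montage()
        band_iii = DEFAULT_BANDS[2]
        grid = [0.15, 0.3, 0.5, 0.75, 1.0]
        mods, cs = [], []
        for g in grid:
            effects = {
                "L1": LevelEffect(global_scale={"III": g}),
                "L2": LevelEffect(),
                "L3": LevelEffect(),
            }
            design = StudyDesign(duration=1200.0, level_effects=effects)
            for seed in range(10):
                s = generate_session(
                    design, "p1", "PVT", "L1", seed=1000 + seed,
                    species=("HbO",), bands=(band_iii,),
                )
                brs = roi_aggregate(s.recordings["HbO"], mont, (band_iii,))[0]
                mods.append(g)
                cs.append(clustering_coefficient(fc_matrix(brs).w))
        rho = spearmanr(mods, cs).statistic
        assert rho > 0


class TestGenerateStudy:
    def test_cell_count(self):
        design = StudyDesign(n_per_cell=2, duration=64.0, seed=3)
        sessions = generate_study(design, species=("HbO",), bands=(BAND_II,))
        assert len(sessions) == 18  # 2 x 3 tasks x 3 levels
        levels = {s.fatigue_level for s in sessions}
        assert levels == {"L1", "L2", "L3"}

    def test_same_seed_byte_identical_files(self, tmp_path):
        design = StudyDesign(n_per_cell=1, duration=32.0, seed=21)
        generate_study(design, out_dir=tmp_path / "a")
        generate_study(design, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_enlarging_study_preserves_existing_sessions(self):
        small = StudyDesign(n_per_cell=1, duration=32.0, seed=4)
        large = StudyDesign(n_per_cell=2, duration=32.0, seed=4)
        s_small = generate_study(small, species=("HbO",), bands=(BAND_II,))
        s_large = generate_study(large, species=("HbO",), bands=(BAND_II,))
        by_id = {s.participant_id: s for s in s_large}
        for s in s_small:
            np.testing.assert_array_equal(
                s.recordings["HbO"].samples, by_id[s.participant_id].recordings["HbO"].samples
            )

    def test_cell_seed_stable_and_bounded(self):
        a = cell_seed(7, "p01", "PVT", "L1")
        assert a == cell_seed(7, "p01", "PVT", "L1")
        assert 0 <= a < 2**31
        assert a != cell_seed(8, "p01", "PVT", "L1")

    def test_round_trip_read_study(self, tmp_path):
        design = StudyDesign(n_per_cell=1, duration=32.0, seed=5)
        written = generate_study(design, out_dir=tmp_path)
        back, mont = read_study(tmp_path)
        assert len(back) == len(written)
        assert mont.n_rois == 8
        for a, b in zip(written, back):
            assert a.participant_id == b.participant_id
            assert a.mfi_items == b.mfi_items
            np.testing.assert_allclose(
                a.recordings["HbO"].samples, b.recordings["HbO"].samples, rtol=1e-11
            )
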