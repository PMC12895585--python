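"""Synthetic cohort generator: determinism, planted structure, clinical copula."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram
from scipy.stats import spearmanr

from fnirsfc.connectivity import dynamic_fc, static_fc
from fnirsfc.preprocess import RoiTimeSeries
from fnirsfc.synthetic import (
    ArtifactSpec,
    DynamicModulation,
    NoiseSpec,
    SimulationConfig,
    generate_clinical,
    generate_roi_latents,
    latent_feature_table,
    project_to_channels,
    simulate_cohort,
)


class TestLatents:
    def test_same_seed_and_index_are_bit_identical(self, small_config):
        a, _ = generate_roi_latents(small_config, 3)
        b, _ = generate_roi_latents(small_config, 3)
        assert np.array_equal(a, b)

    def test_different_indices_differ(self, small_config):
        a, _ = generate_roi_latents(small_config, 0)
        b, _ = generate_roi_latents(small_config, 1)
        assert not np.array_equal(a, b)

    def test_realised_pairwise_z_tracks_planted_target(self, small_config):
        traces, truth = generate_roi_latents(small_config, 0)
        z = static_fc(
            RoiTimeSeries(traces, small_config.roi_names, 10.0)
        ).pair_vector
        assert np.abs(z - np.array(truth["z_base_pairs"])).mean() < 0.05

    def test_hc_cohort_mean_z_within_0p05_of_target(self):
        """Monte-Carlo check of the generator against its own 0.39 target."""
        cfg = SimulationConfig(n_per_group=40, seed=9)
        means = []
        for i in range(cfg.n_per_group, cfg.n_total):  # the HC block
            traces, _ = generate_roi_latents(cfg, i)
            z = static_fc(RoiTimeSeries(traces, cfg.roi_names, 10.0)).pair_vector
            means.append(z.mean())
        assert np.mean(means) == pytest.approx(0.39, abs=0.05)

    def test_stationary_case_windows_match_full_period(self):
        cfg = SimulationConfig(
            n_per_group=4, seed=5, dynamic_modulation=DynamicModulation(0.0, 60.0)
        )
        traces, _ = generate_roi_latents(cfg, 0)
        ts = RoiTimeSeries(traces, cfg.roi_names, 10.0)
        static_z = static_fc(ts).pair_vector
        row_mean = dynamic_fc(ts).X.mean(axis=1)
        assert np.abs(row_mean - static_z).mean() < 0.15

    def test_modulation_raises_window_variability(self):
        base = SimulationConfig(n_per_group=4, seed=5)
        flat = replace(base, dynamic_modulation=DynamicModulation(0.0, 60.0))
        mod = replace(base, dynamic_modulation=DynamicModulation(0.3, 60.0))
        def wsd(cfg):
            tr, _ = generate_roi_latents(cfg, 0)
            return dynamic_fc(RoiTimeSeries(tr, cfg.roi_names, 10.0)).X.std(axis=1).mean()
        assert wsd(mod) > wsd(flat)

    def test_infinite_mean_z_rejected(self):
        with pytest.raises(ValueError, match="implies"):
            SimulationConfig(group_mean_z={"HC": np.inf, "MDD": 0.3})

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SimulationConfig(noise=NoiseSpec(white_sd=-0.1))


class TestChannelProjection:
    def test_zero_noise_makes_roi_channels_identical(self, montage):
        cfg = SimulationConfig(
            n_per_group=2,
            seed=1,
            noise=NoiseSpec(cardiac_amp=0, respiratory_amp=0, mayer_amp=0, white_sd=0),
            artifacts=ArtifactSpec(0, 0),
        )
        lat, _ = generate_roi_latents(cfg, 0)
        rec = project_to_channels(lat, montage, cfg, 0)
        task = rec.task_intensity()
        for roi in montage.roi_order:
            members = montage.roi_channels(roi)
            rows = [rec.channel_ids.index(ch) for ch in members]
            ref = task[830][rows[0]]
            for r in rows[1:]:
                assert np.allclose(task[830][r], ref, atol=1e-15)

    def test_artifact_log_records_injections(self, montage):
        cfg = SimulationConfig(
            n_per_group=2, seed=2, artifacts=ArtifactSpec(spikes_per_min=8, shifts_per_min=4)
        )
        lat, _ = generate_roi_latents(cfg, 0)
        rec = project_to_channels(lat, montage, cfg, 0)
        assert len(rec.log) > 0
        kinds = {e["type"] for e in rec.log}
        assert kinds <= {"spike", "shift"}
        assert all(0 <= e["time_s"] <= 150 for e in rec.log)

    def test_cardiac_component_peaks_near_1hz(self, montage):
        cfg = SimulationConfig(n_per_group=2, seed=3,
                               noise=NoiseSpec(cardiac_amp=2.0, white_sd=0.05),
                               artifacts=ArtifactSpec(0, 0))
        lat, _ = generate_roi_latents(cfg, 0)
        rec = project_to_channels(lat, montage, cfg, 0)
        x = rec.task_intensity()[830][0]
        f, p = periodogram(x - x.mean(), fs=10.0)
        band = (f > 0.5) & (f < 2.0)
        peak = f[band][np.argmax(p[band])]
        assert peak == pytest.approx(1.0, abs=0.1)

    def test_baseline_is_prepended_and_artifact_free(self, montage, small_config):
        lat, _ = generate_roi_latents(small_config, 0)
        rec = project_to_channels(lat, montage, small_config, 0)
        base = rec.baseline_segment()
        assert base.duration_s == pytest.approx(10.0)
        assert rec.n_task_samples == 1500


@pytest.fixture(scope="module")
def cohort83():
    cfg = SimulationConfig(n_per_group=83, seed=13)
    latents = []
    for i in range(cfg.n_total):
        tr, _ = generate_roi_latents(cfg, i)
        latents.append(
            RoiTimeSeries(tr, cfg.roi_names, 10.0,
                          participant_id=cfg.participant_id(i),
                          group=cfg.group_of(i))
        )
    feats = latent_feature_table(cfg, latents)
    clinical = generate_clinical(cfg, feats.table, cfg.seed)
    return cfg, feats, clinical


class TestClinical:
    def test_instrument_ranges_and_demographics(self, cohort83):
        cfg, feats, clinical = cohort83
        mdd = clinical[clinical["group"] == "MDD"]
        assert mdd[["dass_d", "dass_a", "dass_s"]].stack().between(0, 21).all()
        assert mdd["shaps"].between(0, 42).all()
        assert clinical["age"].between(12, 18).all()
        hc = clinical[clinical["group"] == "HC"]
        assert hc["dass_d"].isna().all() and hc["medication"].isna().all()
        assert mdd["medication"].notna().all()

    def test_shaps_moments_match_configuration(self, cohort83):
        cfg, _, clinical = cohort83
        shaps = clinical.loc[clinical["group"] == "MDD", "shaps"]
        n = len(shaps)
        assert shaps.mean() == pytest.approx(33.07, abs=3 * 7.37 / np.sqrt(n))
        assert shaps.std() == pytest.approx(7.37, abs=3 * 7.37 / np.sqrt(2 * n))

    def test_planted_spearman_recovered_within_band(self, cohort83):
        # a single n=83 draw has sampling SD ~ 0.09, so check the mean
        # over several independent clinical draws on the same features
        cfg, feats, _ = cohort83
        acc = {link: [] for link in cfg.clinical.links}
        for s in range(8):
            clinical = generate_clinical(cfg, feats.table, seed=s)
            mdd = clinical[clinical["group"] == "MDD"]
            for feat, score, target in cfg.clinical.links:
                col = {"DASS-D": "dass_d", "DASS-A": "dass_a", "SHAPS": "shaps"}[score]
                acc[(feat, score, target)].append(
                    spearmanr(feats.table.loc[mdd.index, feat], mdd[col]).statistic
                )
        for (feat, score, target), rs in acc.items():
            assert np.mean(rs) == pytest.approx(target, abs=0.15), (feat, score)

    def test_unlinked_score_stays_in_null_band(self, cohort83):
        cfg, feats, clinical = cohort83
        mdd = clinical[clinical["group"] == "MDD"]
        r = spearmanr(
            feats.table.loc[mdd.index, "static|DLPFC(R)~mPFC(R)"], mdd["dass_s"]
        ).statistic
        assert abs(r) < 3.0 / np.sqrt(len(mdd))

    def test_unknown_link_feature_rejected(self, cohort83):
        cfg, feats, _ = cohort83
        bad = replace(cfg)
        bad.clinical = replace(cfg.clinical, links=[("pc99|nope", "SHAPS", -0.5)])
        with pytest.raises(ValueError, match="pc99"):
            generate_clinical(bad, feats.table, 0)

    def test_extreme_target_r_rejected(self):
        from fnirsfc.synthetic import ClinicalSpec

        with pytest.raises(ValueError, match="Spearman"):
            SimulationConfig(
                clinical=ClinicalSpec(links=[("static|DLPFC(R)~mPFC(R)", "SHAPS", 1.0)])
            )


class TestCohortAssembly:
    def test_simulate_cohort_is_deterministic(self):
        cfg = SimulationConfig(n_per_group=2, seed=21)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for ra, rb in zip(a.recordings, b.recordings):
            for lam in ra.wavelengths:
                assert np.array_equal(ra.intensity[lam], rb.intensity[lam])
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        assert a.truth["participants"] == b.truth["participants"]

    def test_one_clinical_row_per_recording(self):
        cfg = SimulationConfig(n_per_group=3, seed=8)
        cohort = simulate_cohort(cfg)
        assert len(cohort.clinical) == len(cohort.recordings)
        ids = {r.participant_id for r in cohort.recordings}
        assert set(cohort.clinical.index) == ids
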