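"""The dipole-model generator: geometry, morphology, priors, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import find_peaks

from cardiolead.preprocess import derive_dependent_leads
from cardiolead.ptbxl import CLASS_NAMES
from cardiolead.synthetic import (
    LEAD_AXES,
    SynthConfig,
    Wave,
    _draw_beat_params,
    dipole_trajectory,
    generate_dataset,
    project_to_leads,
    synth_record,
)


def _labels(*names):
    v = np.zeros(20, dtype=np.int8)
    for n in names:
        v[CLASS_NAMES.index(n)] = 1
    return v


class TestDipoleTrajectory:
    def test_zero_amplitudes_give_zero(self):
        t = np.arange(5000) / 500.0
        waves = [Wave(0.0, 0.02, 0.0, [1, 0, 0])]
        assert np.all(dipole_trajectory(waves, 70, t) == 0.0)

    def test_beat_count_matches_heart_rate(self):
        t = np.arange(5000) / 500.0
        for hr in (50.0, 72.0, 90.0):
            waves = [Wave(1.0, 0.015, 0.0, [1, 0, 0])]
            x = dipole_trajectory(waves, hr, t, phase=0.3)[0]
            peaks, _ = find_peaks(x, height=0.5)
            expected = 10.0 * hr / 60.0
            assert abs(len(peaks) - expected) <= 1

    def test_overlapping_beats_rejected(self):
        t = np.arange(500) / 500.0
        waves = [Wave(1.0, 0.02, -0.32, [0, 1, 0]), Wave(1.0, 0.02, 0.32, [0, 1, 0])]
        with pytest.raises(ValueError, match="bpm"):
            dipole_trajectory(waves, 200.0, t)


class TestProjection:
    def test_limb_identities_exact(self, rng):
        source = rng.normal(size=(3, 400))
        leads = project_to_leads(source)
        d3, avr, avl, avf = derive_dependent_leads(leads[0], leads[1])
        np.testing.assert_allclose(leads[2], d3, atol=1e-13)
        np.testing.assert_allclose(leads[3], avr, atol=1e-13)
        np.testing.assert_allclose(leads[4], avl, atol=1e-13)
        np.testing.assert_allclose(leads[5], avf, atol=1e-13)

    def test_lateral_source_maximal_in_d1(self):
        source = np.zeros((3, 10))
        source[0] = 1.0                      # dipole along the D1 (x) axis
        leads = project_to_leads(source)
        assert np.argmax(np.abs(leads[:6, 0])) == 0     # strongest limb lead: D1
        np.testing.assert_allclose(leads[5], 0.0, atol=1e-15)   # aVF orthogonal

    def test_goldberger_avr_built_in(self):
        np.testing.assert_allclose(
            LEAD_AXES[3], -(LEAD_AXES[0] + LEAD_AXES[1]) / 2.0, atol=1e-15
        )

    def test_bad_source_shape_rejected(self):
        with pytest.raises(ValueError):
            project_to_leads(np.zeros((2, 10)))


class TestSynthRecord:
    CFG = SynthConfig(seed=0)

    def test_norm_qrs_duration_in_range(self):
        _, params = synth_record(_labels("NORM"), self.CFG,
                                 np.random.default_rng(1))
        assert 0.08 <= params.qrs_duration <= 0.10

    def test_clbbb_qrs_widened(self):
        _, params = synth_record(_labels("CLBBB"), self.CFG,
                                 np.random.default_rng(2))
        assert params.qrs_duration >= 0.13

    def test_avb_pr_lengthened(self):
        _, params = synth_record(_labels("_AVB"), self.CFG,
                                 np.random.default_rng(3))
        assert 0.24 <= params.pr_interval <= 0.32

    def test_lvh_gain(self):
        _, params = synth_record(_labels("LVH"), self.CFG,
                                 np.random.default_rng(4))
        assert 1.5 <= params.amplitude_gain <= 2.5

    def test_seeded_determinism(self):
        a, _ = synth_record(_labels("IMI"), self.CFG, np.random.default_rng(9))
        b, _ = synth_record(_labels("IMI"), self.CFG, np.random.default_rng(9))
        np.testing.assert_array_equal(a.signal, b.signal)
        assert a.fold == b.fold

    def test_imi_silent_in_d1_strong_in_d2(self):
        # the IMI deltas lie along the inferior axis, orthogonal to D1
        rng_n = np.random.default_rng(7)
        norm, _ = synth_record(_labels("NORM"), self.CFG, rng_n, noise_free=True)
        rng_i = np.random.default_rng(7)
        imi, _ = synth_record(_labels("IMI"), self.CFG, rng_i, noise_free=True)
        delta = np.abs(imi.signal - norm.signal)
        assert delta[0].max() < 1e-9          # D1 unchanged
        assert delta[1].max() > 0.3           # D2 sees the infarct pattern

    def test_shape_and_bounds(self):
        rec, _ = synth_record(_labels("AMI", "LVH"), self.CFG,
                              np.random.default_rng(5))
        assert rec.signal.shape == (12, 5000)
        assert rec.fs == 500
        assert np.all(np.isfinite(rec.signal))
        assert np.abs(rec.signal).max() <= 10.0
        assert 1 <= rec.fold <= 10

    def test_conflicting_labels_rejected(self):
        with pytest.raises(ValueError, match="exclusive"):
            synth_record(_labels("NORM", "IMI"), self.CFG,
                         np.random.default_rng(0))

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            synth_record(np.zeros(20, dtype=np.int8), self.CFG,
                         np.random.default_rng(0))


class TestGenerateDataset:
    def test_empty(self):
        records, manifest = generate_dataset(SynthConfig(n_records=0))
        assert records == [] and len(manifest) == 0

    def test_norm_frequency_within_binomial_bound(self):
        cfg = SynthConfig(n_records=1000, seed=123)
        records, _ = generate_dataset(cfg)
        norm_idx = CLASS_NAMES.index("NORM")
        count = sum(int(r.labels[norm_idx]) for r in records)
        p = cfg.class_priors["NORM"]
        se = np.sqrt(1000 * p * (1 - p))
        assert abs(count - 1000 * p) <= 3 * se

    def test_every_record_labeled_and_manifest_aligned(self, small_dataset):
        records, manifest = small_dataset
        assert all(r.labels.sum() >= 1 for r in records)
        assert list(manifest["ecg_id"]) == [r.record_id for r in records]
        assert list(manifest["strat_fold"]) == [r.fold for r in records]

    def test_unknown_prior_class_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(class_priors={"NOPE": 0.5})


class TestPathologyDraws:
    def test_modifiers_cover_all_pathological_classes(self):
        cfg = SynthConfig(seed=0)
        rng = np.random.default_rng(0)
        for name in CLASS_NAMES:
            if name == "NORM":
                continue
            params = _draw_beat_params(_labels(name), cfg, rng)
            assert params.qrs_duration > 0 and params.pr_interval > 0
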