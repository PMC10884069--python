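"""GFP, template assignment, polarity-invariant clustering, template matching."""

import itertools

import numpy as np
import pytest

from covmap import (ChannelInfo, Recording, TemplateSet, assign_templates,
                    gfp, gfp_peaks, kmeans_microstates, render_scalp_eeg,
                    resample_templates, template_correlation)
from covmap.microstate import (UNASSIGNED, standard_positions, read_templates,
                               write_templates)


def _rec_from_maps(maps_t, montage, sfreq=500.0):
    chans = [ChannelInfo(n, "scalp", "scalp") for n in montage]
    return Recording(maps_t, sfreq, chans)


class TestGfp:
    def test_two_electrode_antisymmetric_map(self):
        rec = _rec_from_maps(np.array([[1.0], [-1.0]]), ["a", "b"])
        assert gfp(rec)[0] == pytest.approx(1.0)

    def test_constant_map_has_zero_gfp(self):
        rec = _rec_from_maps(np.full((5, 3), 7.0), list("abcde"))
        np.testing.assert_allclose(gfp(rec), 0.0, atol=1e-12)

    def test_gfp_is_homogeneous_of_degree_one(self, scalp_noiseless):
        g1 = gfp(scalp_noiseless)
        g3 = gfp(scalp_noiseless.with_data(3.0 * scalp_noiseless.data))
        np.testing.assert_allclose(g3, 3.0 * g1, rtol=1e-10)

    def test_single_channel_rejected(self):
        rec = _rec_from_maps(np.zeros((1, 4)), ["a"])
        with pytest.raises(ValueError):
            gfp(rec)


class TestGfpPeaks:
    def test_monotone_series_has_no_peaks(self):
        assert gfp_peaks(np.arange(10.0)).size == 0

    def test_simple_series(self):
        np.testing.assert_array_equal(gfp_peaks(np.array([0, 1, 0, 2, 0.0])),
                                      [1, 3])

    def test_rectified_sinusoid_peak_count(self):
        t = np.arange(500) / 500.0
        g = np.abs(np.sin(2 * np.pi * 10.0 * t))
        assert gfp_peaks(g).size == 20  # one peak per half-cycle over 1 s


class TestTemplateSet:
    def test_maps_are_normalized_on_construction(self):
        maps = np.array([[1.0, 2.0, 3.0], [0.0, 5.0, 0.0]])
        tpl = TemplateSet(maps, list("abc"))
        np.testing.assert_allclose(tpl.maps.mean(axis=1), 0.0, atol=1e-14)
        np.testing.assert_allclose(np.linalg.norm(tpl.maps, axis=1), 1.0)

    def test_constant_map_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            TemplateSet(np.ones((1, 4)), list("abcd"))

    def test_tsv_round_trip(self, templates, tmp_path):
        path = tmp_path / "tpl.tsv"
        write_templates(templates, path)
        back = read_templates(path)
        assert back.montage == templates.montage
        np.testing.assert_allclose(back.maps, templates.maps, atol=1e-9)


class TestResampleTemplates:
    def test_identity_montage_preserves_maps(self, templates):
        out = resample_templates(templates, templates.montage)
        for a, b in zip(out.maps, templates.maps):
            assert abs(np.dot(a, b)) > 0.999

    def test_dipolar_field_survives_small_rotation(self):
        pos = standard_positions()
        d = np.array([0.3, 0.8, 0.52])
        src_map = pos @ d
        theta = np.deg2rad(5.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        tgt_pos = pos @ rot.T
        tpl = TemplateSet(src_map[None, :], list(map(str, range(len(pos)))))
        out = resample_templates(tpl, tpl.montage, source_pos=pos,
                                 target_pos=tgt_pos)
        analytic = tgt_pos @ d
        analytic -= analytic.mean()
        r = np.dot(out.maps[0], analytic) / np.linalg.norm(analytic)
        assert abs(r) > 0.99

    def test_too_few_source_electrodes_rejected(self):
        tpl = TemplateSet(np.array([[1.0, -1.0, 0.5]]), list("abc"))
        with pytest.raises(Exception):
            resample_templates(tpl, ["a", "b", "c"],
                               source_pos=np.eye(3), target_pos=np.eye(3))


class TestAssignTemplates:
    @staticmethod
    def _modulated(template):
        # fluctuating field strength so the GFP has peaks to assign at
        amp = 5.0 + np.sin(np.linspace(0, 20 * np.pi, 100))
        return template[:, None] * amp[None, :]

    def test_pure_template_assigned_everywhere(self, templates):
        rec = _rec_from_maps(self._modulated(templates.maps[3]),
                             templates.montage)
        tl = assign_templates(rec, templates)
        assert np.all(tl.labels == 3)

    def test_polarity_invariance(self, templates):
        rec = _rec_from_maps(-self._modulated(templates.maps[3]),
                             templates.montage)
        tl = assign_templates(rec, templates)
        assert np.all(tl.labels == 3)

    def test_noisy_synthetic_recovery_at_snr_five(self, sequence_60s, templates):
        noise_sd = float(np.mean(sequence_60s.amplitude)) / 5.0
        rec = render_scalp_eeg(sequence_60s, templates, noise_sd, seed=21)
        tl = assign_templates(rec, templates)
        peaks = gfp_peaks(gfp(rec))
        agreement = np.mean(tl.labels[peaks] == sequence_60s.labels[peaks])
        assert agreement >= 0.95

    def test_labels_invariant_to_sign_flip_and_scaling(self, sequence_60s,
                                                       templates):
        rec = render_scalp_eeg(sequence_60s, templates, 0.1, seed=22)
        tl = assign_templates(rec, templates)
        flipped = assign_templates(rec.with_data(-2.5 * rec.data), templates)
        np.testing.assert_array_equal(tl.labels, flipped.labels)

    def test_timeline_values_bounded_by_gfp_squared(self, sequence_60s,
                                                    templates):
        rec = render_scalp_eeg(sequence_60s, templates, 0.1, seed=23)
        tl = assign_templates(rec, templates)
        g2 = gfp(rec) ** 2
        total = tl.values.sum(axis=0)
        assert np.all(total <= g2 * (1 + 1e-10))
        # value is nonzero only for the assigned class
        for k in range(templates.k):
            assert np.all(tl.values[k][tl.labels != k] == 0.0)

    def test_masked_samples_are_unassigned_with_zero_value(self, sequence_60s,
                                                           templates):
        rec = render_scalp_eeg(sequence_60s, templates, 0.1, seed=24)
        mask = np.zeros(rec.n_samples, dtype=bool)
        mask[1000:2000] = True
        tl = assign_templates(rec, templates, mask)
        assert np.all(tl.labels[1000:2000] == UNASSIGNED)
        assert np.all(tl.values[:, 1000:2000] == 0.0)

    def test_montage_mismatch_rejected(self, templates, small_recording):
        with pytest.raises(ValueError):
            assign_templates(small_recording, templates)


class TestKmeans:
    def test_recovers_generating_templates(self, sequence_60s, templates):
        rec = render_scalp_eeg(sequence_60s, templates, 0.05, seed=31)
        est = kmeans_microstates(rec, k=7, n_restarts=10, seed=5)
        corr = np.abs(est.maps @ templates.maps.T)
        # greedy matching: every generating map well captured by a distinct mean
        taken = set()
        for j in range(7):
            order = np.argsort(-corr[:, j])
            i = next(i for i in order if i not in taken)
            taken.add(i)
            assert corr[i, j] > 0.9

    def test_single_cluster_on_sign_flipping_copies(self, templates):
        base = templates.maps[0]
        signs = np.resize([1.0, -1.0, 1.0, -1.0, -1.0], 200)
        amps = 1.0 + 0.5 * np.abs(np.sin(np.arange(200.0)))
        data = base[:, None] * (signs * amps)[None, :]
        rec = _rec_from_maps(data, templates.montage)
        est = kmeans_microstates(rec, k=1, n_restarts=3, seed=0)
        assert abs(np.dot(est.maps[0], base)) > 0.999

    def test_deterministic_given_seed(self, sequence_60s, templates):
        rec = render_scalp_eeg(sequence_60s, templates, 0.2, seed=32)
        a = kmeans_microstates(rec, k=7, n_restarts=3, seed=9)
        b = kmeans_microstates(rec, k=7, n_restarts=3, seed=9)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_too_few_peaks_rejected(self, templates):
        data = np.tile(templates.maps[0][:, None], (1, 5))
        rec = _rec_from_maps(data, templates.montage)
        with pytest.raises(ValueError):
            kmeans_microstates(rec, k=7, seed=0)


class TestTemplateCorrelation:
    def test_self_match_is_perfect(self, templates):
        match = template_correlation(templates, templates)
        assert match.mean_abs_r == pytest.approx(1.0)

    def test_sign_flips_do_not_matter(self, templates):
        flipped = TemplateSet(-templates.maps, templates.montage)
        match = template_correlation(flipped, templates)
        assert match.mean_abs_r == pytest.approx(1.0)

    def test_orthogonal_replacement_matches_exhaustive_oracle(self, templates):
        rng = np.random.default_rng(6)
        # replace map 0 by a direction orthogonal to all seven maps
        v = rng.normal(size=templates.n_electrodes)
        v -= v.mean()
        for m in templates.maps:
            v -= np.dot(v, m) * m
        v /= np.linalg.norm(v)
        altered = TemplateSet(
            np.vstack([v, templates.maps[1:]]), templates.montage)
        match = template_correlation(altered, templates)

        corr = np.abs(altered.maps @ templates.maps.T)
        best = max(np.mean([corr[i, j] for i, j in enumerate(perm)])
                   for perm in itertools.permutations(range(7)))
        assert match.mean_abs_r == pytest.approx(best, abs=1e-12)
        assert match.mean_abs_r == pytest.approx(6.0 / 7.0, abs=1e-9)

    def test_k_mismatch_rejected(self, templates):
        smaller = TemplateSet(templates.maps[:5], templates.montage)
        with pytest.raises(ValueError):
            template_correlation(smaller, templates)
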