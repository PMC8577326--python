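"""Forward model: kernels, superposition, noise spectrum, determinism."""

import numpy as np
import pytest
from scipy.signal import welch

from neommr.measures import EARLY_MMR_WINDOW
from neommr.paradigm import generate_block
from neommr.simulate import (
    CHANNELS,
    ErpTemplateParams,
    MmrEffectParams,
    NoiseParams,
    block_config_for,
    make_erp_kernel,
    simulate_cohort,
    simulate_subject,
    _one_over_f_noise,
)

FS = 3000.0


class TestKernel:
    def test_zero_amplitudes_give_flat_kernel(self):
        p = ErpTemplateParams(onset_amp_uv=0.0, offset_amp_uv=0.0,
                              spectrum_effect_central_uv=0.0,
                              duration_effect_midline_uv=0.0)
        k = make_erp_kernel(p, "nonfocal_e", "nonspeech", "CZ", FS)
        assert np.allclose(k, 0.0)

    def test_offset_component_tracks_duration(self):
        """A 180 ms duration difference shifts the offset component by
        exactly 180 ms; the onset component stays put."""
        p = ErpTemplateParams(onset_amp_uv=0.0, duration_effect_midline_uv=0.0)
        k_short = make_erp_kernel(p, "short_e", "nonspeech", "F3", FS)
        k_long = make_erp_kernel(p, "long_e", "nonspeech", "F3", FS)
        shift = int(round(0.180 * FS))
        n = len(k_short) - shift
        assert np.allclose(k_long[shift:], k_short[:n], atol=1e-9)

    def test_central_spectrum_effect_integrates_exactly(self):
        """The [ɛ]-vs-[a] kernel difference at a central channel integrates
        over the onset window to effect x window width (analytic Gaussian
        segment integral)."""
        p = ErpTemplateParams(subject_gain_sd=0.0)
        k_e = make_erp_kernel(p, "nonfocal_e", "speech", "CZ", FS)
        k_a = make_erp_kernel(p, "focal_a", "speech", "CZ", FS)
        t = np.arange(len(k_e)) / FS * 1000.0
        win = (t >= 350.0) & (t <= 550.0)  # onset window, vowel at +150 ms
        area = np.trapezoid((k_e - k_a)[win], t[win])
        assert area == pytest.approx(p.spectrum_effect_central_uv * 200.0, rel=0.01)

    def test_no_spectrum_effect_at_frontal_or_nonspeech(self):
        p = ErpTemplateParams()
        for dom, ch in (("speech", "F3"), ("nonspeech", "C3")):
            k_e = make_erp_kernel(p, "nonfocal_e", dom, ch, FS)
            k_a = make_erp_kernel(p, "focal_a", dom, ch, FS)
            assert np.allclose(k_e, k_a, atol=1e-12)

    def test_latency_outside_support_rejected(self):
        with pytest.raises(ValueError):
            make_erp_kernel(ErpTemplateParams(), "long_e", "speech", "CZ", FS,
                            support_ms=500.0)


class TestSimulateSubject:
    def test_same_seed_bit_identical(self, tiny_block):
        a = simulate_subject(tiny_block, seed=42, domain="speech", dimension="durational")
        b = simulate_subject(tiny_block, seed=42, domain="speech", dimension="durational")
        assert np.array_equal(a.signal, b.signal)

    def test_noise_free_same_category_epochs_identical(self, noise_free_recording):
        from neommr.pipeline import preprocess_recording

        es = preprocess_recording(noise_free_recording)
        mask = ((es.meta.category == "short_e") & (es.meta.role == "standard")).to_numpy()
        sub = es.data[mask]
        assert np.max(sub.max(axis=0) - sub.min(axis=0)) < 1e-5

    def test_evoked_part_is_superposition_of_kernels(self, tiny_block, silent_params):
        """With noise off, the continuous signal equals the sum of per-event
        kernels placed at the event onsets."""
        rec = simulate_subject(
            tiny_block, seed=0, domain="speech", dimension="durational", **silent_params
        )
        expected = np.zeros_like(rec.signal)
        support_ms = tiny_block.config.soa_s * 1000 - 100 + 150.0
        kern = {
            (c, ch): make_erp_kernel(
                silent_params["erp"], c, "speech", ch, FS, support_ms
            )
            for c in ("short_e", "long_e")
            for ch in CHANNELS
        }
        for e in tiny_block:
            i0 = int(round(e.onset_s * FS))
            for ci, ch in enumerate(CHANNELS):
                k = kern[(e.category, ch)]
                expected[ci, i0 : i0 + len(k)] += k
        assert np.allclose(rec.signal, expected, atol=1e-12)

    def test_mmr_deflection_only_on_deviants(self, tiny_block, silent_params):
        params = dict(silent_params)
        params["mmr"] = MmrEffectParams(
            base_early_uv=1.0, base_late_uv=0.0,
            asymmetry_early_uv=0.0, asymmetry_late_uv=0.0, subject_sd_uv=0.0,
        )
        rec = simulate_subject(
            tiny_block, seed=0, domain="speech", dimension="durational", **params
        )
        plain = simulate_subject(
            tiny_block, seed=0, domain="speech", dimension="durational", **silent_params
        )
        diff = rec.signal - plain.signal
        # deflections appear exactly at deviant tokens, inside the early window
        c0 = 150.0 + 180.0  # durational change onset, token time base
        for e in tiny_block:
            i0 = int(round((e.onset_s * 1000 + c0 + EARLY_MMR_WINDOW[0]) * FS / 1000))
            i1 = int(round((e.onset_s * 1000 + c0 + EARLY_MMR_WINDOW[1]) * FS / 1000))
            seg = np.abs(diff[:, i0:i1])
            if e.role == "deviant":
                assert seg.max() > 0.5
            else:
                # window may border a neighbouring deviant's deflection edge
                assert seg.mean() < 0.05

    def test_artifact_rate_drives_rejections(self, tiny_block):
        from neommr.pipeline import preprocess_recording

        noise = NoiseParams(rms_uv=0.0, artifact_rate=0.3)
        rec = simulate_subject(tiny_block, seed=21, noise=noise,
                               domain="nonspeech", dimension="durational")
        es = preprocess_recording(rec)
        n = len(es.meta)
        frac = es.rejected.mean()
        # binomial 99% interval around 0.3 for this n
        half = 2.58 * np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < half + 1e-9


class TestNoise:
    def test_spectral_slope(self):
        rng = np.random.default_rng(0)
        x = _one_over_f_noise(300000, 2, FS, NoiseParams(), rng)
        f, p = welch(x[0], fs=FS, nperseg=8192)
        m = (f >= 1) & (f <= 40)
        slope = np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)

    def test_rms_and_band_limit(self):
        rng = np.random.default_rng(1)
        x = _one_over_f_noise(300000, 3, FS, NoiseParams(), rng)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(15.0, rel=0.01)
        f, p = welch(x[0], fs=FS, nperseg=8192)
        in_band = p[(f > 1) & (f < 80)].mean()
        out_band = p[f > 300].mean()
        assert out_band < in_band / 1e3

    def test_channel_correlation(self):
        rng = np.random.default_rng(2)
        x = _one_over_f_noise(200000, 4, FS, NoiseParams(channel_correlation=0.5), rng)
        r = np.corrcoef(x)
        off = r[np.triu_indices(4, 1)]
        assert np.all(np.abs(off - 0.5) < 0.15)


class TestCohort:
    def test_single_subject(self, silent_params):
        recs = simulate_cohort(1, dimensions=("durational",), master_seed=5,
                               block_kwargs={"occurrences_per_length": 1},
                               **silent_params)
        assert len(recs) == 1 and recs[0].subject_id == "S000"

    def test_zero_subject_sd_shares_kernels(self, silent_params):
        recs = simulate_cohort(2, dimensions=("durational",), master_seed=5,
                               block_kwargs={"occurrences_per_length": 1},
                               **silent_params)
        # same category epochs across subjects are identical up to block order
        from neommr.pipeline import preprocess_recording

        avgs = []
        for rec in recs:
            es = preprocess_recording(rec)
            mask = (es.meta.category == "short_e") & es.meta.sensory
            avgs.append(es.data[mask.to_numpy()].mean(axis=0))
        assert np.allclose(avgs[0], avgs[1], atol=1e-4)

    def test_reproducible_given_master_seed(self):
        a = simulate_cohort(2, dimensions=("spectral",), master_seed=9,
                            block_kwargs={"occurrences_per_length": 1})
        b = simulate_cohort(2, dimensions=("spectral",), master_seed=9,
                            block_kwargs={"occurrences_per_length": 1})
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.signal, rb.signal)
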