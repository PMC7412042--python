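"""Takens embedding, Poincaré sectioning, KL basis and full-lead
reconstruction."""

import numpy as np
import pytest

from pecg_ira import (
    EmbeddingConfig,
    PoincareSection,
    compute_kl_basis,
    detect_r_peaks,
    estimate_embedding,
    extract_ensembles,
    mask_to_paper_layout,
    project_beat,
    reconstruct_lead,
    reconstruct_record,
    rsquared,
    takens_embed,
)
from pecg_ira.reconstruct import BeatEnsemble, section_crossings


class TestRSquared:
    def test_identical_sequences(self):
        x = np.array([0.3, -1.2, 0.7])
        assert rsquared(x, x) == 1.0

    def test_zero_reconstruction(self):
        x = np.array([1.0, -2.0, 0.5])
        assert rsquared(np.zeros(3), x) == 0.0

    def test_hand_computed_value(self):
        # 1 - ((1-1)^2 + (1-2)^2) / (1^2 + 2^2) = 1 - 1/5
        assert rsquared(np.array([1.0, 1.0]), np.array([1.0, 2.0])) == pytest.approx(0.8)

    def test_zero_measured_rejected(self):
        with pytest.raises(ValueError):
            rsquared(np.ones(4), np.zeros(4))


class TestTakensEmbedding:
    def test_dimension_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=50)
        emb = takens_embed(x, EmbeddingConfig(1, 3))
        np.testing.assert_array_equal(emb[:, 0], x)

    def test_trajectory_length(self):
        x = np.arange(100.0)
        emb = takens_embed(x, EmbeddingConfig(3, 5))
        assert emb.shape == (90, 3)

    def test_columns_are_shifted_copies(self):
        x = np.random.default_rng(1).normal(size=80)
        emb = takens_embed(x, EmbeddingConfig(4, 3))
        n = len(emb)
        for j in range(4):
            np.testing.assert_array_equal(emb[:, j], x[j * 3 : j * 3 + n])

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            takens_embed(np.ones(5), EmbeddingConfig(3, 5))


class TestEstimateEmbedding:
    def test_sinusoid_needs_two_dimensions(self):
        t = np.arange(2000) / 500.0
        x = np.sin(2 * np.pi * 3.0 * t)
        cfg = estimate_embedding(x)
        assert cfg.dimension == 2

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            estimate_embedding(np.ones(100))

    def test_deterministic_on_fixed_input(self, noisy_record):
        ecg, _ = noisy_record
        x = ecg.leads["II"][:1250]
        assert estimate_embedding(x) == estimate_embedding(x)


class TestPoincareSectioning:
    def test_periodic_signal_yields_equal_segments(self):
        period = 50
        x = np.sin(2 * np.pi * np.arange(500) / period)
        ens = extract_ensembles(x, config=EmbeddingConfig(2, 5))
        assert np.all(ens.original_lengths == period)

    def test_monotone_signal_has_insufficient_crossings(self):
        with pytest.raises(ValueError):
            extract_ensembles(np.linspace(0, 1, 200), config=EmbeddingConfig(2, 5))

    def test_beat_count_on_short_ecg_segment(self):
        # 2.5 s at 72 bpm holds 3 beats -> 2 or 3 whole inter-crossing segments
        from pecg_ira import DipoleParams, ClassPerturbation, generate_dipole_record

        params = DipoleParams(hr_mean=72.0, hr_sd=0.0)
        ecg, _ = generate_dipole_record(
            params, ClassPerturbation("HC", noise_sd=0.0), seed=0
        )
        seg = ecg.leads["II"][: int(2.5 * ecg.fs)]
        ens = extract_ensembles(
            seg, min_separation=int(0.3 * ecg.fs)
        )
        assert ens.n_beats in (2, 3)

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            PoincareSection(np.zeros(3), 0.0)

    def test_negative_direction_crossings(self):
        x = np.cos(2 * np.pi * np.arange(300) / 60)
        traj = takens_embed(x, EmbeddingConfig(2, 5))
        sec = PoincareSection(np.array([1.0, 0.0]), 0.0, "negative")
        idx = section_crossings(traj, sec)
        assert len(idx) == 5
        # exact zeros at crossing samples may land on either side
        assert np.all(np.abs(np.diff(idx) - 60) <= 1)


class TestKLBasis:
    def _ensemble(self, segments):
        segments = np.asarray(segments, float)
        return BeatEnsemble(
            segments=segments,
            original_lengths=np.full(len(segments), segments.shape[1]),
            start_indices=np.arange(len(segments)) * segments.shape[1],
        )

    def test_identical_segments_give_rank_one(self):
        shape = np.sin(np.linspace(0, np.pi, 40))
        basis = compute_kl_basis(self._ensemble([shape, shape, shape]))
        assert basis.order == 1
        phi = basis.eigenfunctions[:, 0]
        cos = abs(phi @ shape) / (np.linalg.norm(phi) * np.linalg.norm(shape))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_rank_two_mixture_matches_svd_oracle(self):
        rng = np.random.default_rng(0)
        u1 = np.sin(np.linspace(0, 2 * np.pi, 60))
        u2 = np.cos(np.linspace(0, 6 * np.pi, 60))
        segs = np.array([a * u1 + b * u2 for a, b in rng.normal(1, 0.5, (8, 2))])
        basis = compute_kl_basis(self._ensemble(segs), threshold=0.999999)
        assert basis.order == 2
        sv = np.linalg.svd(segs / np.sqrt(len(segs)), compute_uv=False)
        np.testing.assert_allclose(
            basis.eigenvalues[: len(sv)], sv**2, atol=1e-8
        )

    def test_parseval_total_variance(self):
        rng = np.random.default_rng(3)
        segs = rng.normal(size=(6, 30))
        basis = compute_kl_basis(self._ensemble(segs))
        total = np.mean(np.sum(segs**2, axis=1))
        assert basis.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_eigenvalues_descending_and_psd(self):
        rng = np.random.default_rng(4)
        basis = compute_kl_basis(self._ensemble(rng.normal(size=(5, 20))))
        vals = basis.eigenvalues
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(vals >= -1e-10 * vals.sum())

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        ens = self._ensemble(rng.normal(size=(10, 40)))
        orders = [
            compute_kl_basis(ens, threshold=th).order
            for th in (0.5, 0.8, 0.95, 0.999)
        ]
        assert orders == sorted(orders)

    def test_projection_orthonormality(self):
        rng = np.random.default_rng(6)
        ens = self._ensemble(rng.normal(size=(6, 25)))
        basis = compute_kl_basis(ens, threshold=0.999999)
        alpha = project_beat(basis.eigenfunctions[:, 0], basis)
        np.testing.assert_allclose(alpha[0], 1.0, atol=1e-10)
        np.testing.assert_allclose(alpha[1:], 0.0, atol=1e-10)

    def test_projection_pythagoras(self):
        rng = np.random.default_rng(7)
        ens = self._ensemble(rng.normal(size=(4, 25)))
        basis = compute_kl_basis(ens, threshold=0.9)
        beat = rng.normal(size=25)
        alpha = project_beat(beat, basis)
        recon = basis.eigenfunctions @ alpha
        residual = np.linalg.norm(beat - recon) ** 2
        assert np.linalg.norm(beat) ** 2 == pytest.approx(
            np.linalg.norm(alpha) ** 2 + residual, rel=1e-10
        )

    def test_length_mismatch(self):
        ens = self._ensemble(np.ones((3, 20)))
        basis = compute_kl_basis(ens)
        with pytest.raises(ValueError):
            project_beat(np.ones(19), basis)


class TestRPeakDetector:
    def test_flat_signal_empty(self):
        assert len(detect_r_peaks(np.zeros(1000), 500.0)) == 0

    def test_polarity_invariant_count(self, clean_record):
        ecg, _ = clean_record
        x = ecg.leads["II"]
        up = detect_r_peaks(x, ecg.fs)
        down = detect_r_peaks(-x, ecg.fs)
        assert len(up) == len(down)

    def test_refractory_period(self, noisy_record):
        ecg, _ = noisy_record
        peaks = detect_r_peaks(ecg.leads["II"], ecg.fs)
        assert np.all(np.diff(peaks) >= 0.2 * ecg.fs)


class TestLeadReconstruction:
    def test_fully_observed_lead_is_identity(self, clean_record):
        ecg, _ = clean_record
        full = ecg.leads["V5"]
        out, _ = reconstruct_lead(full, 0.0, ecg.leads["II"], ecg.fs)
        np.testing.assert_array_equal(out, full[: len(out)])
        assert rsquared(out, full[: len(out)]) == 1.0

    def test_identical_beats_reconstruct_nearly_exactly(self, clean_record):
        # rank-one case: residual only from alignment quantization
        ecg, _ = clean_record
        paper = mask_to_paper_layout(ecg)
        n = int(10 * ecg.fs)
        for lead in ("V5", "aVF", "I"):
            out, _ = reconstruct_lead(
                paper.segments[lead], paper.offsets[lead],
                paper.reference_signal, ecg.fs,
            )
            assert rsquared(out, ecg.leads[lead][:n]) >= 0.99

    def test_observed_window_passes_through_untouched(self, noisy_record):
        ecg, _ = noisy_record
        paper = mask_to_paper_layout(ecg)
        fs = ecg.fs
        out, _ = reconstruct_lead(
            paper.segments["V3"], paper.offsets["V3"], paper.reference_signal, fs
        )
        s0 = int(round(paper.offsets["V3"] * fs))
        np.testing.assert_array_equal(
            out[s0 : s0 + len(paper.segments["V3"])], paper.segments["V3"]
        )

    def test_flat_reference_rejected(self, noisy_record):
        ecg, _ = noisy_record
        paper = mask_to_paper_layout(ecg)
        with pytest.raises(ValueError):
            reconstruct_lead(
                paper.segments["V3"], paper.offsets["V3"],
                np.zeros_like(paper.reference_signal), ecg.fs,
            )

    def test_full_record_median_r2(self, noisy_record):
        ecg, _ = noisy_record
        paper = mask_to_paper_layout(ecg)
        recon, report = reconstruct_record(paper)
        n = int(10 * ecg.fs)
        r2 = [rsquared(recon.leads[l], ecg.leads[l][:n]) for l in recon.leads]
        assert np.median(r2) >= 0.95
        assert all(rep.n_components >= 1 for l, rep in report.leads.items()
                   if l != paper.reference_lead)
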