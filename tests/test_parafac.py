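"""PARAFAC fitting, diagnostics and component typing."""

import numpy as np
import pandas as pd
import pytest

from riverdom.eem import EEMSpectrum
from riverdom.parafac import (EEMStack, PARAFACError, PARAFACModel,
                              classify_components, compute_fmax, corcondia,
                              fit_parafac, match_components,
                              split_half_validate, tucker_congruence)


def congruences(model, truth, stack):
    """Per-mode Tucker congruences of the fit against the planted truth."""
    B = truth.emission_loadings(stack.em)
    C = truth.excitation_loadings(stack.ex)
    perm = match_components(B, model.B, C, model.C)
    em = [tucker_congruence(B[:, f], model.B[:, perm[f]])
          for f in range(model.n_components)]
    ex = [tucker_congruence(C[:, f], model.C[:, perm[f]])
          for f in range(model.n_components)]
    return em, ex


class TestFit:
    def test_noiseless_recovery(self, noiseless_dataset, noiseless_stack):
        _, truth = noiseless_dataset
        model = fit_parafac(noiseless_stack, 3, n_starts=3, seed=0)
        assert model.sse / model.total_ss < 1e-6
        em, ex = congruences(model, truth, noiseless_stack)
        assert min(em) > 0.999
        assert min(ex) > 0.999

    def test_rank1_scores_proportional_to_truth(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0.5, 2.0, size=6)
        ex = np.arange(250.0, 321.0, 10.0)
        em = np.arange(300.0, 421.0, 10.0)
        c = np.exp(-0.5 * ((ex - 280) / 15) ** 2)
        b = np.exp(-0.5 * ((em - 350) / 20) ** 2)
        eems = [EEMSpectrum(ex=ex, em=em, intensity=s * np.outer(c, b),
                            sample_id=f"S{i}")
                for i, s in enumerate(scores)]
        model = fit_parafac(EEMStack(eems), 1, n_starts=2, seed=0)
        ratio = model.A[:, 0] / scores
        assert np.ptp(ratio) / ratio.mean() < 1e-4

    def test_masking_10pct_barely_moves_loadings(self, noiseless_dataset):
        eems, truth = noiseless_dataset
        stack = EEMStack(eems)
        model = fit_parafac(stack, 3, n_starts=3, seed=1)
        rng = np.random.default_rng(11)
        masked = []
        for e in eems:
            e2 = e.copy()
            e2.mask = rng.random(e2.shape) < 0.10
            masked.append(e2)
        mstack = EEMStack(masked)
        mmodel = fit_parafac(mstack, 3, n_starts=3, seed=1)
        em0, ex0 = congruences(model, truth, stack)
        em1, ex1 = congruences(mmodel, truth, mstack)
        assert max(abs(a - b) for a, b in zip(em0 + ex0, em1 + ex1)) < 0.01

    def test_objective_monotone_within_start(self, recovery_dataset):
        eems, _ = recovery_dataset
        model = fit_parafac(EEMStack(eems), 3, n_starts=1, seed=0)
        h = np.array(model.sse_history)
        assert np.all(np.diff(h) <= 1e-9 * h[:-1] + 1e-12)

    def test_rank_exceeding_mode_rejected(self, noiseless_stack):
        with pytest.raises(PARAFACError, match="rank"):
            fit_parafac(noiseless_stack, 1000)

    def test_all_masked_sample_named(self, noiseless_dataset):
        eems, _ = noiseless_dataset
        bad = [e.copy() for e in eems[:4]]
        bad[2].mask[:] = True
        with pytest.raises(PARAFACError, match=bad[2].sample_id):
            EEMStack(bad)

    def test_recovery_median_congruence_over_seeds(self):
        # 1% noise, n=20; median per-mode congruence over 5 seeds
        from riverdom.synthetic import generate_eem_dataset
        mins = []
        for seed in range(5):
            eems, truth = generate_eem_dataset(20, scatter=False, seed=seed)
            stack = EEMStack(eems)
            model = fit_parafac(stack, 3, n_starts=2, seed=seed)
            em, ex = congruences(model, truth, stack)
            mins.append(min(em + ex))
        assert np.median(mins) > 0.95


class TestCorcondia:
    def test_noiseless_true_rank_is_100(self, noiseless_dataset,
                                        noiseless_stack):
        model = fit_parafac(noiseless_stack, 3, n_starts=3, tol=1e-14,
                            max_iter=5000, seed=0)
        assert corcondia(model, noiseless_stack) == pytest.approx(
            100.0, abs=1e-6)

    def test_rank1_on_rank1_data_is_100(self):
        ex = np.arange(250.0, 321.0, 10.0)
        em = np.arange(300.0, 421.0, 10.0)
        c = np.exp(-0.5 * ((ex - 280) / 15) ** 2)
        b = np.exp(-0.5 * ((em - 350) / 20) ** 2)
        eems = [EEMSpectrum(ex=ex, em=em, intensity=s * np.outer(c, b),
                            sample_id=f"S{i}")
                for i, s in enumerate([1.0, 2.0, 3.0])]
        stack = EEMStack(eems)
        model = fit_parafac(stack, 1, n_starts=2, tol=1e-14, seed=0)
        assert corcondia(model, stack) == pytest.approx(100.0, abs=1e-6)

    def test_overfactoring_collapses_core_consistency(self, recovery_dataset):
        eems, _ = recovery_dataset  # SNR 100:1 (1% noise)
        stack = EEMStack(eems)
        model = fit_parafac(stack, 5, n_starts=3, seed=0)
        assert corcondia(model, stack) < 50.0

    def test_invariant_to_joint_rescaling(self, noiseless_stack):
        model = fit_parafac(noiseless_stack, 3, n_starts=2, seed=0)
        base = corcondia(model, noiseless_stack)
        scaled = PARAFACModel(
            n_components=3, A=model.A * 0.5, B=model.B,
            C=model.C * 2.0, ex=model.ex, em=model.em,
            sample_ids=model.sample_ids, sse=model.sse,
            total_ss=model.total_ss, n_iter=model.n_iter)
        assert corcondia(scaled, noiseless_stack) == pytest.approx(base)


class TestSplitHalf:
    def test_duplicated_samples_give_unit_congruence(self, noiseless_dataset):
        eems, _ = noiseless_dataset
        twice = []
        for i, e in enumerate(eems[:6]):
            a, b = e.copy(), e.copy()
            a.sample_id = f"S{i}a"
            b.sample_id = f"S{i}b"
            twice += [a, b]
        stack = EEMStack(twice)
        res = split_half_validate(stack, 3, scheme="alternating", seed=0,
                                  n_starts=2)
        assert res["min_congruence"]["emission"] == pytest.approx(1.0,
                                                                  abs=1e-4)
        assert res["min_congruence"]["excitation"] == pytest.approx(1.0,
                                                                    abs=1e-4)

    def test_noiseless_alternating_validates(self, noiseless_stack):
        res = split_half_validate(noiseless_stack, 3, seed=0, n_starts=2)
        assert res["validated"]
        assert res["min_congruence"]["emission"] > 0.999
        assert res["min_congruence"]["excitation"] > 0.999

    def test_small_stack_rejected(self, noiseless_dataset):
        eems, _ = noiseless_dataset
        with pytest.raises(PARAFACError):
            split_half_validate(EEMStack(eems[:3]), 2)


class TestFmax:
    def make_model(self, A, B, C, ex, em):
        return PARAFACModel(n_components=A.shape[1], A=A, B=B, C=C,
                            ex=np.asarray(ex, float),
                            em=np.asarray(em, float),
                            sample_ids=[f"S{i}" for i in range(A.shape[0])],
                            sse=0.0, total_ss=1.0, n_iter=1)

    def test_fmax_is_product_of_score_and_loading_maxima(self):
        # un-normalised score 2, em max 0.5, ex max 0.1 -> Fmax 0.1
        A = np.array([[2.0]])
        B = np.array([[0.25], [0.5], [0.1]])
        C = np.array([[0.1], [0.05]])
        model = self.make_model(A, B, C, [250, 300], [300, 350, 400])
        fmax, _ = compute_fmax(model)
        assert fmax.iloc[0, 0] == pytest.approx(0.1)

    def test_percent_abundance_75_25(self):
        A = np.array([[3.0, 1.0]])
        B = np.array([[1.0, 0.2], [0.2, 1.0]])
        C = np.array([[1.0, 0.3], [0.3, 1.0]])
        model = self.make_model(A, B, C, [250, 300], [300, 400])
        _, percent = compute_fmax(model)
        assert sorted(percent.iloc[0].tolist()) == pytest.approx([25.0, 75.0])

    def test_percent_rows_sum_to_100(self, noiseless_stack):
        model = fit_parafac(noiseless_stack, 3, n_starts=2, seed=0)
        _, percent = compute_fmax(model)
        np.testing.assert_allclose(percent.sum(axis=1), 100.0, atol=1e-6)


class TestClassify:
    def gaussian_model(self, peaks):
        """peaks: list of (ex centers, em center)."""
        ex = np.arange(220.0, 401.0, 5.0)
        em = np.arange(250.0, 521.0, 5.0)
        Bs, Cs = [], []
        for ex_centers, em_center in peaks:
            Cs.append(sum(np.exp(-0.5 * ((ex - c) / 12) ** 2)
                          for c in ex_centers))
            Bs.append(np.exp(-0.5 * ((em - em_center) / 18) ** 2))
        B = np.column_stack(Bs)
        C = np.column_stack(Cs)
        A = np.ones((2, len(peaks)))
        return PARAFACModel(n_components=len(peaks), A=A, B=B, C=C,
                            ex=ex, em=em, sample_ids=["S0", "S1"],
                            sse=0.0, total_ss=1.0, n_iter=1)

    def test_tyrosine_like_peak_is_protein(self):
        model = self.gaussian_model([([270], 275)])
        table = classify_components(model)
        assert table.iloc[0]["class"] == "protein-like"
        assert table.iloc[0]["em_peak"] == 275.0

    def test_dual_excitation_humic_component(self):
        model = self.gaussian_model([([245, 365], 455)])
        row = classify_components(model).iloc[0]
        assert row["class"] == "humic-like"
        assert len(row["ex_peaks"]) == 2
        assert row["ex_peaks"] == pytest.approx([245.0, 365.0])

    def test_threshold_boundary_is_humic(self):
        model = self.gaussian_model([([300], 380)])
        assert classify_components(model).iloc[0]["class"] == "humic-like"

    def test_flat_loading_unresolved(self):
        model = self.gaussian_model([([270], 275)])
        model.B[:, 0] = 1.0
        assert classify_components(model).iloc[0]["class"] == "unresolved"
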