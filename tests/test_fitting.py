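"""Single-curve fits, multi-curve fitting, Det index, and summaries."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protonrbe import (
    DomainError,
    LETResponseParams,
    LQParams,
    NoiseSpec,
    PhotonReference,
    PoissonSurvivalParams,
    classify_outliers,
    det_index,
    fit_photon_reference,
    fit_single,
    generate_dataset,
    mcf,
    mcf_single_variable,
    regress_bbeta_on_alphax,
    summarize_across_cell_lines,
)
from protonrbe.published import CELL_LINE_FITS
from protonrbe.survival import SurvivalDataset, SurvivalPoint, eval_sf_lq

from conftest import make_family

DOSES = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


def _noise_free(params, **kw):
    return generate_dataset(params, DOSES, NoiseSpec(sigma=0.0), **kw)


class TestFitSingle:
    def test_recovers_poisson_truth(self):
        ds = _noise_free(PoissonSurvivalParams(1.5, 0.8, 5))
        res = fit_single(ds, model="poisson", m=5)
        assert res.params.alpha == pytest.approx(1.5, abs=1e-3)
        assert res.params.beta == pytest.approx(0.8, abs=1e-3)
        assert res.rmspe <= 1e-6

    def test_recovers_lq_truth(self):
        truth = LQParams(0.3, 0.03)
        pts = [SurvivalPoint(d, eval_sf_lq(d, truth)) for d in DOSES]
        ds = SurvivalDataset("X", "p", "pristine", "proton", 5.0, pts)
        res = fit_single(ds, model="lq")
        assert res.params.alpha_lq == pytest.approx(0.3, abs=1e-3)
        assert res.params.beta_lq == pytest.approx(0.03, abs=1e-3)

    def test_too_few_points_rejected(self):
        pts = [SurvivalPoint(1.0, 0.8), SurvivalPoint(2.0, 0.5)]
        ds = SurvivalDataset("X", "p", "pristine", "proton", 5.0, pts)
        with pytest.raises(DomainError, match="3 non-zero-dose points"):
            fit_single(ds)

    def test_unknown_model_rejected(self):
        ds = _noise_free(PoissonSurvivalParams(1.5, 0.8, 5))
        with pytest.raises(ValueError, match="unknown model"):
            fit_single(ds, model="lqq")


class TestFitPhotonReference:
    def test_noise_free_recovery(self):
        ds = _noise_free(PoissonSurvivalParams(2.34, 0.75, 5), cell_line="AGlike",
                         beam_type="photon", radiation="photon")
        ref = fit_photon_reference([ds])
        assert ref.alpha_x == pytest.approx(2.34, abs=1e-3)
        assert ref.beta_x == pytest.approx(0.75, abs=1e-3)

    def test_noisy_replicates_recovery(self):
        truth = PoissonSurvivalParams(2.0, 0.8, 5)
        rng = np.random.default_rng(3)
        ds = [generate_dataset(truth, DOSES, NoiseSpec(sigma=0.05), cell_line="X",
                               beam_type="photon", radiation="photon", rng=rng)
              for _ in range(2)]
        ref = fit_photon_reference(ds)
        assert ref.alpha_x == pytest.approx(2.0, abs=0.1)
        assert ref.beta_x == pytest.approx(0.8, abs=0.1)

    def test_empty_collection_rejected(self):
        with pytest.raises(DomainError, match="pseudo-photon"):
            fit_photon_reference([])


class TestMCF:
    def test_noise_free_recovery(self, photon_ref, truth_response, noise_free_family):
        res = mcf(noise_free_family, photon_ref, diagnostics=False)
        lr = res.let_response
        assert lr.a_alpha == pytest.approx(truth_response.a_alpha, abs=1e-2)
        assert lr.b_alpha == pytest.approx(truth_response.b_alpha, abs=1e-2)
        assert lr.a_beta == pytest.approx(truth_response.a_beta, abs=1e-2)
        assert lr.b_beta == pytest.approx(truth_response.b_beta, abs=1e-2)
        assert res.objective <= 1e-5

    def test_noisy_recovery(self, photon_ref, truth_response):
        fam = make_family(photon_ref, sigma=0.05, seed=7)
        lr = mcf(fam, photon_ref, diagnostics=False).let_response
        assert lr.a_alpha == pytest.approx(truth_response.a_alpha, abs=0.05)
        assert lr.a_beta == pytest.approx(truth_response.a_beta, abs=0.05)
        assert lr.b_alpha == pytest.approx(truth_response.b_alpha, abs=0.005)
        assert lr.b_beta == pytest.approx(truth_response.b_beta, abs=0.005)

    def test_constrained_fit_never_beats_best_fit(self, photon_ref):
        fam = make_family(photon_ref, sigma=0.05, seed=2)
        res = mcf(fam, photon_ref)
        for diag in res.per_dataset:
            assert diag.rmspe_mcf >= diag.rmspe_best - 1e-9

    def test_single_let_rejected(self, photon_ref):
        fam = make_family(photon_ref, lets=(10.0,))
        with pytest.raises(DomainError, match="distinct LETs"):
            mcf(fam, photon_ref)

    def test_objective_invariant_to_ordering(self, photon_ref):
        fam = make_family(photon_ref, sigma=0.05, seed=5)
        res1 = mcf(fam, photon_ref, diagnostics=False)
        shuffled = list(fam)
        random.Random(0).shuffle(shuffled)
        shuffled = [
            SurvivalDataset(d.cell_line, d.publication, d.beam_type, d.radiation,
                            d.let_kev_um,
                            list(reversed(d.points)))
            for d in shuffled
        ]
        res2 = mcf(shuffled, photon_ref, diagnostics=False)
        assert res2.objective == pytest.approx(res1.objective, abs=1e-7)


class TestDetIndex:
    @pytest.mark.parametrize("r_mcf,r_best,expected",
                             [(0.10, 0.05, 1.0), (0.20, 0.03, 2.5), (0.02, 0.01, 1 / 3)])
    def test_arithmetic(self, r_mcf, r_best, expected):
        assert det_index(r_mcf, r_best) == pytest.approx(expected, rel=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            det_index(-0.1, 0.05)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(r=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0))
    def test_homogeneous_in_numerator(self, r, b):
        assert det_index(2 * r, b) == pytest.approx(2 * det_index(r, b), rel=1e-12)


class TestClassifyOutliers:
    def _result_with_dets(self, photon_ref, dets):
        from protonrbe.fitting import DatasetDiagnostics, MCFResult
        per = [DatasetDiagnostics(f"d{i}", 10.0 * i, det * 0.05, 0.0, det)
               for i, det in enumerate(dets)]
        return MCFResult("X", LETResponseParams(1.12, 0.0, 0.99, 0.0),
                         photon_ref, per, sum(p.rmspe_mcf for p in per))

    def test_threshold_bands(self, photon_ref):
        res = classify_outliers(self._result_with_dets(photon_ref, [1.0, 1.8, 4.5]))
        assert [d.flag for d in res.per_dataset] == ["ok", "acceptable", "outlier"]

    def test_all_small_dets_are_ok(self, photon_ref):
        res = classify_outliers(self._result_with_dets(photon_ref, [0.5, 1.0, 1.25]))
        assert all(d.flag == "ok" for d in res.per_dataset)


class TestSingleVariableMCF:
    def test_noise_free_recovery(self, photon_ref):
        truth = LETResponseParams(1.12, 0.0019, 0.99, 0.020)
        fam = make_family(photon_ref, sigma=0.0, let_response=truth)
        res = mcf_single_variable(fam, photon_ref, 1.12, 0.0019, 0.99,
                                  diagnostics=False)
        assert res.b_beta_hash == pytest.approx(0.020, abs=1e-3)

    def test_single_let_rejected(self, photon_ref):
        fam = make_family(photon_ref, lets=(10.0,))
        with pytest.raises(DomainError, match="distinct LETs"):
            mcf_single_variable(fam, photon_ref, 1.12, 0.0019, 0.99)


class TestCrossCellSummaries:
    def test_published_coefficient_averages(self):
        responses = [LETResponseParams(f.a_alpha, f.b_alpha, f.a_beta, f.b_beta)
                     for f in CELL_LINE_FITS]
        s = summarize_across_cell_lines(responses)
        assert round(s.mean_a_alpha, 2) == 1.12
        assert round(s.sd_a_alpha, 2) == 0.04
        assert float(f"{s.mean_b_alpha:.2g}") == 0.0019
        assert float(f"{s.sd_b_alpha:.1g}") == 0.0008
        assert round(s.mean_a_beta, 2) == 0.99
        assert round(s.sd_a_beta, 2) == 0.03

    def test_identical_inputs_have_zero_sd(self):
        r = LETResponseParams(1.1, 0.002, 1.0, 0.02)
        s = summarize_across_cell_lines([r, r, r])
        assert s.sd_a_alpha == s.sd_b_alpha == s.sd_a_beta == 0.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(DomainError):
            summarize_across_cell_lines([LETResponseParams(1.1, 0.002, 1.0, 0.02)])


class TestRegressBbetaOnAlphax:
    def test_published_pairs_give_slope(self):
        pairs = [(f.alpha_x, f.b_beta_hash) for f in CELL_LINE_FITS]
        assert float(f"{regress_bbeta_on_alphax(pairs):.2g}") == 0.013

    def test_single_pair_is_ratio(self):
        assert regress_bbeta_on_alphax([(1.0, 0.02)]) == pytest.approx(0.02)

    def test_collinear_pairs_exact(self):
        pairs = [(x, 0.011 * x) for x in (0.5, 1.0, 2.0, 3.5)]
        assert regress_bbeta_on_alphax(pairs) == pytest.approx(0.011, abs=1e-12)

    def test_all_zero_x_rejected(self):
        with pytest.raises(DomainError):
            regress_bbeta_on_alphax([(0.0, 0.01), (0.0, 0.02)])
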