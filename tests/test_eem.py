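"""EEM correction, PARAFAC fitting, validation, matching, phenol index."""

import numpy as np
import pandas as pd
import pytest

from sedch4 import SynthConfig, gen_eems
from sedch4.eem import (
    DEFAULT_REFERENCE,
    ComponentAssignment,
    EEMCube,
    ParafacModel,
    ReferenceSpectra,
    excise_scatter,
    inner_filter_correct,
    match_components,
    phenol_index,
    split_half_validate,
    tucker_congruence,
)


def _bare_cube(data, doc=None):
    n = data.shape[0]
    abs_nm = np.arange(250.0, 601.0, 2.0)
    return EEMCube(
        sample_ids=[f"s{i}" for i in range(n)],
        ex_nm=np.arange(250, 451, 5, dtype=float),
        em_nm=np.arange(300, 601, 2, dtype=float),
        data=data,
        absorbance_nm=abs_nm,
        absorbance=np.zeros((n, len(abs_nm))),
        doc_mg_l=doc,
    )


class TestInnerFilter:
    def test_zero_absorbance_is_identity(self):
        rng = np.random.default_rng(0)
        cube = _bare_cube(rng.uniform(0, 1, size=(2, 41, 151)))
        corrected, flagged = inner_filter_correct(cube)
        np.testing.assert_array_equal(corrected.data, cube.data)
        assert flagged == []

    def test_constant_absorbance_closed_form(self):
        cube = _bare_cube(np.ones((1, 41, 151)))
        cube.absorbance[:] = 0.3
        corrected, _ = inner_filter_correct(cube)
        np.testing.assert_allclose(corrected.data, 10**0.3, rtol=1e-12)
        assert corrected.data[0, 0, 0] == pytest.approx(1.9953, abs=1e-4)

    def test_roundtrip_undoes_generator_attenuation(self):
        cfg_att = SynthConfig(seed=9, n_replicates=2, eem_noise=0.0, eem_inner_filter=True)
        cfg_raw = cfg_att.replace(eem_inner_filter=False)
        attenuated, _ = gen_eems(cfg_att)
        truth, _ = gen_eems(cfg_raw)
        corrected, _ = inner_filter_correct(attenuated)
        np.testing.assert_allclose(corrected.data, truth.data, rtol=1e-8, atol=1e-10)

    def test_high_absorbance_flagged(self):
        cube = _bare_cube(np.ones((1, 41, 151)))
        cube.absorbance[:] = 2.0
        _, flagged = inner_filter_correct(cube)
        assert flagged == ["s0"]

    def test_missing_absorbance_rejected(self):
        cube = _bare_cube(np.ones((1, 41, 151)))
        cube.absorbance[0, 5] = np.nan
        with pytest.raises(ValueError, match="missing absorbance"):
            inner_filter_correct(cube)


class TestParafacFit:
    def test_noiseless_rank_one_is_exact(self):
        ref = ReferenceSpectra(labels=("x",), ex_peak_nm=(310.0,), em_peak_nm=(414.0,))
        ex, em = ref.profiles(np.arange(250, 451, 5.0), np.arange(300, 601, 2.0))
        scores = np.array([1.0, 2.0, 0.5, 3.0])
        data = np.einsum("i,j,k->ijk", scores, ex[:, 0], em[:, 0])
        res = ParafacModel(_bare_cube(data), 1).fit(n_starts=2, seed=0)
        assert res.explained_variance >= 1 - 1e-8

    def test_objective_monotone_nonincreasing(self, eem_cube_small):
        cube, _ = eem_cube_small
        res = ParafacModel(cube, 5).fit(n_starts=1, seed=3, max_iter=300, refine_max_iter=300)
        h = res.loss_history
        assert np.all(np.diff(h) <= 1e-9 * h[:-1] + 1e-9)

    def test_sample_permutation_equivariance(self):
        ref = ReferenceSpectra(labels=("a", "b"), ex_peak_nm=(310.0, 345.0),
                               em_peak_nm=(414.0, 462.0))
        ex, em = ref.profiles(np.arange(250, 451, 5.0), np.arange(300, 601, 2.0))
        rng = np.random.default_rng(5)
        scores = rng.uniform(0.5, 2.0, size=(6, 2))
        data = np.einsum("if,jf,kf->ijk", scores, ex, em)
        perm = np.array([3, 1, 5, 0, 4, 2])
        r1 = ParafacModel(_bare_cube(data), 2).fit(n_starts=2, seed=0)
        r2 = ParafacModel(_bare_cube(data[perm]), 2).fit(n_starts=2, seed=0)
        np.testing.assert_allclose(r1.scores[perm], r2.scores, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(r1.ex_loadings, r2.ex_loadings, rtol=1e-5, atol=1e-8)

    def test_loadings_unit_max_and_reconstruction_invariant(self, eem_cube_small):
        cube, _ = eem_cube_small
        res = ParafacModel(cube, 5).fit(n_starts=2, seed=1, max_iter=500, refine_max_iter=500)
        np.testing.assert_allclose(res.ex_loadings.max(axis=0), 1.0, rtol=1e-12)
        np.testing.assert_allclose(res.em_loadings.max(axis=0), 1.0, rtol=1e-12)
        recon = res.reconstruction()
        rss = np.sum((cube.data - recon) ** 2)
        assert 1 - rss / np.sum(cube.data**2) == pytest.approx(
            res.explained_variance, abs=1e-9
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            ParafacModel(_bare_cube(np.ones((4, 41, 151))), 5)

    def test_parameter_recovery_at_low_noise(self, eem_cube_small):
        # matched congruence vs true spectra >= 0.98; peaks within one grid step
        cube, _ = eem_cube_small
        res = ParafacModel(cube, 5).fit(n_starts=4, seed=2)
        assignment = match_components(res)
        assert np.all(assignment.congruence >= 0.98)
        ref = DEFAULT_REFERENCE
        for f, label in enumerate(assignment.labels):
            j = ref.labels.index(label)
            peaks = assignment.peaks.iloc[f]
            assert abs(peaks["ex_peak_nm"] - ref.ex_peak_nm[j]) <= 5.0
            assert abs(peaks["em_peak_nm"] - ref.em_peak_nm[j]) <= 2.0

    def test_scatter_excision_masks_rayleigh_band(self, eem_cube_noiseless):
        cube, _ = eem_cube_noiseless
        masked = excise_scatter(cube, width_nm=10.0)
        band = np.abs(cube.em_nm[None, :] - cube.ex_nm[:, None]) <= 10.0
        assert np.all(np.isnan(masked.data[:, band]))
        assert not np.any(np.isnan(masked.data[:, ~band]))
        # masked fit still recovers the structure off the band
        res = ParafacModel(masked, 5).fit(n_starts=2, seed=0, max_iter=400, refine_max_iter=400)
        assert res.explained_variance >= 0.98


class TestSplitHalf:
    def test_noiseless_cube_congruence_near_one(self, eem_cube_noiseless):
        cube, _ = eem_cube_noiseless
        report = split_half_validate(cube, 5, n_splits=1, seed=0, n_starts=2)
        assert report.passed
        assert np.min(report.congruence) >= 0.995

    def test_five_component_cube_passes_at_1pct_noise(self, eem_cube_small):
        cube, _ = eem_cube_small
        report = split_half_validate(
            cube, 5, n_splits=2, congruence_threshold=0.95, seed=1, n_starts=2
        )
        assert report.passed

    def test_overfactoring_fails_threshold(self, eem_cube_small):
        cube, _ = eem_cube_small
        report = split_half_validate(
            cube, 6, n_splits=2, congruence_threshold=0.95, seed=2, n_starts=2
        )
        assert not report.passed


class TestMatching:
    def test_exact_reference_profiles_identity_assignment(self):
        # loadings equal to the reference profiles must map to their own
        # labels with congruence 1 and the reference peak positions
        from sedch4.eem import ParafacResults

        ref = DEFAULT_REFERENCE
        ex, em = ref.profiles(np.arange(250, 451, 5.0), np.arange(300, 601, 2.0))
        rng = np.random.default_rng(1)
        scores = rng.uniform(1, 2, size=(10, 5))
        data = np.einsum("if,jf,kf->ijk", scores, ex, em)
        model = ParafacModel(_bare_cube(data), 5)
        res = ParafacResults(
            model=model, scores=scores, ex_loadings=ex, em_loadings=em,
            explained_variance=1.0, converged=True, n_iter=0,
            loss_history=np.array([0.0]), start_explained_variances=np.array([1.0]),
        )
        assignment = match_components(res)
        assert assignment.labels == list(ref.labels)
        np.testing.assert_allclose(assignment.congruence, 1.0, atol=1e-12)
        f = assignment.component_for("phenol-leachate")
        assert assignment.peaks.iloc[f]["ex_peak_nm"] == 275.0
        assert assignment.peaks.iloc[f]["em_peak_nm"] == 318.0

    def test_single_component_always_assigned(self):
        ref = ReferenceSpectra(labels=("only",), ex_peak_nm=(310.0,), em_peak_nm=(414.0,))
        ex, em = ref.profiles(np.arange(250, 451, 5.0), np.arange(300, 601, 2.0))
        data = np.einsum("i,j,k->ijk", np.array([1.0, 2.0]), ex[:, 0], em[:, 0])
        res = ParafacModel(_bare_cube(data), 1).fit(n_starts=1, seed=0)
        assignment = match_components(res, ref)
        assert assignment.labels == ["only"]

    def test_tucker_congruence_of_orthogonal_and_identical(self):
        a = np.array([1.0, 0.0])
        assert tucker_congruence(a, a) == pytest.approx(1.0)
        assert tucker_congruence(a, np.array([0.0, 1.0])) == 0.0
        assert tucker_congruence(a, np.zeros(2)) == 0.0


class TestPhenolIndex:
    def _results_with_scores(self, scores, doc):
        scores = np.asarray(scores, float)
        ref = DEFAULT_REFERENCE
        ex, em = ref.profiles(np.arange(250, 451, 5.0), np.arange(300, 601, 2.0))
        data = np.einsum("if,jf,kf->ijk", scores, ex, em)
        cube = _bare_cube(data, doc=np.asarray(doc, float))
        res = ParafacModel(cube, 5)
        # construct results directly from the known factors (no fitting)
        from sedch4.eem import ParafacResults

        results = ParafacResults(
            model=res, scores=scores, ex_loadings=ex, em_loadings=em,
            explained_variance=1.0, converged=True, n_iter=0,
            loss_history=np.array([0.0]), start_explained_variances=np.array([1.0]),
        )
        assignment = ComponentAssignment(
            labels=list(ref.labels), congruence=np.ones(5),
            peaks=results.peak_wavelengths(),
        )
        return results, cube, assignment

    def test_all_fluorescence_in_phenol_component(self):
        scores = np.zeros((10, 5))
        scores[:, 4] = 3.0  # phenol-leachate column
        res, cube, assign = self._results_with_scores(scores, doc=np.full(10, 10.0))
        out = phenol_index(res, cube, assign)
        np.testing.assert_allclose(out["phenol_index"], 10.0)

    def test_zero_phenol_score_gives_zero_index(self):
        scores = np.ones((10, 5))
        scores[:, 4] = 0.0
        res, cube, assign = self._results_with_scores(scores, doc=np.full(10, 25.0))
        out = phenol_index(res, cube, assign)
        np.testing.assert_allclose(out["phenol_index"], 0.0)

    def test_all_zero_scores_defined_as_zero(self):
        res, cube, assign = self._results_with_scores(np.zeros((10, 5)), np.full(10, 5.0))
        out = phenol_index(res, cube, assign)
        np.testing.assert_allclose(out["phenol_index"], 0.0)

    def test_linear_in_doc(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0.5, 2.0, size=(10, 5))
        res, cube, assign = self._results_with_scores(scores, np.full(10, 10.0))
        res2, cube2, assign2 = self._results_with_scores(scores, np.full(10, 5.0))
        i1 = phenol_index(res, cube, assign)["phenol_index"]
        i2 = phenol_index(res2, cube2, assign2)["phenol_index"]
        np.testing.assert_allclose(i1, 2 * i2)
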