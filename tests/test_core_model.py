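"""Standardization, eigendecomposition, component selection and orientation."""

import numpy as np
import pandas as pd
import pytest

from mgfs import (
    MGFSError,
    MissingValueError,
    PhenotypeRecord,
    ReferenceCohort,
    SelectionRule,
    ZeroVarianceError,
    align_component_signs,
    fit_normative_model,
    loading_report,
    select_components,
    standardize_cohort,
)
from mgfs.synthetic import TABLE_CORRELATIONS, TABLE_EIGENVALUES

from conftest import random_cohort


def make_cohort(matrix, names=None):
    matrix = np.asarray(matrix, dtype=float)
    names = tuple(names or (f"v{j}" for j in range(matrix.shape[1])))
    frame = pd.DataFrame(matrix, columns=list(names))
    frame.insert(0, "subject_id", [f"S{i}" for i in range(len(matrix))])
    return ReferenceCohort(frame, names)


class TestStandardize:
    def test_two_point_symmetry(self):
        z, means, sds = standardize_cohort(make_cohort([[0.0], [2.0]]))
        assert means[0] == 1.0
        assert sds[0] == pytest.approx(np.sqrt(2))
        assert z[:, 0] == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_location_invariance(self, rng):
        cohort = random_cohort(rng, n=30, p=4)
        shifted = make_cohort(cohort.values() + 10.0, cohort.variable_order)
        z0, m0, _ = standardize_cohort(cohort)
        z1, m1, _ = standardize_cohort(shifted)
        np.testing.assert_allclose(z1, z0, atol=1e-10)
        np.testing.assert_allclose(m1, m0 + 10.0, atol=1e-10)

    def test_columns_are_zscores(self, reference_cohort):
        z, _, _ = standardize_cohort(reference_cohort)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_generator_marginals_recovered(self):
        # oracle: direct sample statistics of a large seeded cohort
        from mgfs import SyntheticSpec, simulate_cohort

        spec = SyntheticSpec(n=10000, seed=7)
        cohort = simulate_cohort(spec)
        x = cohort.values()
        se_mean = spec.marginal_sds / np.sqrt(spec.n)
        assert np.all(np.abs(x.mean(axis=0) - spec.marginal_means) < 3 * se_mean)
        se_sd = spec.marginal_sds / np.sqrt(2 * (spec.n - 1))
        assert np.all(np.abs(x.std(axis=0, ddof=1) - spec.marginal_sds) < 3 * se_sd)

    def test_zero_variance_names_variable(self):
        cohort = make_cohort([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]], ("flat", "ok"))
        with pytest.raises(ZeroVarianceError, match="flat"):
            standardize_cohort(cohort)

    def test_missing_value_names_subject_and_variable(self):
        cohort = make_cohort([[1.0, 2.0], [np.nan, 3.0], [2.0, 4.0]], ("a", "b"))
        with pytest.raises(MissingValueError, match=r"S1.*'a'"):
            standardize_cohort(cohort)


class TestSelectComponents:
    @pytest.mark.parametrize("eigenvalues, p, expected_k", [
        ([3.49, 1.65, 1.39, 0.55, 0.5, 0.45, 0.4, 0.32, 0.25], 9, 3),
        ([1.0] * 9, 9, 9),                                # boundary kept
        ([6.9, 0.5, 0.5, 0.5, 0.4, 0.3, 0.3, 0.3, 0.2, 0.1], 10, 2),  # 69% -> extend
        ([5.0, 3.0, 1.0], 9, 3),
    ])
    def test_retention_rule(self, eigenvalues, p, expected_k):
        assert select_components(np.array(eigenvalues), p) == expected_k

    def test_exclusive_boundary_configurable(self):
        ev = np.array([1.0] * 9)
        k = select_components(ev, 9, SelectionRule(inclusive=False, cumulative_cutoff=0.5))
        assert k == 5  # falls through to the cumulative rule

    def test_non_descending_rejected(self):
        with pytest.raises(MGFSError):
            select_components(np.array([1.0, 2.0, 0.5]), 9)


class TestSignAlignment:
    def test_flip_and_idempotence(self):
        rot = np.array([[-0.6, 0.1], [0.8, 0.3], [0.0, -0.9]])
        names = ("a", "b", "c")
        aligned, anchors = align_component_signs(rot, names, [("a", +1), ("c", -1)])
        assert aligned[0, 0] > 0 and aligned[2, 1] < 0
        again, _ = align_component_signs(aligned, names, [("a", +1), ("c", -1)])
        np.testing.assert_array_equal(again, aligned)

    def test_already_aligned_unchanged(self):
        rot = np.array([[0.6], [0.8]])
        aligned, _ = align_component_signs(rot, ("a", "b"), [("a", +1)])
        np.testing.assert_array_equal(aligned, rot)

    def test_zero_anchor_correlation_errors(self):
        rot = np.array([[0.0], [1.0]])
        with pytest.raises(MGFSError, match="orientation undefined"):
            align_component_signs(rot, ("a", "b"), [("a", +1)])

    def test_reference_fit_matches_all_printed_signs(self, reference_model):
        loadings = loading_report(reference_model).correlations
        assert np.all(np.sign(loadings) == np.sign(TABLE_CORRELATIONS))


class TestFit:
    def test_two_variable_closed_form(self, rng):
        # 2x2 correlation matrix with correlation r has eigenvalues 1 +/- r
        r = 0.5
        cov = np.array([[1.0, r], [r, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=4000)
        cohort = make_cohort(x)
        model = fit_normative_model(cohort, SelectionRule(cumulative_cutoff=1.0))
        r_hat = np.corrcoef(x.T)[0, 1]
        np.testing.assert_allclose(model.all_eigenvalues, [1 + r_hat, 1 - r_hat],
                                   atol=1e-10)
        np.testing.assert_allclose(np.abs(model.rotation[:, 0]),
                                   [1 / np.sqrt(2)] * 2, atol=1e-10)

    def test_independent_variables_give_unit_eigenvalues(self, rng):
        x = rng.normal(size=(20000, 5))
        model = fit_normative_model(make_cohort(x))
        np.testing.assert_allclose(model.all_eigenvalues, 1.0, atol=0.06)

    def test_reference_recovers_printed_eigenvalues(self, reference_model):
        np.testing.assert_allclose(reference_model.eigenvalues, TABLE_EIGENVALUES,
                                   atol=0.15)

    def test_trace_conservation_and_orthonormality(self, reference_model):
        m = reference_model
        assert m.all_eigenvalues.sum() == pytest.approx(m.p, abs=1e-8)
        np.testing.assert_allclose(m.rotation.T @ m.rotation, np.eye(m.k), atol=1e-8)

    def test_too_small_cohort_rejected(self, rng):
        with pytest.raises(MGFSError, match="too small"):
            fit_normative_model(random_cohort(rng, n=4, p=5))

    def test_oracle_equivalence_random_cohorts(self, rng):
        """Fitted eigenstructure equals brute-force eigendecomposition of the
        explicitly computed correlation matrix, up to anchored signs."""
        for _ in range(100):
            cohort = random_cohort(rng, n=50, p=5)
            model = fit_normative_model(cohort, SelectionRule(cumulative_cutoff=1.0))
            corr = pd.DataFrame(cohort.values()).corr().to_numpy()
            evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
            np.testing.assert_allclose(model.all_eigenvalues, evals, atol=1e-8)
            for comp in range(model.k):
                u = model.rotation[:, comp]
                lam = model.eigenvalues[comp]
                np.testing.assert_allclose(corr @ u, lam * u, atol=1e-8)

    def test_matches_sklearn_pca(self, reference_cohort):
        """Independent cross-check against scikit-learn's PCA on z-scores."""
        from sklearn.decomposition import PCA

        z, _, _ = standardize_cohort(reference_cohort)
        pca = PCA(n_components=3).fit(z)  # explained_variance_ uses n-1
        model = fit_normative_model(reference_cohort)
        np.testing.assert_allclose(model.eigenvalues, pca.explained_variance_,
                                   rtol=1e-8)
        for comp in range(3):
            cos = abs(pca.components_[comp] @ model.rotation[:, comp])
            assert cos == pytest.approx(1.0, abs=1e-8)


class TestLoadingReport:
    def test_unit_eigenvalue_identity(self, rng):
        from mgfs.core_model import NormativeModel

        rot = np.array([[0.6], [0.8]])
        model = NormativeModel(
            variable_order=("a", "b"), means=np.zeros(2), sds=np.ones(2),
            rotation=rot, eigenvalues=np.array([1.0]),
            all_eigenvalues=np.array([1.0, 1.0]),
            selection_rule={}, anchor_signs=(("a", 1),))
        report = loading_report(model)
        assert report.correlations[0, 0] == pytest.approx(0.6)

    def test_unit_norm_identity(self, reference_model):
        # sum_j c_jk^2 / lambda_k = 1 restates eigenvector unit norm
        report = loading_report(reference_model)
        norms = (report.correlations ** 2).sum(axis=0) / reference_model.eigenvalues
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_reference_relevance_pattern(self, reference_model):
        """|c| > 0.5 in exactly the nine printed bold cells: five on PC1
        (three VABS, IQ, ADI-R Socialization), three on PC2, one on PC3."""
        flags = loading_report(reference_model).relevant_flags
        expected = np.abs(TABLE_CORRELATIONS) > 0.5
        assert flags.sum() == 9
        np.testing.assert_array_equal(flags, expected)


def test_printed_loading_table_is_internally_consistent():
    """The printed correlations and eigenvalues satisfy the unit-norm
    identity sum_j c_jk^2 = lambda_k to within rounding (0.99-1.01)."""
    ratios = (TABLE_CORRELATIONS ** 2).sum(axis=0) / TABLE_EIGENVALUES
    assert np.all((ratios > 0.99) & (ratios < 1.01))


def test_phenotype_record_validation():
    base = dict(subject_id="X", vabs_communication=50, vabs_socialization=51,
                vabs_dls=54, adi_social=28, adi_communication=7, adi_rrb=5,
                total_iq=54, cbcl_internalizing=72, cbcl_externalizing=56)
    rec = PhenotypeRecord(**base)
    assert rec.as_array()[0] == 50.0
    with pytest.raises(MissingValueError, match="total_iq"):
        PhenotypeRecord(**{**base, "total_iq": float("nan")})
    with pytest.raises(MGFSError, match="adi_rrb"):
        PhenotypeRecord(**{**base, "adi_rrb": -1})
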