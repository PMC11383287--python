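"""Standardized PCA of initial states: eigen-equivalence, projection
semantics, loadings, and recovery of planted structure."""

import numpy as np
import pytest

from lineagesim import fit_pca, initial_state_matrix, project, top_loadings
from lineagesim.heterogeneity import (StateMatrix, component_correlations,
                                      inverse_transform)


def random_matrix(n=10, p=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3.0, size=p)
    return StateMatrix(values=X, row_ids=[f"1.{i}" for i in range(n)],
                       columns=[f"sp{j}" for j in range(p)])


class TestFitPca:
    def test_matches_bruteforce_eigendecomposition(self):
        """Oracle: eigh of the hand-computed standardized covariance."""
        m = random_matrix(10, 5, seed=1)
        transform, scores = fit_pca(m)
        Z = (m.values - m.values.mean(0)) / m.values.std(0)
        cov = Z.T @ Z / Z.shape[0]
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for i in range(transform.n_components):
            got = transform.components[i]
            want = v[:, i]
            # eigenvectors match up to sign
            assert min(np.abs(got - want).max(),
                       np.abs(got + want).max()) < 1e-8
        np.testing.assert_allclose(
            transform.explained_variance_ratio, w / w.sum(), atol=1e-8)

    def test_single_varying_column_takes_all_loading(self):
        X = np.ones((6, 3))
        X[:, 1] = np.arange(6.0)
        m = StateMatrix(values=X, row_ids=list("abcdef"),
                        columns=["c0", "c1", "c2"])
        transform, scores = fit_pca(m)
        assert transform.dropped_columns == ["c0", "c2"]
        assert abs(transform.components[0][0]) == pytest.approx(1.0)
        assert top_loadings(transform, component=1, k=1).species.iloc[0] == "c1"

    def test_planted_direction_recovered(self):
        """Two clusters separated along a known axis align with PC1."""
        rng = np.random.default_rng(4)
        p = 6
        direction = rng.normal(size=p)
        direction /= np.linalg.norm(direction)
        X = rng.normal(size=(200, p)) * 0.05
        X[100:] += 3.0 * direction
        X += 10.0  # keep concentrations positive-ish
        m = StateMatrix(values=X, row_ids=[str(i) for i in range(200)],
                        columns=[f"sp{j}" for j in range(p)])
        transform, _ = fit_pca(m)
        # compare in the standardized metric the PCA actually sees
        scaled = direction / transform.std
        scaled /= np.linalg.norm(scaled)
        cos = abs(float(transform.components[0] @ scaled))
        assert cos > 0.99

    def test_variance_ordering_and_total(self):
        transform, _ = fit_pca(random_matrix(30, 6, seed=2))
        evr = transform.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        transform, _ = fit_pca(random_matrix(12, 4, seed=3))
        for comp in transform.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_degenerate_inputs_rejected(self):
        X = np.ones((5, 4))
        m = StateMatrix(values=X, row_ids=list("abcde"),
                        columns=list("wxyz"))
        with pytest.raises(ValueError, match="constant"):
            fit_pca(m)

    def test_reconstruction_with_all_components(self):
        m = random_matrix(15, 5, seed=5)
        transform, scores = fit_pca(m)
        Z = (m.values - transform.mean) / transform.std
        np.testing.assert_allclose(inverse_transform(transform, scores), Z,
                                   atol=1e-8)


class TestProject:
    def test_idempotent_on_control(self):
        m = random_matrix(20, 5, seed=6)
        transform, scores = fit_pca(m)
        np.testing.assert_allclose(project(transform, m), scores, atol=1e-10)

    def test_row_of_control_means_scores_zero(self):
        m = random_matrix(20, 5, seed=7)
        transform, _ = fit_pca(m)
        row = StateMatrix(values=transform.mean[None, :], row_ids=["mean"],
                          columns=transform.columns)
        np.testing.assert_allclose(project(transform, row), 0.0, atol=1e-10)

    def test_shifted_copy_shifts_scores_linearly(self):
        """Linear-map oracle: scores of X + d are scores(X) + (d/std) W^T."""
        m = random_matrix(20, 5, seed=8)
        transform, scores = fit_pca(m)
        shift = np.linspace(0.5, 2.5, 5)
        shifted = StateMatrix(values=m.values + shift, row_ids=m.row_ids,
                              columns=m.columns)
        expected = scores + (shift / transform.std) @ transform.components.T
        np.testing.assert_allclose(project(transform, shifted), expected,
                                   atol=1e-10)

    def test_column_mismatch_reported(self):
        m = random_matrix(10, 5, seed=9)
        transform, _ = fit_pca(m)
        other = StateMatrix(values=m.values[:, :3], row_ids=m.row_ids,
                            columns=m.columns[:3])
        with pytest.raises(ValueError, match="missing columns"):
            project(transform, other)


class TestTopLoadings:
    def test_defaults_are_pc2_top20(self):
        import inspect

        sig = inspect.signature(top_loadings)
        assert sig.parameters["component"].default == 2
        assert sig.parameters["k"].default == 20

    def test_ranking_invariant_under_sign_flip(self):
        m = random_matrix(15, 6, seed=10)
        transform, _ = fit_pca(m)
        ranked = top_loadings(transform, component=2, k=6)
        transform.components[1] *= -1.0
        flipped = top_loadings(transform, component=2, k=6)
        assert list(ranked.species) == list(flipped.species)

    def test_k_truncated_with_warning(self):
        transform, _ = fit_pca(random_matrix(15, 4, seed=11))
        with pytest.warns(UserWarning, match="truncating"):
            out = top_loadings(transform, component=1, k=20)
        assert len(out) == 4

    def test_component_out_of_range(self):
        transform, _ = fit_pca(random_matrix(8, 3, seed=12))
        with pytest.raises(ValueError, match="outside fitted range"):
            top_loadings(transform, component=9)


class TestInitialStateMatrix:
    def test_dimensions_and_alignment(self, control_run):
        matrix, counts = initial_state_matrix(control_run)
        n_species = len(control_run.config["species"])
        assert matrix.values.shape == (control_run.n0, n_species)
        assert len(counts) == control_run.n0
        # row order follows mother index order
        assert matrix.row_ids == [f"1.{i}" for i in range(control_run.n0)]
        rec = control_run.record("1.3")
        np.testing.assert_array_equal(matrix.values[3], rec.initial_state)

    def test_response_is_progeny_division_count(self, control_run):
        from lineagesim import progeny_division_count

        _, counts = initial_state_matrix(control_run)
        assert counts[5] == progeny_division_count(control_run, "1.5")


class TestParameterRecovery:
    def test_division_count_component_loads_on_erk_branch(self, control_run):
        """Cycle speed is driven through the ERK cascade, so the component
        that stratifies division counts should load on ERK-branch species."""
        matrix, counts = initial_state_matrix(control_run)
        transform, scores = fit_pca(matrix)
        corr = component_correlations(scores, counts)
        best = int(np.argmax(np.abs(corr)))
        assert abs(corr[best]) > 0.5
        top = set(top_loadings(transform, component=best + 1, k=10).species)
        erk_branch = {"ERK", "pERK", "MEK", "pMEK", "RasGDP", "RasGTP"}
        assert len(top & erk_branch) >= 2
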