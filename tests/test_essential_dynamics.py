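import numpy as np
import pytest

from allodyn import (
    SyntheticSpec,
    extreme_interpolation,
    fit_modes,
    generate_trajectory,
    project,
    reference_projection,
    select_representatives,
    variance_fractions,
)
from conftest import make_frame_set


def covariance_oracle(coords):
    """Explicit double-loop ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩ on flattened coordinates."""
    flat = coords.reshape(coords.shape[0], -1)
    mean = flat.mean(axis=0)
    n = flat.shape[1]
    cov = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            cov[i, j] = cov[j, i] = np.mean((flat[:, i] - mean[i]) * (flat[:, j] - mean[j]))
    return cov


def planted_frame_set(spec):
    ens, truth = generate_trajectory(spec)
    return select_representatives(ens, "CA", truth.domain_map), truth


class TestFitModes:
    def test_static_trajectory_all_zero_eigenvalues(self):
        frame = np.random.default_rng(0).uniform(-10, 10, size=(6, 3))
        rfs = make_frame_set(np.repeat(frame[None], 5, axis=0))
        modes = fit_modes(rfs, skip_initial_ps=0)
        np.testing.assert_allclose(modes.eigvals, 0.0, atol=1e-18)

    def test_single_planted_mode_recovered(self):
        spec = SyntheticSpec(n_res_per_domain=10, n_frames=200, noise_sigma=0.0,
                             mode_amplitudes={"open_close": 4.0}, seed=1)
        rfs, truth = planted_frame_set(spec)
        modes = fit_modes(rfs, skip_initial_ps=0, superpose_frames=False)
        cosine = abs(modes.eigvecs[:, 0] @ truth.mode_vectors["open_close"])
        assert cosine >= 0.99
        assert variance_fractions(modes, 1) >= 0.999
        assert modes.eigvals[0] == pytest.approx(4.0**2 / 2, rel=1e-9)

    def test_isotropic_noise_spectrum_flat(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(5000, 4, 3))
        modes = fit_modes(make_frame_set(coords), skip_initial_ps=0,
                          superpose_frames=False)
        assert modes.eigvals[0] / modes.eigvals[-1] < 2.0

    def test_covariance_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=0.5, size=(40, 5, 3)) + rng.uniform(-5, 5, (1, 5, 3))
        modes = fit_modes(make_frame_set(coords), skip_initial_ps=0,
                          superpose_frames=False)
        cov = covariance_oracle(coords)
        rebuilt = modes.eigvecs @ np.diag(modes.eigvals) @ modes.eigvecs.T
        np.testing.assert_allclose(rebuilt, cov, atol=1e-10)
        # orthonormality
        np.testing.assert_allclose(modes.eigvecs.T @ modes.eigvecs,
                                   np.eye(15), atol=1e-8)

    def test_equilibration_window_skipped(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(100, 4, 3))
        rfs = make_frame_set(coords, frame_interval=200.0)
        modes = fit_modes(rfs, skip_initial_ps=10_000.0)
        assert modes.n_frames_used == 50  # t >= 10 ns, i.e. frames 50..99

    def test_short_trajectory_falls_back_with_warning(self):
        rng = np.random.default_rng(5)
        rfs = make_frame_set(rng.normal(size=(10, 4, 3)), frame_interval=2.0)
        with pytest.warns(UserWarning, match="full trajectory"):
            modes = fit_modes(rfs, skip_initial_ps=10_000.0)
        assert modes.n_frames_used == 10

    def test_mode_recovery_degrades_gracefully_with_noise(self):
        a = 4.0
        spec = SyntheticSpec(n_res_per_domain=10, n_frames=500, noise_sigma=a / 4,
                             mode_amplitudes={"open_close": a}, seed=6)
        rfs, truth = planted_frame_set(spec)
        modes = fit_modes(rfs, skip_initial_ps=0)
        cosine = abs(modes.eigvecs[:, 0] @ truth.mode_vectors["open_close"])
        assert cosine >= 0.9


class TestVarianceFractions:
    def test_limits(self):
        rng = np.random.default_rng(7)
        modes = fit_modes(make_frame_set(rng.normal(size=(20, 4, 3))), skip_initial_ps=0)
        assert variance_fractions(modes, 0) == 0.0
        assert variance_fractions(modes, modes.eigvals.size) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            variance_fractions(modes, modes.eigvals.size + 1)

    def test_two_planted_modes_four_to_one(self):
        a = 4.0
        spec = SyntheticSpec(n_res_per_domain=10, n_frames=240, noise_sigma=0.0,
                             mode_amplitudes={"open_close": a, "twist": a / 2}, seed=8)
        rfs, _ = planted_frame_set(spec)
        modes = fit_modes(rfs, skip_initial_ps=0, superpose_frames=False)
        assert variance_fractions(modes, 1) == pytest.approx(0.8, abs=1e-9)


class TestProjection:
    def test_score_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(60, 5, 3)) * rng.uniform(0.2, 2.0, size=(1, 5, 1))
        rfs = make_frame_set(coords)
        modes = fit_modes(rfs, skip_initial_ps=0)
        proj = project(rfs, modes, mode_indices=range(5))
        var = proj.scores.var(axis=0)
        np.testing.assert_allclose(var, modes.eigvals[:5], rtol=1e-6)

    def test_mean_structure_projects_to_zero(self):
        rng = np.random.default_rng(10)
        rfs = make_frame_set(rng.normal(size=(30, 5, 3)))
        modes = fit_modes(rfs, skip_initial_ps=0)
        proj = project(modes.mean_coords[None], modes)
        np.testing.assert_allclose(proj.scores, 0.0, atol=1e-9)

    def test_planted_sinusoid_traced(self):
        a = 3.0
        spec = SyntheticSpec(n_res_per_domain=10, n_frames=200, noise_sigma=0.05,
                             mode_amplitudes={"twist": a}, seed=11)
        rfs, truth = planted_frame_set(spec)
        modes = fit_modes(rfs, skip_initial_ps=0, superpose_frames=False)
        proj = project(rfs, modes, mode_indices=[0])
        t = np.arange(200)
        expected = a * np.sin(2 * np.pi * 3 * t / 200)  # twist runs 3 cycles
        sign = np.sign(proj.scores[:, 0] @ expected)
        np.testing.assert_allclose(sign * proj.scores[:, 0], expected, atol=0.35)

    def test_reconstruction_with_all_modes(self):
        rng = np.random.default_rng(12)
        rfs = make_frame_set(rng.normal(size=(25, 4, 3)))
        modes = fit_modes(rfs, skip_initial_ps=0, superpose_frames=False)
        proj = project(rfs, modes, mode_indices=range(12))
        rebuilt = modes.mean_coords.ravel() + proj.scores @ modes.eigvecs.T
        np.testing.assert_allclose(rebuilt.reshape(rfs.coords.shape), rfs.coords,
                                   atol=1e-10)

    def test_atom_mismatch_errors(self):
        rng = np.random.default_rng(13)
        modes = fit_modes(make_frame_set(rng.normal(size=(10, 4, 3))), skip_initial_ps=0)
        with pytest.raises(ValueError):
            project(rng.normal(size=(3, 5, 3)), modes)


class TestExtremeInterpolation:
    def _modes_scores(self):
        spec = SyntheticSpec(n_res_per_domain=10, n_frames=120, noise_sigma=0.0,
                             mode_amplitudes={"open_close": 4.0}, seed=14)
        rfs, truth = planted_frame_set(spec)
        modes = fit_modes(rfs, skip_initial_ps=0, superpose_frames=False)
        proj = project(rfs, modes, mode_indices=[0])
        return modes, proj.scores[:, 0], truth

    def test_two_steps_are_the_extremes(self):
        modes, scores, _ = self._modes_scores()
        structures, _ = extreme_interpolation(modes, 0, scores, n_steps=2)
        v = modes.eigvecs[:, 0].reshape(-1, 3)
        np.testing.assert_allclose(structures[0],
                                   modes.mean_coords + scores.min() * v, atol=1e-9)
        np.testing.assert_allclose(structures[1],
                                   modes.mean_coords + scores.max() * v, atol=1e-9)

    def test_midpoint_near_mean_for_symmetric_scores(self):
        modes, scores, _ = self._modes_scores()
        structures, _ = extreme_interpolation(modes, 0, scores, n_steps=3)
        assert np.abs(structures[1] - modes.mean_coords).max() < 0.15

    def test_arrows_parallel_to_planted_mode(self):
        modes, scores, truth = self._modes_scores()
        _, arrows = extreme_interpolation(modes, 0, scores, n_steps=5)
        flat = arrows.ravel()
        cosine = abs(flat @ truth.mode_vectors["open_close"]) / np.linalg.norm(flat)
        assert cosine >= 0.99

    def test_zero_variance_mode_rejected(self):
        modes, scores, _ = self._modes_scores()
        with pytest.raises(ValueError):
            extreme_interpolation(modes, 50, np.zeros(10), n_steps=4)


class TestReferenceProjection:
    def _state_ensembles(self, offsets, n_frames=80, noise=0.2, seed=15):
        refs = []
        for k, b in enumerate(offsets):
            spec = SyntheticSpec(n_res_per_domain=10, n_frames=n_frames,
                                 noise_sigma=noise, mode_amplitudes={},
                                 mode_bias={"open_close": b}, seed=seed + k)
            rfs, _ = planted_frame_set(spec)
            refs.append((f"state{k}", rfs))
        return refs

    def test_query_overlaps_matching_state(self):
        refs = self._state_ensembles([-6.0, -2.0, 2.0, 6.0])
        query_spec = SyntheticSpec(n_res_per_domain=10, n_frames=60, noise_sigma=0.2,
                                   mode_amplitudes={}, mode_bias={"open_close": 2.0},
                                   seed=99)
        query, _ = planted_frame_set(query_spec)
        _, proj = reference_projection(refs, query, k=2, superpose_frames=False)
        centroids = {lab: proj.scores[proj.labels == lab, 0].mean()
                     for lab in np.unique(proj.labels)}
        spreads = {lab: proj.scores[proj.labels == lab, 0].std()
                   for lab in np.unique(proj.labels)}
        d_to_match = abs(centroids["query"] - centroids["state2"])
        assert d_to_match < spreads["state2"] * 2
        for other in ("state0", "state1", "state3"):
            assert d_to_match < abs(centroids["query"] - centroids[other])

    def test_four_states_separate_monotonically_on_pc1(self):
        refs = self._state_ensembles([-6.0, -2.0, 2.0, 6.0])
        query = refs[0][1]
        _, proj = reference_projection(refs, query, k=1, superpose_frames=False)
        assert proj.scores.shape[1] == 1  # k=1 -> one score column
        centroids = [proj.scores[proj.labels == f"state{k}", 0].mean() for k in range(4)]
        diffs = np.diff(centroids)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_residue_mismatch_rejected(self):
        refs = self._state_ensembles([0.0])
        small_spec = SyntheticSpec(n_res_per_domain=5, n_frames=10, mode_amplitudes={})
        small, _ = planted_frame_set(small_spec)
        with pytest.raises(ValueError):
            reference_projection(refs, small)
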