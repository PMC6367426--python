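import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allodyn import (
    SyntheticSpec,
    cp_matrix,
    delta_cp,
    fast_comm_fraction,
    generate_trajectory,
    neighbor_baseline,
    select_representatives,
)
from allodyn.comm_propensity import CPMatrix
from conftest import make_frame_set


def eq3_oracle(coords):
    """Direct double-loop evaluation of ⟨(d_ij − d̄_ij)²⟩ per pair."""
    f, n, _ = coords.shape
    cp = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
            cp[i, j] = cp[j, i] = np.mean((d - d.mean()) ** 2)
    return cp


class TestCpMatrix:
    def test_rigid_body_trajectory_null(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-15, 15, size=(12, 3))
        frames = []
        for t in range(25):
            r = Rotation.random(random_state=t).as_matrix()
            frames.append(base @ r + rng.normal(size=3) * 20)
        cpm = cp_matrix(make_frame_set(np.stack(frames)))
        assert cpm.cp.max() <= 1e-10

    def test_alternating_pair_gives_amplitude_squared(self):
        d0, a = 8.0, 1.3
        coords = np.zeros((6, 2, 3))
        coords[::2, 1, 0] = d0 + a
        coords[1::2, 1, 0] = d0 - a
        cpm = cp_matrix(make_frame_set(coords))
        assert cpm.cp[0, 1] == pytest.approx(a**2, rel=1e-12)
        assert cpm.d_mean[0, 1] == pytest.approx(d0)

    def test_static_trajectory_zero_with_frame0_distances(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(-10, 10, size=(8, 3))
        cpm = cp_matrix(make_frame_set(np.repeat(frame[None], 4, axis=0)))
        np.testing.assert_allclose(cpm.cp, 0.0, atol=1e-12)
        from scipy.spatial.distance import squareform, pdist

        np.testing.assert_allclose(cpm.d_mean, squareform(pdist(frame)), atol=1e-9)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(scale=3.0, size=(30, 7, 3)) + rng.uniform(-20, 20, size=(1, 7, 3))
        cpm = cp_matrix(make_frame_set(coords))
        np.testing.assert_allclose(cpm.cp, eq3_oracle(coords), atol=1e-8)

    def test_requires_ca_scheme_and_two_frames(self):
        coords = np.zeros((1, 5, 3))
        with pytest.raises(ValueError):
            cp_matrix(make_frame_set(coords))
        with pytest.raises(ValueError, match="CA"):
            cp_matrix(make_frame_set(np.zeros((3, 5, 3)), scheme="CB_or_CA_for_GLY"))


class TestDeltaCp:
    def test_identity_and_antisymmetry(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(10, 6, 3))
        cpm = cp_matrix(make_frame_set(coords))
        np.testing.assert_allclose(delta_cp(cpm, cpm), 0.0)
        other = cp_matrix(make_frame_set(coords * 2))
        np.testing.assert_allclose(delta_cp(cpm, other), -delta_cp(other, cpm))

    def test_noisier_bound_everywhere_negative(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(-20, 20, size=(8, 3))
        quiet = base[None] + rng.normal(0, 0.1, size=(60, 8, 3))
        loud = base[None] + rng.normal(0, 1.0, size=(60, 8, 3))
        d = delta_cp(cp_matrix(make_frame_set(quiet)), cp_matrix(make_frame_set(loud)))
        off = ~np.eye(8, dtype=bool)
        assert np.all(d[off] < 0)

    def test_quieted_domain_shows_positive_block(self):
        """Halving a domain's noise in 'bound' raises its communication efficiency."""
        rng = np.random.default_rng(5)
        base = rng.uniform(-20, 20, size=(12, 3))
        sigma_free = np.full(12, 0.8)
        sigma_bound = sigma_free.copy()
        sigma_bound[:4] = 0.4  # the "domain" that quiets down
        free = base[None] + rng.normal(size=(400, 12, 3)) * sigma_free[None, :, None]
        bound = base[None] + rng.normal(size=(400, 12, 3)) * sigma_bound[None, :, None]
        d = delta_cp(cp_matrix(make_frame_set(free)), cp_matrix(make_frame_set(bound)))
        block = d[np.ix_(range(4), range(4))][~np.eye(4, dtype=bool)]
        assert block.mean() > 0
        # direct-formula recomputation agrees
        d_oracle = eq3_oracle(free) - eq3_oracle(bound)
        np.testing.assert_allclose(d, d_oracle, atol=1e-8)

    def test_shape_mismatch(self):
        a = cp_matrix(make_frame_set(np.random.default_rng(0).normal(size=(4, 5, 3))))
        b = cp_matrix(make_frame_set(np.random.default_rng(0).normal(size=(4, 6, 3))))
        with pytest.raises(ValueError):
            delta_cp(a, b)


class TestNeighborBaseline:
    def test_static_zero_and_uniform_value(self):
        static = cp_matrix(make_frame_set(np.repeat(
            np.random.default_rng(6).uniform(-9, 9, size=(1, 8, 3)), 3, axis=0)))
        assert neighbor_baseline(static) == pytest.approx(0.0, abs=1e-12)
        c = 0.37
        cp = np.full((8, 8), c)
        np.fill_diagonal(cp, 0.0)
        cpm = CPMatrix(cp=cp, d_mean=np.ones((8, 8)), n_frames_used=2)
        assert neighbor_baseline(cpm) == pytest.approx(c)

    def test_hand_built_six_residue_enumeration(self):
        rng = np.random.default_rng(7)
        cp = rng.random((6, 6))
        cp = (cp + cp.T) / 2
        np.fill_diagonal(cp, 0.0)
        cpm = CPMatrix(cp=cp, d_mean=np.ones((6, 6)), n_frames_used=2)
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6) if j - i <= 4]
        expected = np.mean([cp[i, j] for i, j in pairs])
        assert neighbor_baseline(cpm, window=4) == pytest.approx(expected)
        exact4 = np.mean([cp[i, j] for i, j in pairs if j - i == 4])
        assert neighbor_baseline(cpm, window=4, exact=True) == pytest.approx(exact4)

    def test_interchain_pairs_excluded(self):
        cp = np.ones((6, 6))
        np.fill_diagonal(cp, 0.0)
        cp[2, 3] = cp[3, 2] = 100.0  # straddles the chain break below
        import pandas as pd

        meta = pd.DataFrame({"chain_id": ["A"] * 3 + ["B"] * 3})
        cpm = CPMatrix(cp=cp, d_mean=np.ones((6, 6)), n_frames_used=2, residue_meta=meta)
        assert neighbor_baseline(cpm, window=4) == pytest.approx(1.0)

    def test_window_validation(self):
        cpm = CPMatrix(cp=np.zeros((5, 5)), d_mean=np.ones((5, 5)), n_frames_used=2)
        with pytest.raises(ValueError):
            neighbor_baseline(cpm, window=0)


class TestFastCommunication:
    def _cpm(self, cp, d):
        return CPMatrix(cp=cp, d_mean=d, n_frames_used=2)

    def test_all_above_threshold_zero(self):
        n = 6
        cp = np.full((n, n), 5.0)
        np.fill_diagonal(cp, 0.0)
        prof = fast_comm_fraction(self._cpm(cp, np.full((n, n), 100.0)), threshold=1.0)
        np.testing.assert_allclose(prof.fraction, 0.0)

    def test_floor_beyond_diameter_zero(self):
        n = 6
        cp = np.zeros((n, n))
        prof = fast_comm_fraction(self._cpm(cp, np.full((n, n), 50.0)), threshold=1.0,
                                  dist_floor=80.0)
        np.testing.assert_allclose(prof.fraction, 0.0)

    def test_brute_force_count(self):
        rng = np.random.default_rng(8)
        n = 12
        cp = rng.random((n, n)) * 2
        cp = (cp + cp.T) / 2
        np.fill_diagonal(cp, 0.0)
        d = rng.uniform(40, 120, size=(n, n))
        d = (d + d.T) / 2
        thr, floor = 0.9, 80.0
        prof = fast_comm_fraction(self._cpm(cp, d), threshold=thr, dist_floor=floor)
        for i in range(n):
            count = sum(1 for j in range(n)
                        if j != i and d[i, j] > floor and cp[i, j] <= thr)
            assert prof.fraction[i] == pytest.approx(count / (n - 1))

    def test_auto_threshold_is_neighbor_baseline(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(30, 10, 3)) * 0.5 + rng.uniform(-60, 60, (1, 10, 3))
        cpm = cp_matrix(make_frame_set(coords))
        prof = fast_comm_fraction(cpm)
        assert prof.threshold == pytest.approx(neighbor_baseline(cpm))

    def test_far_partner_coupling_detected_in_dimer(self):
        """NTD tips >80 Å apart that move coherently show nonzero fast fractions."""
        spec = SyntheticSpec(n_res_per_domain=10, n_frames=300, noise_sigma=0.15,
                             mode_amplitudes={"twist": 2.0}, seed=10)
        ens, truth = generate_trajectory(spec)
        rfs = select_representatives(ens, "CA", truth.domain_map)
        cpm = cp_matrix(rfs)
        prof = fast_comm_fraction(cpm, dist_floor=60.0)
        ntd = np.concatenate([rfs.indices("A", "NTD"), rfs.indices("B", "NTD")])
        assert (cpm.d_mean > 60.0).any()
        assert prof.fraction[ntd].max() > 0


class TestHingeBlockStructure:
    def test_cross_hinge_pairs_fluctuate_much_more_than_intra_domain(self):
        spec = SyntheticSpec(n_res_per_domain=10, n_frames=400, noise_sigma=0.1, seed=3)
        ens, truth = generate_trajectory(spec)
        rfs = select_representatives(ens, "CA", truth.domain_map)
        cpm = cp_matrix(rfs)
        na, nb = rfs.indices("A", "NTD"), rfs.indices("B", "NTD")
        ma = rfs.indices("A", "M")
        cross = cpm.cp[np.ix_(na, nb)].mean()
        triu = np.triu_indices(len(ma), 1)
        intra = cpm.cp[np.ix_(ma, ma)][triu].mean()
        assert cross / intra > 5
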