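"""NMFSC: Hoyer sparseness measure, the sparseness projection operator,
and the alternating multiplicative/projected-subtractive factorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from compcode.nmfsc import (
    NMFSC,
    hoyer_sparseness,
    multiplicative_v_update,
    project_columns_sparseness,
    project_sparseness,
)


class TestHoyerSparseness:
    def test_uniform_is_zero(self):
        assert hoyer_sparseness(np.ones(8)) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_is_one(self):
        assert hoyer_sparseness(np.eye(5)[2]) == pytest.approx(1.0)

    def test_closed_form_half_active(self):
        # (sqrt(4) - 2/sqrt(2)) / (sqrt(4) - 1) = 2 - sqrt(2)
        v = np.array([1.0, 1.0, 0.0, 0.0])
        assert hoyer_sparseness(v) == pytest.approx(2 - np.sqrt(2), abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            hoyer_sparseness(np.zeros(4))


def _brute_force_projection(v, s, n_starts=40):
    """Independent oracle: numerically minimize ||u - v|| subject to
    u >= 0, ||u||_2 = ||v||_2 and Hoyer sparseness s (i.e. an L1
    equality), from many random starts."""
    n = v.size
    l2 = np.linalg.norm(v)
    l1 = l2 * (np.sqrt(n) - s * (np.sqrt(n) - 1))
    best, best_val = None, np.inf
    rng = np.random.default_rng(7)
    starts = [v.copy()] + [rng.uniform(0, 1, n) for _ in range(n_starts - 1)]
    cons = [
        {"type": "eq", "fun": lambda u: np.sum(u * u) - l2**2},
        {"type": "eq", "fun": lambda u: np.sum(u) - l1},
    ]
    for u0 in starts:
        res = minimize(
            lambda u: np.sum((u - v) ** 2),
            u0,
            method="SLSQP",
            bounds=[(0, None)] * n,
            constraints=cons,
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if res.success and res.fun < best_val:
            best, best_val = res.x, res.fun
    return best, best_val


class TestProjection:
    def test_fixed_point_unchanged(self, rng):
        v = project_sparseness(rng.uniform(0, 1, 9), 0.6)
        again = project_sparseness(v, 0.6)
        assert np.abs(again - v).max() < 1e-9

    def test_limit_case_one_hot(self, rng):
        v = rng.uniform(0.1, 1, 7)
        u = project_sparseness(v, 1.0)
        assert np.count_nonzero(u) == 1
        assert u.argmax() == v.argmax()
        assert np.linalg.norm(u) == pytest.approx(np.linalg.norm(v))

    @pytest.mark.parametrize("s", [0.3, 0.55, 0.7, 0.9])
    def test_matches_brute_force_minimizer(self, s, rng):
        v = rng.uniform(0, 1, 5)
        ours = project_sparseness(v, s)
        oracle, oracle_val = _brute_force_projection(v, s)
        assert oracle is not None
        ours_val = np.sum((ours - v) ** 2)
        assert ours_val <= oracle_val + 1e-4
        assert np.abs(ours - oracle).max() < 1e-3

    @given(
        st.lists(st.floats(-1, 2), min_size=3, max_size=12),
        st.floats(0.05, 0.99),
    )
    @settings(max_examples=120, deadline=None)
    def test_always_feasible(self, vals, s):
        """The projection output simultaneously satisfies non-negativity,
        the L2 norm of the input, and the target sparseness."""
        v = np.asarray(vals)
        if np.linalg.norm(v) < 1e-6:
            return
        u = project_sparseness(v, s)
        assert (u >= 0).all()
        assert np.linalg.norm(u) == pytest.approx(np.linalg.norm(v), rel=1e-6)
        assert hoyer_sparseness(u) == pytest.approx(s, abs=1e-6)

    def test_batched_matches_single(self, rng):
        M = rng.uniform(0, 1, (9, 30))
        P = project_columns_sparseness(M, 0.8)
        for j in range(0, 30, 7):
            single = project_sparseness(M[:, j], 0.8)
            assert np.allclose(P[:, j], single, atol=1e-10)

    def test_zero_columns_stay_zero(self):
        M = np.zeros((5, 3))
        M[:, 1] = [1, 2, 0, 0, 1]
        P = project_columns_sparseness(M, 0.7)
        assert not P[:, 0].any() and not P[:, 2].any()
        assert P[:, 1].any()


class TestFactorization:
    def test_multiplicative_update_fixed_point(self, rng):
        V0 = rng.uniform(0.1, 1, (12, 4))
        Y0 = rng.uniform(0.1, 1, (4, 20))
        X = V0 @ Y0
        V1 = multiplicative_v_update(V0, Y0, X, eps=0.0)
        assert np.abs(V1 - V0).max() < 1e-12

    def test_error_monotone_without_projection(self, rng):
        """The Euclidean multiplicative basis update never increases the
        reconstruction error on random problems."""
        for _ in range(100):
            X = rng.uniform(0, 1, (20, 30))
            V = rng.uniform(0.1, 1, (20, 6))
            Y = rng.uniform(0.1, 1, (6, 30))
            prev = np.sum((V @ Y - X) ** 2)
            for _ in range(5):
                V = multiplicative_v_update(V, Y, X)
                err = np.sum((V @ Y - X) ** 2)
                assert err <= prev + 1e-9
                prev = err

    def test_fit_enforces_code_sparseness(self, rng):
        X = rng.uniform(0, 1, (80, 24))
        model = NMFSC(n_components=6, sparseness_y=0.85, max_epochs=60, seed=3)
        model.fit(X)
        codes = model.encode(X)
        for row in codes:
            if row.any():
                assert hoyer_sparseness(row) == pytest.approx(0.85, abs=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            NMFSC(n_components=3).fit(np.array([[1.0, -0.5], [0.2, 0.1]]))

    def test_encode_zero_input_gives_zero_code(self, rng):
        X = rng.uniform(0, 1, (40, 12))
        model = NMFSC(n_components=4, sparseness_y=0.8, max_epochs=40, seed=1)
        model.fit(X)
        code = model.encode(np.zeros((1, 12)))
        assert not code.any()

    def test_encode_deterministic(self, rng):
        X = rng.uniform(0, 1, (40, 12))
        model = NMFSC(n_components=4, sparseness_y=0.8, max_epochs=40, seed=1)
        model.fit(X)
        assert np.array_equal(model.encode(X[:10]), model.encode(X[:10]))

    def test_basis_column_input_activates_its_unit(self, rng):
        """Feeding one basis vector concentrates the code on that unit."""
        X = rng.uniform(0, 1, (150, 20))
        model = NMFSC(n_components=8, sparseness_y=0.8, max_epochs=80, seed=2)
        model.fit(X)
        codes = model.encode(model.V_.T)  # each basis column as an input
        hits = sum(codes[k].argmax() == k for k in range(8))
        assert hits >= 7

    def test_nonnegativity_preserved(self, rng):
        X = rng.uniform(0, 1, (60, 16))
        model = NMFSC(n_components=5, sparseness_y=0.75, max_epochs=50, seed=4)
        model.fit(X)
        assert (model.V_ >= 0).all()
        assert (model.encode(X) >= 0).all()

    def test_save_load_roundtrip(self, tmp_path, rng):
        X = rng.uniform(0, 1, (40, 12))
        model = NMFSC(n_components=4, sparseness_y=0.8, max_epochs=30, seed=1)
        model.fit(X)
        model.save(tmp_path / "m.npz")
        back = NMFSC.load(tmp_path / "m.npz")
        assert np.array_equal(back.encode(X[:5]), model.encode(X[:5]))
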