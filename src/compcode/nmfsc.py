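"""Non-negative matrix factorization with a sparseness constraint (NMFSC).

The data matrix X (inputs in columns) is factorized as X ~ V Y with
V, Y >= 0.  The basis V is updated with the multiplicative Euclidean
rule V <- V * (X Y^T) / (V Y Y^T); the code Y is updated with a
subtractive gradient step Y <- Y - mu V^T (V Y - X) followed by a
column-wise projection that forces every code vector to a target Hoyer
sparseness while preserving its L2 norm.  The projection is the
competition mechanism: it trades activity between units so that only a
few stay active per input.

Sparseness is Hoyer's L1/L2 measure

    s(v) = (sqrt(n) - |v|_1 / |v|_2) / (sqrt(n) - 1)

which is 0 for a uniform vector and 1 for a one-hot vector.  Only the
code Y is constrained; the basis V is left unconstrained (its columns
are simply kept at unit L2 norm).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-9


def hoyer_sparseness(v: np.ndarray) -> float:
    """Hoyer L1/L2 sparseness of a non-negative vector, in [0, 1].

    Raises ``ValueError`` for the zero vector (undefined).
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise ValueError("sparseness is undefined for the zero vector")
    l1 = np.abs(v).sum()
    return float((np.sqrt(n) - l1 / l2) / (np.sqrt(n) - 1.0))


def _target_l1(l2: np.ndarray, s: float, n: int) -> np.ndarray:
    """L1 norm giving Hoyer sparseness ``s`` at L2 norm ``l2``."""
    return l2 * (np.sqrt(n) - s * (np.sqrt(n) - 1.0))


def project_columns_sparseness(M: np.ndarray, s: float) -> np.ndarray:
    """Project every column of ``M`` to Hoyer sparseness ``s``, keeping
    each column's L2 norm.

    Vectorized form of Hoyer's alternating projection: shift onto the
    target-L1 hyperplane, step to the L2 sphere along the line from the
    uniform point, and zero out negative coordinates until the iterate
    is feasible.  Each pass permanently zeroes at least one coordinate
    per infeasible column, so at most ``n`` passes are needed.
    All-zero columns are returned as zeros.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"target sparseness must be in [0, 1], got {s}")
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    l2 = np.linalg.norm(M, axis=0)
    live = l2 > 0
    if not np.any(live):
        return np.zeros_like(M)
    l1 = _target_l1(l2, s, n)

    v = M + (l1 - M.sum(axis=0)) / n
    zeroed = np.zeros(M.shape, dtype=bool)
    for _ in range(n + 1):
        n_active = n - zeroed.sum(axis=0)
        mid = np.divide(l1, n_active, out=np.zeros_like(l1), where=n_active > 0)
        m = np.where(zeroed, 0.0, mid[None, :])
        w = np.where(zeroed, 0.0, v - m)
        a = np.einsum("ij,ij->j", w, w)
        # degenerate columns (v uniform over active coords, w = 0): the
        # projection is non-unique; break the tie with a fixed zero-sum
        # direction so the result is deterministic and feasible
        stuck = (a <= _EPS) & live & (n_active > 1)
        if stuck.any():
            tie = np.where(zeroed, 0.0, np.arange(n, dtype=float)[:, None])
            tie_mean = np.divide(
                tie.sum(axis=0), n_active, out=np.zeros_like(l1),
                where=n_active > 0,
            )
            tie = np.where(zeroed, 0.0, tie - tie_mean[None, :])
            w = np.where(stuck[None, :], tie, w)
            a = np.einsum("ij,ij->j", w, w)
        b = 2.0 * np.einsum("ij,ij->j", w, m)
        c = np.einsum("ij,ij->j", m, m) - l2**2
        disc = np.maximum(b * b - 4.0 * a * c, 0.0)
        safe_a = np.where(a > _EPS, a, 1.0)
        alpha = np.where(a > _EPS, (-b + np.sqrt(disc)) / (2.0 * safe_a), 0.0)
        v = m + alpha[None, :] * w
        neg = (v < 0.0) & live[None, :]
        if not neg.any():
            break
        zeroed |= neg
        v = np.where(zeroed, 0.0, v)
        n_active = n - zeroed.sum(axis=0)
        excess = np.divide(
            v.sum(axis=0) - l1, n_active, out=np.zeros_like(l1), where=n_active > 0
        )
        v = np.where(zeroed, 0.0, v - excess[None, :])
    v = np.maximum(v, 0.0)
    v[v < 1e-13 * v.max(axis=0, keepdims=True)] = 0.0  # float dust
    v[:, ~live] = 0.0
    return v


def project_sparseness(
    v: np.ndarray, s: float, preserve_l2: bool = True
) -> np.ndarray:
    """Closest non-negative vector to ``v`` with Hoyer sparseness ``s``.

    With ``preserve_l2`` the result keeps ``v``'s L2 norm (the only mode
    the training loop uses; the flag exists so callers can renormalize).
    """
    v = np.asarray(v, dtype=float)
    out = project_columns_sparseness(v[:, None], s)[:, 0]
    if not preserve_l2:
        nrm = np.linalg.norm(out)
        if nrm > 0:
            out = out / nrm
    return out


def multiplicative_v_update(
    V: np.ndarray, Y: np.ndarray, X: np.ndarray, eps: float = _EPS
) -> np.ndarray:
    """One multiplicative basis update V <- V * (X Y^T) / (V Y Y^T).

    The fixed point V Y = X leaves V unchanged; for unconstrained Y the
    rule never increases the Euclidean reconstruction error.
    """
    numer = X @ Y.T
    denom = V @ (Y @ Y.T) + eps
    return V * (numer / denom)


class NMFSC:
    """NMF with a hard Hoyer-sparseness constraint on the code.

    Parameters
    ----------
    n_components : int
        Number of basis vectors / code units.
    sparseness_y : float or None
        Target Hoyer sparseness of every code column (None = plain
        non-negativity, no projection).
    mu0 : float
        Initial subtractive step size for the code update; halved
        whenever a step would increase the reconstruction error.
    max_epochs, tol : int, float
        Stop when the relative change of the reconstruction error drops
        below ``tol`` or after ``max_epochs`` alternations.
    """

    def __init__(
        self,
        n_components: int,
        sparseness_y: float | None = 0.85,
        mu0: float = 1.0,
        max_epochs: int = 300,
        tol: float = 1e-5,
        encode_max_iter: int = 200,
        encode_tol: float = 1e-5,
        seed: int = 0,
    ):
        self.n_components = n_components
        self.sparseness_y = sparseness_y
        self.mu0 = mu0
        self.max_epochs = max_epochs
        self.tol = tol
        self.encode_max_iter = encode_max_iter
        self.encode_tol = encode_tol
        self.seed = seed
        self.V_: np.ndarray | None = None
        self.n_epochs_: int | None = None

    # -- internals ---------------------------------------------------------

    def _project_codes(self, Y: np.ndarray) -> np.ndarray:
        if self.sparseness_y is None:
            return np.maximum(Y, 0.0)
        return project_columns_sparseness(Y, self.sparseness_y)

    def _code_step(self, V, Y, X, mu):
        """Subtractive code update with error-backtracking step size."""
        err = float(np.sum((V @ Y - X) ** 2))
        grad = V.T @ (V @ Y - X)
        for _ in range(40):
            Y_new = self._project_codes(Y - mu * grad)
            err_new = float(np.sum((V @ Y_new - X) ** 2))
            if err_new <= err or mu < 1e-12:
                return Y_new, err_new, mu
            mu *= 0.5
        return Y, err, mu

    # -- API ---------------------------------------------------------------

    def fit(self, X: np.ndarray) -> "NMFSC":
        """Fit the basis on inputs ``X`` of shape (n_samples, n_inputs)."""
        X = np.asarray(X, dtype=float).T  # inputs in columns, d x n
        if np.any(X < 0):
            raise ValueError("NMFSC requires non-negative inputs")
        d, n = X.shape
        r = self.n_components
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x4E4D]))
        V = rng.uniform(0.1, 1.0, size=(d, r))
        V /= np.linalg.norm(V, axis=0, keepdims=True)
        Y = self._project_codes(rng.uniform(0.1, 1.0, size=(r, n)))

        mu = self.mu0
        prev_err = np.inf
        for epoch in range(self.max_epochs):
            V = multiplicative_v_update(V, Y, X)
            norms = np.linalg.norm(V, axis=0, keepdims=True)
            norms[norms == 0] = 1.0
            V /= norms
            Y *= norms.T  # keep V Y invariant; projection restores sparseness
            Y, err, mu = self._code_step(V, Y, X, mu)
            mu = min(mu * 1.2, self.mu0)
            if prev_err < np.inf and abs(prev_err - err) <= self.tol * max(
                prev_err, _EPS
            ):
                break
            prev_err = err
        self.V_ = V
        self.n_epochs_ = epoch + 1
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Infer codes for (n_samples, n_inputs) with the basis frozen.

        Codes start at the rectified projection V^T x and are refined by
        the same subtractive update + sparseness projection until the
        largest code change falls below ``encode_tol``.  Deterministic.
        """
        if self.V_ is None:
            raise RuntimeError("NMFSC model is not fitted")
        V = self.V_
        Xc = np.asarray(X, dtype=float).T
        Y = self._project_codes(np.maximum(V.T @ Xc, 0.0))
        mu = self.mu0
        for _ in range(self.encode_max_iter):
            Y_new, _, mu = self._code_step(V, Y, Xc, mu)
            mu = min(mu * 1.2, self.mu0)
            delta = float(np.max(np.abs(Y_new - Y))) if Y.size else 0.0
            Y = Y_new
            if delta < self.encode_tol:
                break
        return Y.T

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            V=self.V_,
            sparseness_y=np.float64(
                -1.0 if self.sparseness_y is None else self.sparseness_y
            ),
            mu0=self.mu0,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "NMFSC":
        data = np.load(path)
        s = float(data["sparseness_y"])
        model = cls(
            n_components=data["V"].shape[1],
            sparseness_y=None if s < 0 else s,
            mu0=float(data["mu0"]),
            seed=int(data["seed"]),
        )
        model.V_ = data["V"]
        return model
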