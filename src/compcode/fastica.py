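"""FastICA baseline: a purely linear code with no competition.

Fixed-point ICA finds an unmixing matrix W maximizing negentropy
(non-gaussianity) of the components, so that y = W (x - mean) are as
independent as possible and x ~ V y + mean with V = pinv(W).  Encoding
an occluded input is a single matrix product — nothing in the dynamics
lets active units suppress others, which is exactly why this model is
the no-competition reference point.

The optimization itself is the standard symmetric (parallel) fixed-point
iteration with the tanh/logcosh contrast, provided by scikit-learn.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import FastICA as _SkFastICA


class FastICAModel:
    """Linear ICA code over centered inputs.

    Parameters
    ----------
    n_components : int
        Number of independent components (units).  Reduced automatically
        with a warning if the centered data has lower rank.
    tol, max_iter : float, int
        Fixed-point convergence threshold on the maximum row-direction
        change and the iteration cap.
    """

    def __init__(
        self,
        n_components: int,
        tol: float = 1e-4,
        max_iter: int = 500,
        seed: int = 0,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.mean_: np.ndarray | None = None
        self.W_: np.ndarray | None = None  # unmixing, y = W (x - mean)
        self.V_: np.ndarray | None = None  # mixing,  x ~ V y + mean
        self.n_iter_: int | None = None

    def fit(self, X: np.ndarray) -> "FastICAModel":
        """Fit on (n_samples, n_inputs); requires n_samples >= n_components."""
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.n_components:
            raise ValueError(
                f"need at least {self.n_components} samples, got {X.shape[0]}"
            )
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        k = self.n_components
        if rank < k:
            warnings.warn(
                f"data rank {rank} < {k} components; reducing to {rank}",
                stacklevel=2,
            )
            k = rank
        ica = _SkFastICA(
            n_components=k,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=np.random.SeedSequence([self.seed, 0x1CA]).generate_state(1)[
                0
            ]
            % (2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings handled by caller
            ica.fit(X)
        self.mean_ = ica.mean_
        self.W_ = ica.components_
        self.V_ = ica.mixing_
        self.n_iter_ = ica.n_iter_
        self.n_components = k
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        """y = W (x - mean): signed activities, shape (n_samples, k)."""
        if self.W_ is None:
            raise RuntimeError("FastICA model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) @ self.W_.T

    def decode(self, Y: np.ndarray) -> np.ndarray:
        """x = V y + mean, the generative direction."""
        if self.V_ is None:
            raise RuntimeError("FastICA model is not fitted")
        return np.atleast_2d(Y) @ self.V_.T + self.mean_

    def save(self, path) -> None:
        np.savez(
            path, W=self.W_, V=self.V_, mean=self.mean_,
            seed=self.seed, n_iter=self.n_iter_,
        )

    @classmethod
    def load(cls, path) -> "FastICAModel":
        data = np.load(path)
        model = cls(n_components=data["W"].shape[0], seed=int(data["seed"]))
        model.W_, model.V_, model.mean_ = data["W"], data["V"], data["mean"]
        model.n_iter_ = int(data["n_iter"])
        return model
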