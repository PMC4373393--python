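"""Predictive coding / biased competition (PC/BC) via divisive input
modulation (DIM).

A population of error units divides the input by its top-down
reconstruction,

    e = x / (eps1 + V^T y),

and the output units integrate the modulated input multiplicatively,

    y <- (eps2 + y) * (W e).

Iterating the two equations implements the competition: units that
explain part of the input remove that part (divisively) from the error
signal every other unit sees, driving the population toward a small
reconstruction error.  Learning is multiplicative as well,

    W <- W * (1 + beta * y (e^T - 1)),

so weights are stationary exactly when the reconstruction matches the
input (e = 1) and never change sign (non-negativity is conserved).
Feedforward W and feedback V hold the same synapses under different
normalizations: W rows sum to 1, V rows are scaled to maximum 1.

The output floor ``eps2`` re-seeds silent units so they can re-enter the
competition.  In its default mode it is a random small number, drawn
uniformly from [0, 2 * eps2] per unit and iteration; over a full
settling run the randomness averages out, but a single iteration (the
competition ablation) inherits it as multiplicative noise — which is
precisely why the ablated code carries so little usable information.
A fixed-eps2 mode is available for analytic work on the dynamics.
"""

from __future__ import annotations

import zlib

import numpy as np


def pcbc_error(x: np.ndarray, V: np.ndarray, y: np.ndarray, eps1: float) -> np.ndarray:
    """Error-unit activity e = x / (eps1 + V^T y); columns are samples."""
    recon = V.T @ y
    return x / (eps1 + recon)


class PCBC:
    """Divisive-input-modulation network.

    Parameters
    ----------
    n_units, n_inputs : int
        Output population size and input dimensionality.
    beta : float
        Learning rate of the multiplicative weight update.
    eps1 : float
        Division guard in the error units.  Also sets the scale of the
        error transient for unexplained inputs; it should sit at the
        scale of small input values (default 0.05 for inputs with unit
        mean-square pixels), or single stray pixels dominate learning.
    eps2 : float
        Output floor scale.  In ``eps2_mode="random"`` each unit draws
        its floor from U[0, 2 * eps2] at every iteration (same mean).
    n_iter_settle, n_iter_train : int
        Error/output alternations when encoding (200 at test time per
        the experimental protocol) and during a training presentation.
    """

    def __init__(
        self,
        n_units: int,
        n_inputs: int,
        beta: float = 0.01,
        eps1: float = 0.05,
        eps2: float = 0.01,
        eps2_mode: str = "random",
        n_iter_settle: int = 200,
        n_iter_train: int = 50,
        seed: int = 0,
    ):
        if eps2_mode not in ("random", "fixed"):
            raise ValueError(f"eps2_mode must be 'random' or 'fixed', got {eps2_mode}")
        self.n_units = n_units
        self.n_inputs = n_inputs
        self.beta = beta
        self.eps1 = eps1
        self.eps2 = eps2
        self.eps2_mode = eps2_mode
        self.n_iter_settle = n_iter_settle
        self.n_iter_train = n_iter_train
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9CBC]))
        W = rng.uniform(0.5, 1.0, size=(n_units, n_inputs))
        self.W_ = W / W.sum(axis=1, keepdims=True)
        self._refresh_feedback()

    def _refresh_feedback(self) -> None:
        """Feedback V = W rescaled so each unit's strongest synapse is 1."""
        row_max = self.W_.max(axis=1, keepdims=True)
        row_max[row_max == 0] = 1.0
        self.V_ = self.W_ / row_max

    def _floor_rng(self, X: np.ndarray) -> np.random.Generator | None:
        """Content-addressed RNG for the random output floor.

        Keyed by the model seed and a CRC of the input bytes, so
        encoding the same batch twice is bit-identical while different
        batches (e.g. clean vs occluded) get independent draws.
        """
        if self.eps2_mode != "random":
            return None
        key = zlib.crc32(np.ascontiguousarray(X).tobytes())
        return np.random.default_rng(np.random.SeedSequence([self.seed, 0xE2, key]))

    def _floor(self, shape, rng) -> np.ndarray | float:
        if rng is None:
            return self.eps2
        return rng.uniform(0.0, 2.0 * self.eps2, size=shape)

    # -- dynamics ----------------------------------------------------------

    def settle(
        self,
        X: np.ndarray,
        n_iter: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Iterate error and output updates from y = 0.

        ``X`` is (n_samples, n_inputs); returns non-negative activities
        (n_samples, n_units).  With ``n_iter=1`` the output is the pure
        feedforward response (the competition ablation).  Deterministic:
        in random-floor mode the noise stream is derived from the model
        seed and the input content.
        """
        if n_iter is None:
            n_iter = self.n_iter_settle
        if rng is None:
            rng = self._floor_rng(X)
        Xc = np.atleast_2d(np.asarray(X, dtype=float)).T  # d x n
        Y = np.zeros((self.n_units, Xc.shape[1]))
        for _ in range(n_iter):
            E = pcbc_error(Xc, self.V_, Y, self.eps1)
            Y = (self._floor(Y.shape, rng) + Y) * (self.W_ @ E)
        return Y.T

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.settle(X, self.n_iter_settle)

    # -- learning ----------------------------------------------------------

    def learn_step(self, x: np.ndarray, y: np.ndarray, e: np.ndarray) -> None:
        """W <- W * (1 + beta * outer(y, e - 1)), clipped at 0, rows
        renormalized to sum 1; feedback V recomputed."""
        factor = 1.0 + self.beta * np.outer(y, e - 1.0)
        if np.all(factor == 1.0):
            return  # stationary (e = 1, y = 0 or beta = 0): keep W bit-exact
        self.W_ = np.maximum(self.W_ * factor, 0.0)
        sums = self.W_.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        self.W_ /= sums
        self._refresh_feedback()

    def train(self, X: np.ndarray, n_presentations: int = 100_000) -> "PCBC":
        """Online training on presentations sampled with replacement.

        Each presentation settles for ``n_iter_train`` iterations and
        applies one weight update.  Deterministic given the seed.
        """
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x7247]))
        order = rng.integers(0, X.shape[0], size=n_presentations)
        floor_rng = (
            np.random.default_rng(np.random.SeedSequence([self.seed, 0xE2, 0x77]))
            if self.eps2_mode == "random"
            else None
        )
        for idx in order:
            x = X[idx]
            y = np.zeros(self.n_units)
            for _ in range(self.n_iter_train):
                e = x / (self.eps1 + self.V_.T @ y)
                y = (self._floor(y.shape, floor_rng) + y) * (self.W_ @ e)
            self.learn_step(x, y, e)
        return self

    def ablated(self) -> "PCBCAblated":
        """Competition off: encoding uses a single error/output iteration."""
        return PCBCAblated(self)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path, W=self.W_, beta=self.beta, eps1=self.eps1, eps2=self.eps2,
            eps2_mode=self.eps2_mode,
            n_iter_settle=self.n_iter_settle, n_iter_train=self.n_iter_train,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "PCBC":
        d = np.load(path)
        model = cls(
            n_units=d["W"].shape[0], n_inputs=d["W"].shape[1],
            beta=float(d["beta"]), eps1=float(d["eps1"]), eps2=float(d["eps2"]),
            eps2_mode=str(d["eps2_mode"]),
            n_iter_settle=int(d["n_iter_settle"]),
            n_iter_train=int(d["n_iter_train"]), seed=int(d["seed"]),
        )
        model.W_ = d["W"]
        model._refresh_feedback()
        return model


class PCBCAblated:
    """View of a PC/BC model that encodes with one iteration only."""

    def __init__(self, model: PCBC):
        self.model = model

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.model.settle(X, n_iter=1)
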