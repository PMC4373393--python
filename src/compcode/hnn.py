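"""Hebbian neural network (HNN) with learned lateral inhibition.

A single layer of threshold-linear rate neurons receives the input
through feedforward weights Wff and inhibits itself through a learned
non-negative lateral matrix C (zero diagonal):

    tau_r dr_j/dt = -r_j + [ (Wff x)_j - sum_k C[k, j] r_k ]+

integrated with explicit Euler steps.  A fast calcium trace Ca tracks
the rates and is what the plasticity actually sees.  Feedforward
learning is covariance Hebb with an Oja-style decay regulated by a
per-unit homeostatic term theta_j that pulls every unit's long-run mean
activity toward a common target p:

    dWff[j,i] = eta_ff * ( (x_i - xbar_i) (Ca_j - Cabar_j)
                           - theta_j Ca_j^2 Wff[j,i] )

Lateral weights are anti-Hebbian in effect (Foldiak scheme): they grow
with coactivation above the target level and decay otherwise,

    dC[k,j] = eta_lat * (Ca_k Ca_j - p^2),   C >= 0, diag C = 0,

so units that fire together come to inhibit each other — competition is
learned, local, and selective for units with similar receptive fields.
"""

from __future__ import annotations

import numpy as np


class HNN:
    """Rate-based Hebbian/anti-Hebbian network.

    Parameters
    ----------
    n_units, n_inputs : int
        Population size and input dimensionality.
    tau_r, tau_ca : float
        Rate and calcium-trace time constants in integration steps
        (1 step = 1 ms); the small ``tau_ca`` makes the trace fast, so
        learning behaves like an activity-based rule.
    eta_ff, eta_lat, eta_theta : float
        Learning rates of the feedforward, lateral and homeostatic
        updates.
    p : float
        Homeostatic target for the long-run mean activity (in units of
        firing rate); p**2 is the anti-Hebbian coactivation target.
    n_steps : int
        Euler steps per stimulus presentation (100 ms).
    w0 : float
        Initial L2 norm of each feedforward row.  Starting small keeps
        early rates (and hence the Oja decay and lateral growth, both
        quadratic in activity) gentle while structure forms; homeostasis
        then grows the rows to their working scale.
    nonneg : bool
        Clip feedforward weights at zero after each update (excitatory
        synapses), as in the lateral-inhibition models this network
        follows.
    """

    def __init__(
        self,
        n_units: int,
        n_inputs: int,
        tau_r: float = 10.0,
        tau_ca: float = 2.0,
        eta_ff: float = 2e-3,
        eta_lat: float = 1e-3,
        eta_theta: float = 1e-2,
        p: float = 0.3,
        n_steps: int = 100,
        mean_tau: float = 500.0,
        w0: float = 0.1,
        nonneg: bool = True,
        seed: int = 0,
    ):
        self.n_units = n_units
        self.n_inputs = n_inputs
        self.tau_r = tau_r
        self.tau_ca = tau_ca
        self.eta_ff = eta_ff
        self.eta_lat = eta_lat
        self.eta_theta = eta_theta
        self.p = p
        self.n_steps = n_steps
        self.mean_tau = mean_tau
        self.w0 = w0
        self.nonneg = nonneg
        self.seed = seed

        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x48AE]))
        W = rng.uniform(0.0, 1.0, size=(n_units, n_inputs))
        self.Wff_ = W / np.linalg.norm(W, axis=1, keepdims=True) * w0
        self.C_ = np.zeros((n_units, n_units))
        self.theta_ = np.full(n_units, 1.0)
        # running means used by covariance learning and homeostasis
        self._xbar = np.zeros(n_inputs)
        self._cabar = np.zeros(n_units)
        self._abar = np.full(n_units, p)

    # -- dynamics ----------------------------------------------------------

    def settle(
        self, X: np.ndarray, n_steps: int | None = None, return_trace: bool = False
    ):
        """Integrate the rate dynamics for ``n_steps`` from r = 0.

        ``X`` is (n_samples, n_inputs); returns (n_samples, n_units)
        non-negative rates, plus the final calcium trace if requested.
        """
        if n_steps is None:
            n_steps = self.n_steps
        Xc = np.atleast_2d(np.asarray(X, dtype=float))
        drive_ff = self.Wff_ @ Xc.T  # r x n
        R = np.zeros_like(drive_ff)
        Ca = np.zeros_like(drive_ff)
        for _ in range(n_steps):
            drive = np.maximum(drive_ff - self.C_.T @ R, 0.0)
            R += (drive - R) / self.tau_r
            Ca += (R - Ca) / self.tau_ca
        if return_trace:
            return R.T, Ca.T
        return R.T

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.settle(X)

    # -- learning ----------------------------------------------------------

    def learn_step(self, x: np.ndarray, ca: np.ndarray) -> None:
        """One plasticity step from a settled calcium trace."""
        # slow running means (covariance terms and homeostatic estimate)
        self._xbar += (x - self._xbar) / self.mean_tau
        self._cabar += (ca - self._cabar) / self.mean_tau
        self._abar += (ca - self._abar) / self.mean_tau

        hebb = np.outer(ca - self._cabar, x - self._xbar)
        oja = (self.theta_ * ca**2)[:, None] * self.Wff_
        self.Wff_ += self.eta_ff * (hebb - oja)
        if self.nonneg:
            np.maximum(self.Wff_, 0.0, out=self.Wff_)

        self.theta_ = np.maximum(
            self.theta_ + self.eta_theta * (self._abar - self.p), 0.05
        )

        self.C_ += self.eta_lat * (np.outer(ca, ca) - self.p**2)
        np.fill_diagonal(self.C_, 0.0)
        np.maximum(self.C_, 0.0, out=self.C_)

    def train(self, X: np.ndarray, n_presentations: int = 200_000) -> "HNN":
        """Online training: settle 100 steps, then learn, per presentation.

        Presentations are sampled with replacement; deterministic given
        the seed.
        """
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x7248]))
        order = rng.integers(0, X.shape[0], size=n_presentations)
        for idx in order:
            x = X[idx]
            _, ca = self.settle(x[None], return_trace=True)
            self.learn_step(x, ca[0])
        return self

    def ablated(self) -> "HNN":
        """Copy with all lateral inhibition removed (C = 0)."""
        clone = HNN(
            self.n_units, self.n_inputs, tau_r=self.tau_r, tau_ca=self.tau_ca,
            eta_ff=self.eta_ff, eta_lat=self.eta_lat, eta_theta=self.eta_theta,
            p=self.p, n_steps=self.n_steps, mean_tau=self.mean_tau,
            w0=self.w0, nonneg=self.nonneg, seed=self.seed,
        )
        clone.Wff_ = self.Wff_.copy()
        clone.C_ = np.zeros_like(self.C_)
        clone.theta_ = self.theta_.copy()
        return clone

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path, Wff=self.Wff_, C=self.C_, theta=self.theta_,
            tau_r=self.tau_r, tau_ca=self.tau_ca, eta_ff=self.eta_ff,
            eta_lat=self.eta_lat, eta_theta=self.eta_theta, p=self.p,
            n_steps=self.n_steps, mean_tau=self.mean_tau,
            w0=self.w0, nonneg=self.nonneg, seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "HNN":
        d = np.load(path)
        model = cls(
            n_units=d["Wff"].shape[0], n_inputs=d["Wff"].shape[1],
            tau_r=float(d["tau_r"]), tau_ca=float(d["tau_ca"]),
            eta_ff=float(d["eta_ff"]), eta_lat=float(d["eta_lat"]),
            eta_theta=float(d["eta_theta"]), p=float(d["p"]),
            n_steps=int(d["n_steps"]), mean_tau=float(d["mean_tau"]),
            w0=float(d["w0"]), nonneg=bool(d["nonneg"]), seed=int(d["seed"]),
        )
        model.Wff_, model.C_, model.theta_ = d["Wff"], d["C"], d["theta"]
        return model
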