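"""Robustness evaluation: LDA classification under occlusion, code
stability (cosine), population sparseness, receptive-field estimation
and the lateral-selectivity analysis.

The robustness protocol: every model is trained on non-occluded inputs;
a linear discriminant classifier is fitted on the model's training-set
code; test images are occluded at increasing levels, preprocessed with
the frozen whitening scale, encoded, and classified.  A model's
robustness is how slowly its accuracy decays with the occlusion level —
and, complementarily, how little its code rotates (cosine between the
non-occluded and occluded activity vector of the same image).
"""

from __future__ import annotations

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from compcode.datatypes import ImageBatch
from compcode.nmfsc import hoyer_sparseness
from compcode.preprocessing import Preprocessor, occlude, recombine_on_off


def fit_lda(Y: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """Linear discriminant classifier: class means + pooled within-class
    covariance, empirical priors.

    A tiny shrinkage (1e-6) regularizes the pooled covariance so
    rank-deficient codes (many silent units) remain classifiable.
    Raises ``ValueError`` if any class has fewer than 2 samples.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
    lda.fit(np.asarray(Y, dtype=float), labels)
    return lda


def accuracy_curve(
    model,
    preprocessor: Preprocessor,
    train_batch: ImageBatch,
    test_batch: ImageBatch,
    levels,
    occlusion_seed: int = 0,
    X_train: np.ndarray | None = None,
) -> dict[float, float]:
    """Classification accuracy of ``model``'s code at each occlusion level.

    The model is assumed trained; the classifier is (re)fitted on the
    model's code of the non-occluded training set.  Occlusion is applied
    by the preprocessor to the downscaled digits, with an RNG keyed only
    by ``occlusion_seed`` and image index, so every model evaluated with
    the same seed sees identical occluded images.  Passing ``model=None``
    evaluates the raw-input baseline: the classifier works directly on
    the 288-dim preprocessed vectors.
    """
    if X_train is None:
        X_train = preprocessor.transform(train_batch)
    code_train = X_train if model is None else model.encode(X_train)
    lda = fit_lda(code_train, train_batch.labels)

    result: dict[float, float] = {}
    for level in levels:
        X_test = preprocessor.transform(test_batch, float(level), occlusion_seed)
        code_test = X_test if model is None else model.encode(X_test)
        result[float(level)] = float(lda.score(code_test, test_batch.labels))
    return result


def cosine_stability(Y_clean: np.ndarray, Y_occluded: np.ndarray) -> float:
    """Mean per-image cosine between clean and occluded activity vectors.

    Image pairs where either vector is zero contribute cosine 0 (the
    code carried no information to be preserved).
    """
    Y0 = np.asarray(Y_clean, dtype=float)
    Y1 = np.asarray(Y_occluded, dtype=float)
    dots = np.einsum("ij,ij->i", Y0, Y1)
    n0 = np.linalg.norm(Y0, axis=1)
    n1 = np.linalg.norm(Y1, axis=1)
    denom = n0 * n1
    cos = np.divide(dots, denom, out=np.zeros_like(dots), where=denom > 0)
    return float(cos.mean())


def mean_code_sparseness(Y: np.ndarray) -> float:
    """Mean Hoyer sparseness of per-image activity vectors.

    Signed codes (FastICA) are measured on absolute values; all-zero
    codes are excluded (sparseness undefined).
    """
    A = np.abs(np.asarray(Y, dtype=float))
    vals = [hoyer_sparseness(row) for row in A if row.any()]
    if not vals:
        raise ValueError("all codes are zero; sparseness undefined")
    return float(np.mean(vals))


def template_match_fraction(
    W: np.ndarray, X: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> float:
    """Fraction of units whose weight vector correlates above
    ``threshold`` with its nearest class-mean input (digit-like RFs)."""
    templates = np.stack(
        [X[labels == c].mean(axis=0) for c in np.unique(labels)]
    )
    n = W.shape[0]
    corr = np.corrcoef(np.vstack([W, templates]))[:n, n:]
    return float((corr.max(axis=1) > threshold).mean())


# -- receptive fields ------------------------------------------------------


def random_dot_images(
    n_probes: int, side: int = 28, n_dots: int = 90, seed: int = 0
) -> ImageBatch:
    """Probe stimuli: ``n_dots`` unit-intensity pixels on a zero background."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD07]))
    pixels = np.zeros((n_probes, side * side))
    for i in range(n_probes):
        idx = rng.choice(side * side, size=n_dots, replace=False)
        pixels[i, idx] = 1.0
    return ImageBatch(pixels.reshape(n_probes, side, side))


def reverse_correlation_rf(
    model,
    preprocessor: Preprocessor,
    units,
    n_probes: int = 50_000,
    n_dots: int = 90,
    seed: int = 0,
    batch_size: int = 5_000,
    decorrelate: bool = True,
) -> np.ndarray:
    """Estimate receptive fields from random-dot probe stimuli.

    Random-dot images are preprocessed and encoded; each unit's RF is
    the response-weighted average of the preprocessed probe vectors
    (baseline-corrected, i.e. the response/input covariance), recombined
    on - off into a 12 x 12 map.  With ``decorrelate`` (default) the
    covariance is additionally solved against the probe covariance
    (ridge-regularized), which removes the correlations the resize and
    whitening filters leave in the probe ensemble — for a purely linear
    unit y = w.x this recovers w itself rather than cov(x) w.

    Returns (n_units_requested, side, side).
    """
    units = np.atleast_1d(units)
    d = preprocessor.n_inputs
    sum_x = np.zeros(d)
    sum_y = np.zeros(len(units))
    sum_yx = np.zeros((len(units), d))
    sum_xx = np.zeros((d, d)) if decorrelate else None
    total = 0
    for start in range(0, n_probes, batch_size):
        nb = min(batch_size, n_probes - start)
        probes = random_dot_images(nb, side=28, n_dots=n_dots, seed=seed + start)
        X = preprocessor.transform(probes)
        Y = np.atleast_2d(model.encode(X))[:, units]
        sum_x += X.sum(axis=0)
        sum_y += Y.sum(axis=0)
        sum_yx += Y.T @ X
        if decorrelate:
            sum_xx += X.T @ X
        total += nb
    mean_x = sum_x / total
    mean_y = sum_y / total
    cov = sum_yx / total - np.outer(mean_y, mean_x)
    if decorrelate:
        cov_x = sum_xx / total - np.outer(mean_x, mean_x)
        ridge = 1e-3 * np.trace(cov_x) / d
        cov = np.linalg.solve(cov_x + ridge * np.eye(d), cov.T).T
    side = preprocessor.side_
    return np.stack([recombine_on_off(row, side) for row in cov])


def weight_image(on_weights: np.ndarray, off_weights: np.ndarray) -> np.ndarray:
    """On minus off halves of a unit's weight vector as a square map."""
    on = np.asarray(on_weights, dtype=float).ravel()
    off = np.asarray(off_weights, dtype=float).ravel()
    if on.size != off.size:
        raise ValueError("on and off halves must have equal length")
    side = int(round(np.sqrt(on.size)))
    return (on - off).reshape(side, side)


def display_scale(img: np.ndarray) -> np.ndarray:
    """Map a signed weight image to [0, 1] gray levels.

    Zero maps to mid-gray (0.5), the maximum weight to white (1) and the
    minimum to black (0); positive and negative sides are scaled
    independently so both extremes are reached.
    """
    img = np.asarray(img, dtype=float)
    out = np.full(img.shape, 0.5)
    vmax = img.max()
    vmin = img.min()
    if vmax > 0:
        out = np.where(img > 0, 0.5 + 0.5 * img / vmax, out)
    if vmin < 0:
        out = np.where(img < 0, 0.5 - 0.5 * img / vmin, out)
    return out


# -- lateral selectivity (HNN) ---------------------------------------------


def lateral_selectivity(
    state, n_neurons: int = 10, top_k: int = 10, seed: int = 0
) -> tuple[list[dict], float]:
    """Do units inhibit most strongly the units most similar to them?

    For each of ``n_neurons`` sampled units, the outgoing lateral weights
    C[j, :] order the other units; the statistic is the mean cosine
    similarity of feedforward weights to the ``top_k`` most-inhibited
    targets minus that to the ``top_k`` least-inhibited ones, averaged
    over sampled units.  Positive means inhibition is selective for
    similarly tuned units.  Ties are broken by unit index, so the
    all-zero lateral matrix gives a well-defined statistic of 0.
    """
    Wff = state.Wff_
    C = state.C_
    n = Wff.shape[0]
    norms = np.linalg.norm(Wff, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Wn = Wff / norms
    cos = Wn @ Wn.T

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1A7]))
    chosen = rng.choice(n, size=min(n_neurons, n), replace=False)

    panel = []
    diffs = []
    for j in chosen:
        others = np.array([k for k in range(n) if k != j])
        # stable sort on (-weight, index): descending inhibition
        order = others[np.lexsort((others, -C[j, others]))]
        top = order[:top_k]
        bottom = order[-top_k:]
        if np.ptp(C[j, others]) == 0:
            diff = 0.0  # no inhibition structure: ordering is pure ties
        else:
            diff = float(cos[j, top].mean() - cos[j, bottom].mean())
        diffs.append(diff)
        panel.append(
            {"unit": int(j), "targets": order[:top_k].tolist(), "diff": diff}
        )
    return panel, float(np.mean(diffs))
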