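"""End-to-end experiment orchestration.

``run_experiment`` wires the full pipeline — synthetic data (or IDX
files), preprocessing, training of the four models, occlusion-robustness
curves with ablations, code stability, sparseness and lateral
selectivity — from a single validated config, with per-model state
caching so reruns with an identical config reuse trained weights.

All randomness flows from the single ``seed`` through named substreams
(data, occlusion, per-model initialization), so a rerun with the same
config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from compcode import evaluation
from compcode.datatypes import ImageBatch
from compcode.fastica import FastICAModel
from compcode.hnn import HNN
from compcode.idx import read_idx
from compcode.nmfsc import NMFSC
from compcode.pcbc import PCBC
from compcode.preprocessing import Preprocessor
from compcode.synthetic import generate_digits

log = logging.getLogger("compcode")

MODEL_NAMES = ("fastica", "nmfsc", "pcbc", "hnn")


def substream(seed: int, name: str) -> int:
    """Derive a named 31-bit seed from the global seed."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class ExperimentConfig:
    """Resolved configuration of one robustness experiment.

    The defaults are a scaled-down benchmark (synthetic digits, 2,000
    train / 500 test, 64 units) that reproduces the qualitative
    comparison in minutes on one CPU; the full-scale protocol uses MNIST
    IDX paths, 288 units, 100,000 (PC/BC) and 200,000 (HNN)
    presentations and the 0-60% occlusion grid in steps of 5%.
    """

    # data
    n_train: int = 2000
    n_test: int = 500
    idx_train: tuple[str, str] | None = None  # (images, labels) paths
    idx_test: tuple[str, str] | None = None
    # preprocessing
    resize_factor: float = 0.40
    f0_ratio: float = 0.78
    # models
    n_units: int = 64
    nmfsc_sparseness: float = 0.85
    nmfsc_max_epochs: int = 300
    pcbc_presentations: int = 30_000
    pcbc_iter_train: int = 50
    pcbc_iter_settle: int = 200
    pcbc_beta: float = 0.01
    hnn_presentations: int = 60_000
    hnn_params: dict = field(default_factory=dict)
    # evaluation
    levels: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    repeats: int = 1
    ablations: bool = True
    models: tuple[str, ...] = MODEL_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_train < 10 or self.n_test < 10:
            errors.append("n_train/n_test must be >= 10")
        if not all(0.0 <= l <= 1.0 for l in self.levels):
            errors.append("occlusion levels must lie in [0, 1]")
        if self.n_units < 2:
            errors.append("n_units must be >= 2")
        if not 0.0 < self.resize_factor <= 1.0:
            errors.append("resize_factor must be in (0, 1]")
        if self.repeats < 1:
            errors.append("repeats must be >= 1")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            errors.append(f"unknown models: {sorted(unknown)}")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        self.levels = tuple(float(l) for l in self.levels)
        self.models = tuple(self.models)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"invalid config: unknown keys {sorted(unknown)}")
        for key in ("levels", "models", "idx_train", "idx_test"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RobustnessReport:
    """Long-format results table plus the per-model artefacts."""

    records: pd.DataFrame  # columns: model, level, repeat, metric, value
    config: ExperimentConfig

    def value(self, model: str, metric: str, level: float | None = None) -> float:
        df = self.records
        mask = (df["model"] == model) & (df["metric"] == metric)
        if level is not None:
            mask &= np.isclose(df["level"].astype(float), level)
        vals = df.loc[mask, "value"]
        if vals.empty:
            raise KeyError(f"no record for {model}/{metric}/{level}")
        return float(vals.mean())

    def accuracy(self, model: str, level: float) -> float:
        return self.value(model, "accuracy", level)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "report.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(
                {
                    "config": self.config.to_dict(),
                    "records": self.records.to_dict(orient="records"),
                },
                fh,
                indent=1,
                default=str,
            )
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)


# -- stages ------------------------------------------------------------------


def load_data(cfg: ExperimentConfig) -> tuple[ImageBatch, ImageBatch]:
    if cfg.idx_train is not None:
        train = read_idx(*cfg.idx_train)
        test = read_idx(*cfg.idx_test)
        if cfg.n_train < len(train):
            train = train.subset(np.arange(cfg.n_train))
        if cfg.n_test < len(test):
            test = test.subset(np.arange(cfg.n_test))
    else:
        train = generate_digits(cfg.n_train, seed=substream(cfg.seed, "data-train"))
        test = generate_digits(cfg.n_test, seed=substream(cfg.seed, "data-test"))
    return train, test


def make_model(name: str, cfg: ExperimentConfig, n_inputs: int, repeat: int = 0):
    seed = substream(cfg.seed, f"model-{name}-{repeat}")
    if name == "fastica":
        return FastICAModel(n_components=cfg.n_units, seed=seed)
    if name == "nmfsc":
        return NMFSC(
            n_components=cfg.n_units,
            sparseness_y=cfg.nmfsc_sparseness,
            max_epochs=cfg.nmfsc_max_epochs,
            seed=seed,
        )
    if name == "pcbc":
        return PCBC(
            n_units=cfg.n_units,
            n_inputs=n_inputs,
            beta=cfg.pcbc_beta,
            n_iter_settle=cfg.pcbc_iter_settle,
            n_iter_train=cfg.pcbc_iter_train,
            seed=seed,
        )
    if name == "hnn":
        return HNN(n_units=cfg.n_units, n_inputs=n_inputs, seed=seed, **cfg.hnn_params)
    raise ValueError(f"unknown model {name}")


def train_model(name: str, model, X_train: np.ndarray, cfg: ExperimentConfig):
    if name == "fastica":
        return model.fit(X_train)
    if name == "nmfsc":
        return model.fit(X_train)
    if name == "pcbc":
        return model.train(X_train, n_presentations=cfg.pcbc_presentations)
    if name == "hnn":
        return model.train(X_train, n_presentations=cfg.hnn_presentations)
    raise ValueError(f"unknown model {name}")


_MODEL_CLASSES = {"fastica": FastICAModel, "nmfsc": NMFSC, "pcbc": PCBC, "hnn": HNN}


def get_trained_model(
    name: str,
    cfg: ExperimentConfig,
    X_train: np.ndarray,
    repeat: int = 0,
    cache_dir: Path | None = None,
):
    """Train (or load from cache) one model on the preprocessed train set."""
    cache_file = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_file = cache_dir / f"{cfg.digest()}_{name}_{repeat}.npz"
        if cache_file.exists():
            log.info("stage train[%s/%d]: cached", name, repeat)
            return _MODEL_CLASSES[name].load(cache_file)
    model = make_model(name, cfg, X_train.shape[1], repeat)
    log.info("stage train[%s/%d]: fitting", name, repeat)
    train_model(name, model, X_train, cfg)
    if cache_file is not None:
        model.save(cache_file)
    return model


def run_experiment(
    cfg: ExperimentConfig, outdir=None, progress: bool = False
) -> RobustnessReport:
    """Run the full comparison; returns (and optionally writes) the report.

    Deterministic models (FastICA, NMFSC) run once regardless of
    ``repeats``; the stochastically initialized PC/BC and HNN are
    averaged over ``cfg.repeats`` seeds.
    """
    cache_dir = Path(outdir) / "cache" if outdir is not None else None
    train, test = load_data(cfg)
    log.info("stage data: %d train / %d test", len(train), len(test))

    pp = Preprocessor(cfg.resize_factor, cfg.f0_ratio)
    X_train = pp.fit_transform(train)
    occ_seed = substream(cfg.seed, "occlusion")

    # occluded test inputs are shared by every model
    X_test: dict[float, np.ndarray] = {}
    for level in cfg.levels:
        X_test[level] = pp.transform(test, level, occ_seed)
    log.info("stage preprocess: %d-dim inputs", X_train.shape[1])

    rows: list[dict] = []

    def add(model, level, repeat, metric, value):
        rows.append(
            dict(model=model, level=level, repeat=repeat, metric=metric,
                 value=float(value))
        )

    # raw-input baseline
    lda_raw = evaluation.fit_lda(X_train, train.labels)
    for level in cfg.levels:
        add("raw", level, 0, "accuracy", lda_raw.score(X_test[level], test.labels))

    for name in cfg.models:
        n_rep = cfg.repeats if name in ("pcbc", "hnn") else 1
        for rep in range(n_rep):
            model = get_trained_model(name, cfg, X_train, rep, cache_dir)
            code_train = model.encode(X_train)
            lda = evaluation.fit_lda(code_train, train.labels)
            add(name, 0.0, rep, "sparseness",
                evaluation.mean_code_sparseness(code_train))

            codes = {lv: model.encode(X_test[lv]) for lv in cfg.levels}
            clean = codes.get(0.0)
            for lv in cfg.levels:
                add(name, lv, rep, "accuracy", lda.score(codes[lv], test.labels))
                if clean is not None:
                    add(name, lv, rep, "cosine",
                        evaluation.cosine_stability(clean, codes[lv]))

            if cfg.ablations and name in ("pcbc", "hnn"):
                abl = model.ablated()
                abl_train = abl.encode(X_train)
                lda_abl = evaluation.fit_lda(abl_train, train.labels)
                abl_codes = {lv: abl.encode(X_test[lv]) for lv in cfg.levels}
                for lv in cfg.levels:
                    add(f"{name}_ablated", lv, rep, "accuracy",
                        lda_abl.score(abl_codes[lv], test.labels))
                    add(f"{name}_ablated", lv, rep, "cosine",
                        evaluation.cosine_stability(abl_codes[0.0], abl_codes[lv]))
                add(f"{name}_ablated", 0.0, rep, "sparseness",
                    evaluation.mean_code_sparseness(abl.encode(X_train)))

            if name in ("pcbc", "hnn"):
                W = model.W_ if name == "pcbc" else model.Wff_
                add(name, 0.0, rep, "template_match",
                    evaluation.template_match_fraction(W, X_train, train.labels))
            if name == "hnn":
                _, stat = evaluation.lateral_selectivity(
                    model, seed=substream(cfg.seed, "lateral")
                )
                add("hnn", 0.0, rep, "lateral_selectivity", stat)
            log.info("stage evaluate[%s/%d]: done", name, rep)

    report = RobustnessReport(pd.DataFrame(rows), cfg)
    if outdir is not None:
        report.save(outdir)
    return report


def nmfsc_sparseness_sweep(
    cfg: ExperimentConfig,
    X_train: np.ndarray,
    train_labels: np.ndarray,
    X_test: dict[float, np.ndarray],
    test_labels: np.ndarray,
    targets=(None, 0.75, 0.85, 0.95),
) -> dict:
    """Robustness of NMFSC as a function of its sparseness target.

    For each target (None = unconstrained), fits NMFSC on the training
    code and scores LDA accuracy on every occluded test set; the figure
    of merit is the mean accuracy over the non-zero occlusion levels.
    Returns ``{target: {"accuracy": {level: acc}, "mean_occluded": m}}``.
    """
    out = {}
    for s in targets:
        model = NMFSC(
            n_components=cfg.n_units,
            sparseness_y=s,
            max_epochs=cfg.nmfsc_max_epochs,
            seed=substream(cfg.seed, "model-nmfsc-0"),
        ).fit(X_train)
        lda = evaluation.fit_lda(model.encode(X_train), train_labels)
        acc = {
            lv: float(lda.score(model.encode(X_test[lv]), test_labels))
            for lv in X_test
        }
        occluded = [a for lv, a in acc.items() if lv > 0]
        out[s] = {
            "accuracy": acc,
            "mean_occluded": float(np.mean(occluded)) if occluded else float("nan"),
        }
        log.info("stage sweep[s=%s]: mean occluded accuracy %.3f", s,
                 out[s]["mean_occluded"])
    return out
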