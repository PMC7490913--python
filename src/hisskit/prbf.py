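"""Possibility rule-based classifier using function approximation.

An evolutionary population of overlapping interval-condition rules is
trained online.  Each rule covers a hyper-rectangle of standardized
feature space and carries one linear model per class predicting the
degree of possibility (in [0, 1]) that a covered instance belongs to
that class.  Training interleaves delta-rule consequent updates, a
steady-state genetic algorithm on the match set, covering for unmatched
instances, and fitness-proportional deletion.  At inference the match
set's clamped predictions are fused (fitness-weighted mean by default);
an empty match set yields the all-ones distribution of total ignorance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .experts import N_CLASSES


@dataclass(frozen=True)
class PRBFConfig:
    population_size: int = 4000
    stretch: float = 25.0
    learning_rate: float = 0.1
    iterations: int = 100_000
    ga_interval: int = 25
    mutation_rate: float = 0.1
    mutation_scale: float = 0.1     # sd of gene perturbations, as fraction of stretch
    error_beta: float = 0.2         # running-error update rate
    deletion_experience: int = 20   # rules younger than this are deletion candidates last
    fusion: str = "mean"            # "mean" (fitness-weighted) or "max"

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.stretch <= 0:
            raise ValueError("stretch must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.fusion not in ("mean", "max"):
            raise ValueError("fusion must be 'mean' or 'max'")


@dataclass
class PRBFModel:
    """Rule population plus the feature standardization it was trained with."""

    centers: np.ndarray      # (P, F)
    halfwidths: np.ndarray   # (P, F), each in (0, stretch]
    weights: np.ndarray      # (P, C, F) linear consequent slopes
    intercepts: np.ndarray   # (P, C)
    fitness: np.ndarray      # (P,)
    experience: np.ndarray   # (P,)
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    config: PRBFConfig = field(default_factory=PRBFConfig)
    mae_history: list[float] = field(default_factory=list)

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.feature_mean) / self.feature_scale

    def to_json(self) -> str:
        doc = {
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "config": self.config.__dict__,
            "rules": [
                {
                    "center": self.centers[i].tolist(),
                    "halfwidth": self.halfwidths[i].tolist(),
                    "weights": self.weights[i].tolist(),
                    "intercepts": self.intercepts[i].tolist(),
                    "fitness": float(self.fitness[i]),
                    "experience": int(self.experience[i]),
                }
                for i in range(self.n_rules)
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PRBFModel":
        doc = json.loads(text)
        rules = doc["rules"]
        return cls(
            centers=np.array([r["center"] for r in rules], dtype=float),
            halfwidths=np.array([r["halfwidth"] for r in rules], dtype=float),
            weights=np.array([r["weights"] for r in rules], dtype=float),
            intercepts=np.array([r["intercepts"] for r in rules], dtype=float),
            fitness=np.array([r["fitness"] for r in rules], dtype=float),
            experience=np.array([r["experience"] for r in rules], dtype=int),
            feature_mean=np.asarray(doc["feature_mean"], dtype=float),
            feature_scale=np.asarray(doc["feature_scale"], dtype=float),
            config=PRBFConfig(**doc["config"]),
        )


def match_set(model: PRBFModel, x: np.ndarray) -> np.ndarray:
    """Indices of rules whose closed interval conditions cover ``x``.

    ``x`` must already be on the standardized feature scale.
    """
    if model.n_rules == 0:
        return np.empty(0, dtype=int)
    inside = np.abs(model.centers - x) <= model.halfwidths
    return np.flatnonzero(inside.all(axis=1))


def cover(x: np.ndarray, u: np.ndarray, config: PRBFConfig,
          rng: np.random.Generator) -> dict[str, np.ndarray]:
    """A fresh rule centered at ``x`` whose consequent predicts ``u`` at ``x``."""
    n_features = x.shape[0]
    c = u.shape[0]
    halfwidth = rng.uniform(1e-6, config.stretch, size=n_features)
    return {
        "center": x.astype(float).copy(),
        "halfwidth": halfwidth,
        "weights": np.zeros((c, n_features)),
        "intercepts": u.astype(float).copy(),
        "fitness": 0.5,
        "experience": 0,
    }


def _rule_predictions(model: PRBFModel, idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Clamped consequent outputs of rules ``idx`` at standardized ``x``: (|idx|, C)."""
    raw = np.einsum("rcf,f->rc", model.weights[idx], x) + model.intercepts[idx]
    return np.clip(raw, 0.0, 1.0)


def predict_possibility(model: PRBFModel, x: np.ndarray,
                        standardized: bool = False) -> np.ndarray:
    """Fused per-class possibility for one raw (or standardized) input."""
    if model.n_rules == 0:
        return np.ones(N_CLASSES)
    z = np.asarray(x, dtype=float)
    if not standardized:
        z = model.standardize(z)[0]
    m = match_set(model, z)
    c = model.intercepts.shape[1]
    if m.size == 0:
        return np.ones(c)
    preds = _rule_predictions(model, m, z)
    if model.config.fusion == "max":
        return preds.max(axis=0)
    w = model.fitness[m]
    total = w.sum()
    if total <= 0:
        return np.clip(preds.mean(axis=0), 0.0, 1.0)
    return np.clip((w[:, None] * preds).sum(axis=0) / total, 0.0, 1.0)


def crispify(pi: np.ndarray) -> int:
    """Highest-possibility class; ties break toward higher severity."""
    pi = np.asarray(pi, dtype=float)
    return int(np.flatnonzero(pi == pi.max()).max())


def predict_crisp(model: PRBFModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([crispify(predict_possibility(model, x)) for x in X])


def _delete_one(model: PRBFModel, rng: np.random.Generator) -> None:
    """Remove the weakest rule (lowest fitness; ties to lowest experience)."""
    exp_enough = model.experience >= model.config.deletion_experience
    pool = np.flatnonzero(exp_enough) if exp_enough.any() else np.arange(model.n_rules)
    f = model.fitness[pool]
    worst = pool[np.flatnonzero(f == f.min())]
    idx = worst[np.argmin(model.experience[worst])]
    keep = np.ones(model.n_rules, dtype=bool)
    keep[idx] = False
    model.centers = model.centers[keep]
    model.halfwidths = model.halfwidths[keep]
    model.weights = model.weights[keep]
    model.intercepts = model.intercepts[keep]
    model.fitness = model.fitness[keep]
    model.experience = model.experience[keep]
    model._errors = model._errors[keep]  # type: ignore[attr-defined]


def _append_rule(model: PRBFModel, rule: dict, error: float = 1.0) -> None:
    model.centers = np.vstack([model.centers, rule["center"][None, :]])
    model.halfwidths = np.vstack([model.halfwidths, rule["halfwidth"][None, :]])
    model.weights = np.concatenate([model.weights, rule["weights"][None, :, :]])
    model.intercepts = np.vstack([model.intercepts, rule["intercepts"][None, :]])
    model.fitness = np.append(model.fitness, rule["fitness"])
    model.experience = np.append(model.experience, rule["experience"])
    model._errors = np.append(model._errors, error)  # type: ignore[attr-defined]


def _ga_step(model: PRBFModel, m: np.ndarray, rng: np.random.Generator) -> None:
    """Steady-state GA: crossover + mutation of two fit matching rules."""
    cfg = model.config
    f = model.fitness[m] + 1e-12
    p = f / f.sum()
    parents = rng.choice(m, size=2, p=p)
    a, b = parents
    mask = rng.random(model.centers.shape[1]) < 0.5
    center = np.where(mask, model.centers[a], model.centers[b])
    halfwidth = np.where(mask, model.halfwidths[a], model.halfwidths[b])
    mut = rng.random(center.shape[0]) < cfg.mutation_rate
    center = center + mut * rng.normal(0.0, cfg.mutation_scale * cfg.stretch, center.shape[0])
    halfwidth = halfwidth + mut * rng.normal(0.0, cfg.mutation_scale * cfg.stretch, center.shape[0])
    halfwidth = np.clip(halfwidth, 1e-6, cfg.stretch)
    rule = {
        "center": center,
        "halfwidth": halfwidth,
        "weights": 0.5 * (model.weights[a] + model.weights[b]),
        "intercepts": 0.5 * (model.intercepts[a] + model.intercepts[b]),
        "fitness": 0.5 * (model.fitness[a] + model.fitness[b]),
        "experience": 0,
    }
    error = 0.5 * (model._errors[a] + model._errors[b])  # type: ignore[attr-defined]
    _append_rule(model, rule, error=error)


def train_prbf(
    features: np.ndarray,
    labels: np.ndarray,
    config: PRBFConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PRBFModel:
    """Train a rule population on possibility-labelled instances.

    ``features`` is (n, F) raw-scale; ``labels`` is (n, C) with entries
    in [0, 1].  Deterministic given the generator state.
    """
    config = config if config is not None else PRBFConfig()
    rng = rng if rng is not None else np.random.default_rng()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    U = np.atleast_2d(np.asarray(labels, dtype=float))
    if X.shape[0] != U.shape[0]:
        raise ValueError(
            f"features ({X.shape[0]} rows) and labels ({U.shape[0]} rows) disagree"
        )
    if np.any(U < 0) or np.any(U > 1):
        raise ValueError("possibility labels must lie in [0, 1]")
    n, n_features = X.shape
    c = U.shape[1]

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    model = PRBFModel(
        centers=np.empty((0, n_features)),
        halfwidths=np.empty((0, n_features)),
        weights=np.empty((0, c, n_features)),
        intercepts=np.empty((0, c)),
        fitness=np.empty(0),
        experience=np.empty(0, dtype=int),
        feature_mean=mean,
        feature_scale=scale,
        config=config,
    )
    model._errors = np.empty(0)  # running MAE per rule

    lr = config.learning_rate
    beta = config.error_beta
    for it in range(config.iterations):
        i = int(rng.integers(n))
        x, u = Z[i], U[i]
        m = match_set(model, x)
        if m.size == 0:
            _append_rule(model, cover(x, u, config, rng))
            m = np.array([model.n_rules - 1])
        preds = _rule_predictions(model, m, x)

        # system prediction error before the update, for convergence tracking
        w = model.fitness[m]
        fused = (w[:, None] * preds).sum(axis=0) / max(w.sum(), 1e-12)
        model.mae_history.append(float(np.abs(fused - u).mean()))

        err = u[None, :] - preds
        model.weights[m] += lr * err[:, :, None] * x[None, None, :]
        model.intercepts[m] += lr * err
        mae = np.abs(err).mean(axis=1)
        model._errors[m] += beta * (mae - model._errors[m])
        model.fitness[m] = 1.0 / (1.0 + model._errors[m])
        model.experience[m] += 1

        if m.size >= 2 and (it + 1) % config.ga_interval == 0:
            _ga_step(model, m, rng)
        while model.n_rules > config.population_size:
            _delete_one(model, rng)
    return model


def training_mae(model: PRBFModel, features: np.ndarray, labels: np.ndarray) -> float:
    """Mean absolute possibility-approximation error over a dataset."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    U = np.atleast_2d(np.asarray(labels, dtype=float))
    errs = [np.abs(predict_possibility(model, x) - u).mean() for x, u in zip(X, U)]
    return float(np.mean(errs))
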