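"""Three-layer radial basis function (RBF) network for nucleus classification.

The network maps a standardized morphometric feature vector through k
Gaussian hidden units φⱼ(x) = exp(−‖x − cⱼ‖² / 2σⱼ²) to a single linear
output; a nucleus is called malignant when the output score reaches the
decision cut (default 0.5 against 0/1 targets, ties malignant).

Training follows the classical recipe: hidden-unit centers from seeded
k-means on the standardized training features, widths from the mean distance
to each center's nearest neighbouring centers, and output weights by
ridge-regularized least squares.  The hidden-layer size is adjusted from the
data: each k in a grid is scored by balanced accuracy on an internal
stratified holdout, and the winner is refit on all training rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "Standardizer",
    "RBFConfig",
    "RBFModel",
    "NucleusPrediction",
    "fit_standardizer",
    "rbf_activations",
    "rbf_widths",
    "solve_output_weights",
    "fit_rbf",
    "predict_nucleus",
]

BENIGN, MALIGNANT = "benign", "malignant"


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training data; constant columns dropped."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: list[str]
    dropped: list[str] = field(default_factory=list)

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"expected {self.mean.shape[0]} features "
                f"({self.feature_names}), got {x.shape[1]}"
            )
        return (x - self.mean) / self.sd

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(z) * self.sd + self.mean


def fit_standardizer(
    x: np.ndarray, feature_names: list[str] | None = None
) -> tuple[Standardizer, np.ndarray]:
    """Fit means/SDs on an n×d table; returns (standardizer, transformed table).

    Columns with zero variance carry no information and are dropped with a
    warning; the standardizer records their names.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an n x d table with n >= 2")
    names = list(feature_names) if feature_names is not None \
        else [f"f{i}" for i in range(x.shape[1])]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("dropping constant feature(s): %s", dropped)
    std = Standardizer(
        mean=mean[keep],
        sd=sd[keep],
        feature_names=[n for n, k in zip(names, keep) if k],
        dropped=dropped,
    )
    return std, std.transform(x[:, keep])


def rbf_activations(
    x: np.ndarray, centers: np.ndarray, widths: np.ndarray
) -> np.ndarray:
    """Gaussian hidden-layer activations; each in (0, 1].

    ``x`` may be a single standardized vector or an n×d batch; returns
    (n, k) activations φⱼ(x) = exp(−‖x − cⱼ‖²/(2σⱼ²)).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    centers = np.asarray(centers, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if x.shape[1] != centers.shape[1]:
        raise ValueError("feature dimension mismatch with centers")
    d2 = cdist(x, centers, "sqeuclidean")
    return np.exp(-d2 / (2.0 * widths ** 2))


def rbf_widths(
    centers: np.ndarray, x: np.ndarray, n_neighbors: int = 2
) -> np.ndarray:
    """Width σⱼ per center: mean distance to its n nearest other centers.

    With a single center the inter-center rule is undefined; σ falls back to
    the mean distance of the training points to that center.
    """
    centers = np.atleast_2d(centers)
    k = centers.shape[0]
    if k == 1:
        return np.array([float(cdist(x, centers).mean())])
    d = cdist(centers, centers)
    np.fill_diagonal(d, np.inf)
    nn = min(n_neighbors, k - 1)
    widths = np.sort(d, axis=1)[:, :nn].mean(axis=1)
    return np.maximum(widths, 1e-12)


def solve_output_weights(
    phi: np.ndarray, y: np.ndarray, ridge_lambda: float = 1e-6
) -> np.ndarray:
    """Ridge least squares of the design [1, Φ] against 0/1 targets.

    Singular normal equations trigger a tenfold λ escalation, retried up to
    3 times before failing.
    """
    design = np.column_stack([np.ones(len(phi)), phi])
    gram = design.T @ design
    rhs = design.T @ np.asarray(y, dtype=float)
    lam = ridge_lambda
    for attempt in range(4):
        try:
            w = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), rhs)
            if np.isfinite(w).all():
                return w
        except np.linalg.LinAlgError:
            pass
        if attempt == 3:
            break
        lam *= 10.0
        logger.warning("singular normal equations; raising ridge lambda to %g", lam)
    raise np.linalg.LinAlgError("output-weight solve failed even with raised lambda")


@dataclass
class RBFConfig:
    k_grid: tuple[int, ...] = (10, 20, 40, 80)
    width_neighbors: int = 2
    ridge_lambda: float = 1e-6
    seed: int = 0
    decision_cut: float = 0.5

    @classmethod
    def from_json(cls, path: str | Path) -> "RBFConfig":
        raw = json.loads(Path(path).read_text())
        raw["k_grid"] = tuple(raw.get("k_grid", cls.k_grid))
        return cls(**raw)


@dataclass(frozen=True)
class NucleusPrediction:
    score: float
    label: str  # benign | malignant


@dataclass
class RBFModel:
    standardizer: Standardizer
    centers: np.ndarray
    widths: np.ndarray
    output_weights: np.ndarray  # k + 1 including leading bias
    decision_cut: float
    k: int
    training_seed: int
    config: RBFConfig
    selection_record: list[dict] = field(default_factory=list)

    # -- inference ---------------------------------------------------------
    def decision_function(self, x: np.ndarray) -> np.ndarray:
        z = self.standardizer.transform(x)
        phi = rbf_activations(z, self.centers, self.widths)
        return np.column_stack([np.ones(len(phi)), phi]) @ self.output_weights

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self.decision_function(x)
        return np.where(scores >= self.decision_cut, MALIGNANT, BENIGN)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "standardizer": {
                "mean": self.standardizer.mean.tolist(),
                "sd": self.standardizer.sd.tolist(),
                "feature_names": self.standardizer.feature_names,
                "dropped": self.standardizer.dropped,
            },
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "output_weights": self.output_weights.tolist(),
            "decision_cut": self.decision_cut,
            "k": self.k,
            "training_seed": self.training_seed,
            "config": {**self.config.__dict__, "k_grid": list(self.config.k_grid)},
            "selection_record": self.selection_record,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RBFModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        cfg = doc["config"]
        cfg["k_grid"] = tuple(cfg["k_grid"])
        return cls(
            standardizer=Standardizer(
                mean=np.array(doc["standardizer"]["mean"]),
                sd=np.array(doc["standardizer"]["sd"]),
                feature_names=doc["standardizer"]["feature_names"],
                dropped=doc["standardizer"]["dropped"],
            ),
            centers=np.array(doc["centers"]),
            widths=np.array(doc["widths"]),
            output_weights=np.array(doc["output_weights"]),
            decision_cut=doc["decision_cut"],
            k=doc["k"],
            training_seed=doc["training_seed"],
            config=RBFConfig(**cfg),
            selection_record=doc["selection_record"],
        )


def _canonical_order(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row order keyed to content (label, then lexicographic features).

    Makes the internal holdout split invariant to the order the caller
    happened to store the training rows in.
    """
    keys = [z[:, j] for j in range(z.shape[1] - 1, -1, -1)] + [y]
    return np.lexsort(tuple(keys))


def _stratified_holdout(
    y: np.ndarray, holdout_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of holdout (validation) rows, stratified by class.

    Per-class holdout counts are within one row of the target fraction, so
    class proportions mirror the parent set.
    """
    val = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(holdout_fraction * len(idx))))
        val[rng.permutation(idx)[:n_val]] = True
    return val


def _fit_at_k(
    z: np.ndarray,
    t: np.ndarray,
    k: int,
    config: RBFConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(z)
    centers = km.cluster_centers_
    widths = rbf_widths(centers, z, config.width_neighbors)
    phi = rbf_activations(z, centers, widths)
    w = solve_output_weights(phi, t, config.ridge_lambda)
    return centers, widths, w


def fit_rbf(
    features: np.ndarray,
    labels: np.ndarray,
    config: RBFConfig | None = None,
    feature_names: list[str] | None = None,
) -> RBFModel:
    """Train the RBF nucleus classifier; deterministic for fixed data + seed.

    labels are 'benign'/'malignant' strings (targets 0/1).  Hidden-layer size
    is selected from ``config.k_grid`` by balanced accuracy on an internal
    stratified 80/20 holdout, then the model is refit on all rows at the
    chosen k.
    """
    config = config or RBFConfig()
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    t = (labels == MALIGNANT).astype(float)
    if t.min() == t.max():
        raise ValueError("training data must contain both classes")
    if x.shape[0] <= max(config.k_grid):
        raise ValueError("need more training rows than the largest k in k_grid")

    # canonical row order first, so every later float reduction is invariant
    # to the order the caller stored the rows in
    order = _canonical_order(x, t)
    x, t = x[order], t[order]
    std, z = fit_standardizer(x, feature_names)

    rng = np.random.default_rng(config.seed)
    val = _stratified_holdout(t, 0.2, rng)
    z_tr, t_tr = z[~val], t[~val]
    z_val, t_val = z[val], t[val]

    record = []
    best = None
    for k in config.k_grid:
        if k >= len(z_tr):
            logger.warning("skipping k=%d: not enough holdout-training rows", k)
            continue
        centers, widths, w = _fit_at_k(z_tr, t_tr, k, config, config.seed)
        phi = rbf_activations(z_val, centers, widths)
        scores = np.column_stack([np.ones(len(phi)), phi]) @ w
        pred = (scores >= config.decision_cut).astype(float)
        sens = pred[t_val == 1].mean() if (t_val == 1).any() else 0.0
        spec = (1 - pred[t_val == 0]).mean() if (t_val == 0).any() else 0.0
        bal = (sens + spec) / 2.0
        record.append({"k": k, "balanced_accuracy": float(bal)})
        if best is None or bal > best[1] + 1e-12:
            best = (k, bal)
    if best is None:
        raise ValueError("no k in k_grid was feasible")

    k = best[0]
    centers, widths, w = _fit_at_k(z, t, k, config, config.seed)
    return RBFModel(
        standardizer=std,
        centers=centers,
        widths=widths,
        output_weights=w,
        decision_cut=config.decision_cut,
        k=k,
        training_seed=config.seed,
        config=config,
        selection_record=record,
    )


def predict_nucleus(model: RBFModel, x: np.ndarray) -> NucleusPrediction:
    """Classify one feature vector; score >= decision_cut → malignant."""
    score = float(model.decision_function(np.atleast_2d(x))[0])
    label = MALIGNANT if score >= model.decision_cut else BENIGN
    return NucleusPrediction(score=score, label=label)
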