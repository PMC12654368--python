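"""Model training harness: imbalance handling, randomized hyperparameter
search with 5-fold cross-validation, final refit, artifact persistence, and
the ranked selection rule for fingerprint–model combinations.

Two modeling tasks share the harness: ``contribution`` (binary positive/
negative aroma contribution, selected by macro-F1 with Accuracy →
Macro-Precision → Macro-Recall tie-breaks) and ``threshold`` (regression of
y = -log10(odor threshold mg/L), selected by R² with RMSE tie-break). A
``category`` multi-class head reuses the classification path. Model
families: random forest (RF), gradient-boosted trees (GBDT), multilayer
perceptron (MLP), and a graph-convolution family (GCN) built on fixed
normalized-adjacency propagation with an MLP readout.

Class imbalance is handled two ways, matching the training protocol the
package implements: the training-set majority class is downsampled to a cap
(default 5000) and inverse-frequency sample weights are applied where the
estimator supports them. The held-out validation set is never touched by
either step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import f1_score, mean_squared_error, r2_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler
from xgboost import XGBClassifier, XGBRegressor


class _StringLabelXGBClassifier(XGBClassifier):
    """XGBClassifier accepting arbitrary label values via internal encoding."""

    def fit(self, X, y, sample_weight=None, **kwargs):
        self._label_encoder = LabelEncoder().fit(y)
        self._fitting = True
        try:
            return super().fit(
                X, self._label_encoder.transform(y), sample_weight=sample_weight, **kwargs
            )
        finally:
            self._fitting = False

    def predict(self, X, **kwargs):
        return self._label_encoder.inverse_transform(super().predict(X, **kwargs))

    @property
    def classes_(self):
        # During xgboost's own fit-time sanity check the encoder exists but
        # y is already integer-encoded, so report the encoded range there.
        if getattr(self, "_fitting", False) or not hasattr(self, "_label_encoder"):
            return super().classes_
        return self._label_encoder.classes_

from . import features as feat
from .registry import SmilesParseError

FAMILIES = ("rf", "gbdt", "mlp", "gcn")
TASKS = ("contribution", "category", "threshold")

N_PHYSCHEM = 4

# Hyperparameter search domains per family. Tree and MLP domains follow the
# grids the harness was designed around; every randomized draw stays inside
# its domain.
SEARCH_SPACES: dict[str, dict[str, list]] = {
    "rf": {
        "n_estimators": [200, 300, 400, 600],
        "max_depth": [10, 20, 30],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 4],
        "max_features": ["sqrt", "log2"],
    },
    "gbdt": {
        "n_estimators": [300, 600, 900],
        "max_depth": [4, 6, 8],
        "learning_rate": [0.03, 0.05, 0.1],
        "subsample": [0.7, 0.9, 1.0],
        "colsample_bytree": [0.6, 0.8, 1.0],
        "reg_lambda": [0.0, 1.0, 3.0],
    },
    "mlp": {
        "hidden_layer_sizes": [(512, 128), (256, 128), (256, 64)],
        "alpha": list(np.logspace(-5, -3, 5)),
        "learning_rate_init": list(np.logspace(-4, -3, 5)),
        "batch_size": [128, 256, 512],
    },
    "gcn": {
        "hidden_dim": [64, 128, 256],
        "dropout": [0.1, 0.3, 0.5],
        "learning_rate": [1e-3, 3e-3, 5e-4],
        "weight_decay": [0.0, 1e-4, 5e-4],
        "batch_size": [64, 128, 256],
    },
}


# ---------------------------------------------------------------------------
# Imbalance handling
# ---------------------------------------------------------------------------

def downsample_majority(labels, cap: int = 5000, seed: int | None = None) -> np.ndarray:
    """Indices retaining at most *cap* rows of the majority class.

    The majority class is sampled without replacement with a seeded RNG;
    all other classes are kept in full. Returned indices are sorted, so the
    same seed always retains the same set.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    majority = classes[np.argmax(counts)]
    maj_idx = np.flatnonzero(labels == majority)
    if maj_idx.size <= cap:
        return np.arange(labels.size)
    rng = np.random.default_rng(seed)
    keep = rng.choice(maj_idx, size=cap, replace=False)
    rest = np.flatnonzero(labels != majority)
    return np.sort(np.concatenate([keep, rest]))


def class_weights(labels) -> dict:
    """Inverse-frequency class weights w_c = N / (K · N_c).

    Weighted counts conserve the sample size: Σ_c w_c · N_c = N.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("class weights need at least two classes")
    n, k = labels.size, classes.size
    return {c: n / (k * nc) for c, nc in zip(classes, counts)}


def sample_weights(labels) -> np.ndarray:
    w = class_weights(labels)
    return np.array([w[c] for c in np.asarray(labels)])


# ---------------------------------------------------------------------------
# Graph-convolution embedding (the GCN family's front end)
# ---------------------------------------------------------------------------

def graph_embedding(smiles: str, n_layers: int = 2) -> np.ndarray:
    """Fixed-weight graph-convolution embedding of one molecule.

    Node features are propagated *n_layers* times through the symmetric-
    normalized adjacency with self-loops (D^-1/2 (A+I) D^-1/2); the mean-
    pooled node features after each propagation round are concatenated and
    the molecule's physchem 4-vector appended at readout. Parameter-free by
    construction — the learnable part of the family is the MLP readout.
    """
    g = feat.to_graph(smiles)
    n = g.n_nodes
    a = np.eye(n)
    for (i, j), order in zip(g.edges, g.bond_orders):
        a[i, j] = a[j, i] = order
    d = 1.0 / np.sqrt(a.sum(axis=1))
    s = a * d[:, None] * d[None, :]
    x = g.node_features
    pooled = [x.mean(axis=0)]
    for _ in range(n_layers):
        x = s @ x
        pooled.append(x.mean(axis=0))
    return np.concatenate(pooled + [g.physchem])


def graph_matrix(smiles_list, n_layers: int = 2) -> np.ndarray:
    return np.stack([graph_embedding(s, n_layers) for s in smiles_list])


def design_matrix(smiles_list, scheme: str) -> np.ndarray:
    """Feature matrix for a scheme, including the 'graph' pseudo-scheme."""
    if scheme == "graph":
        return graph_matrix(smiles_list)
    return feat.feature_matrix(smiles_list, scheme)


# ---------------------------------------------------------------------------
# Estimator construction
# ---------------------------------------------------------------------------

class _PhyschemScaler(BaseEstimator, TransformerMixin):
    """Standardize only the trailing physchem columns; fingerprint bits pass
    through untouched. Fit statistics come from the training folds only, so
    no validation information leaks into scaling."""

    def __init__(self, n_physchem: int = N_PHYSCHEM):
        self.n_physchem = n_physchem

    def fit(self, X, y=None):
        self.scaler_ = StandardScaler().fit(X[:, -self.n_physchem:])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64).copy()
        X[:, -self.n_physchem:] = self.scaler_.transform(X[:, -self.n_physchem:])
        return X


def build_estimator(family: str, task: str, config: dict, seed: int = 0) -> Pipeline:
    """Assemble the pipeline (physchem standardization + estimator)."""
    is_clf = task in ("contribution", "category")
    cfg = dict(config)
    if family == "rf":
        cls = RandomForestClassifier if is_clf else RandomForestRegressor
        est = cls(random_state=seed, n_jobs=1, **cfg)
    elif family == "gbdt":
        cls = _StringLabelXGBClassifier if is_clf else XGBRegressor
        est = cls(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
            **cfg,
        )
    elif family == "mlp":
        cls = MLPClassifier if is_clf else MLPRegressor
        est = cls(
            random_state=seed,
            max_iter=300,
            early_stopping=True,
            validation_fraction=0.1,
            **cfg,
        )
    elif family == "gcn":
        # Graph family: propagation happens in the embedding; the searched
        # hidden_dim / learning_rate / weight_decay / batch_size drive the
        # MLP readout. The dropout domain is accepted but inert (no
        # stochastic layers in the closed-form propagation).
        cls = MLPClassifier if is_clf else MLPRegressor
        est = cls(
            hidden_layer_sizes=(cfg.get("hidden_dim", 128),),
            alpha=cfg.get("weight_decay", 0.0),
            learning_rate_init=cfg.get("learning_rate", 1e-3),
            batch_size=cfg.get("batch_size", 128),
            random_state=seed,
            max_iter=300,
            early_stopping=True,
            validation_fraction=0.1,
        )
    else:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    return Pipeline([("scale", _PhyschemScaler()), ("clf", est)])


def _fit(pipeline: Pipeline, X, y, weights: np.ndarray | None):
    name = type(pipeline.named_steps["clf"]).__name__
    if weights is not None and name in (
        "RandomForestClassifier",
        "RandomForestRegressor",
        "_StringLabelXGBClassifier",
        "XGBRegressor",
    ):
        pipeline.fit(X, y, clf__sample_weight=weights)
    else:
        pipeline.fit(X, y)
    return pipeline


# ---------------------------------------------------------------------------
# Randomized search with 5-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Outcome of a randomized search: per-fold metric values of the winner."""

    task: str
    scheme: str
    family: str
    config: dict
    fold_scores: list[float]
    mean_score: float
    sd_score: float
    all_draws: list[dict] = field(default_factory=list)

    @property
    def folds(self) -> int:
        return len(self.fold_scores)


def draw_configs(family: str, n_draws: int, seed: int | None = None) -> list[dict]:
    """Seeded uniform draws from the family's search domains (may repeat)."""
    space = SEARCH_SPACES[family]
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        draws.append({k: v[rng.integers(len(v))] for k, v in space.items()})
    return draws


def _cv_scores(pipeline, X, y, task, folds, seed, use_weights):
    is_clf = task in ("contribution", "category")
    if is_clf:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < folds:
            raise ValueError(
                f"stratified {folds}-fold CV impossible: a class has only "
                f"{counts.min()} members"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    primary, secondary = [], []
    for tr, te in splitter.split(X, y if is_clf else None):
        p = clone(pipeline)
        w = sample_weights(y[tr]) if (use_weights and is_clf) else None
        _fit(p, X[tr], y[tr], w)
        pred = p.predict(X[te])
        if is_clf:
            primary.append(f1_score(y[te], pred, average="macro", zero_division=0))
            secondary.append(0.0)
        else:
            primary.append(r2_score(y[te], pred))
            secondary.append(float(np.sqrt(mean_squared_error(y[te], pred))))
    return primary, secondary


def random_search(
    task: str,
    scheme: str,
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    n_draws: int = 30,
    folds: int = 5,
    seed: int | None = None,
    use_weights: bool = True,
) -> CVResult:
    """Evaluate *n_draws* seeded configurations by k-fold CV; keep the best.

    Classification selects by fold-mean macro-F1 (stratified folds);
    regression by fold-mean R² with fold-mean RMSE as tie-breaker. Exact
    metric ties resolve to the earlier draw.
    """
    y = np.asarray(y)
    configs = draw_configs(family, n_draws, seed)
    best = None
    all_draws = []
    for i, cfg in enumerate(configs):
        pipeline = build_estimator(family, task, cfg, seed=0 if seed is None else seed)
        primary, secondary = _cv_scores(pipeline, X, y, task, folds, seed, use_weights)
        mean_p = float(np.mean(primary))
        mean_s = float(np.mean(secondary))
        all_draws.append({"config": cfg, "mean_score": mean_p})
        # regression tie-break: higher R², then lower RMSE, then draw order
        key = (mean_p, -mean_s, -i)
        if best is None or key > best[0]:
            best = (key, cfg, primary)
    _, cfg, primary = best
    return CVResult(
        task=task,
        scheme=scheme,
        family=family,
        config=cfg,
        fold_scores=[float(v) for v in primary],
        mean_score=float(np.mean(primary)),
        sd_score=float(np.std(primary)),
        all_draws=all_draws,
    )


def rank_combinations(validation_reports: list[dict]) -> list[dict]:
    """Order fingerprint–model combinations by validation performance.

    Lexicographic descending sort on (macro-F1, accuracy, macro-precision,
    macro-recall); fully tied reports keep their input order (stable sort).
    """
    def key(r):
        m = r["metrics"] if "metrics" in r else r
        return (
            -m["macro_f1"],
            -m["accuracy"],
            -m["macro_precision"],
            -m["macro_recall"],
        )

    return sorted(validation_reports, key=key)


# ---------------------------------------------------------------------------
# Final fit, prediction, persistence
# ---------------------------------------------------------------------------

ARTIFACT_VERSION = "1"


@dataclass
class ModelArtifact:
    """A fitted pipeline plus everything needed to reproduce its predictions."""

    task: str
    scheme: str
    family: str
    config: dict
    pipeline: Pipeline
    classes: list | None = None
    seed: int | None = None
    data_hash: str | None = None
    version: str = ARTIFACT_VERSION


def _hash_training_data(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.asarray(y).astype(str).tobytes() if y.dtype.kind in "OU" else y.tobytes())
    return h.hexdigest()[:16]


def fit_final(
    task: str,
    scheme: str,
    family: str,
    config: dict,
    X: np.ndarray,
    y,
    seed: int = 0,
    use_weights: bool = True,
) -> ModelArtifact:
    """Refit the selected configuration on the full training set."""
    y = np.asarray(y)
    pipeline = build_estimator(family, task, config, seed=seed)
    is_clf = task in ("contribution", "category")
    w = sample_weights(y) if (use_weights and is_clf) else None
    _fit(pipeline, X, y, w)
    classes = list(pipeline.named_steps["clf"].classes_) if is_clf else None
    return ModelArtifact(
        task=task,
        scheme=scheme,
        family=family,
        config={k: (v if not isinstance(v, tuple) else list(v)) for k, v in config.items()},
        pipeline=pipeline,
        classes=classes,
        seed=seed,
        data_hash=_hash_training_data(X, y),
    )


def predict(artifact: ModelArtifact, smiles_list) -> list[dict]:
    """Per-molecule predictions; unparseable SMILES become error records.

    Contribution: probability of the positive class (P(pos) + P(neg) = 1).
    Threshold: y on the -log10(mg/L) scale. Category: predicted label.
    """
    rows = []
    ok_idx, vecs = [], []
    for i, s in enumerate(smiles_list):
        try:
            vec = (
                graph_embedding(s)
                if artifact.scheme == "graph"
                else feat.featurize(s, artifact.scheme).vector
            )
            ok_idx.append(i)
            vecs.append(vec)
            rows.append({"smiles": s})
        except SmilesParseError as exc:
            rows.append({"smiles": s, "error": str(exc)})
    if vecs:
        X = np.stack(vecs)
        clf = artifact.pipeline
        if artifact.task == "contribution":
            proba = clf.predict_proba(X)
            pos_col = artifact.classes.index("positive") if "positive" in artifact.classes else 1
            for r, p in zip((rows[i] for i in ok_idx), proba[:, pos_col]):
                r["p_positive"] = float(p)
                r["label"] = "positive" if p >= 0.5 else "negative"
        elif artifact.task == "category":
            for r, lab in zip((rows[i] for i in ok_idx), clf.predict(X)):
                r["category"] = str(lab)
        else:
            for r, yhat in zip((rows[i] for i in ok_idx), clf.predict(X)):
                r["y_neglog10_mg_L"] = float(yhat)
                r["threshold_mg_L"] = float(10.0 ** (-yhat))
    return rows


def save_artifact(artifact: ModelArtifact, out_dir: str | Path) -> Path:
    """Persist the artifact: params binary + manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    joblib.dump(artifact.pipeline, out / "model.joblib")
    manifest = {
        "task": artifact.task,
        "scheme": artifact.scheme,
        "family": artifact.family,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in artifact.config.items()},
        "classes": artifact.classes,
        "seed": artifact.seed,
        "data_hash": artifact.data_hash,
        "version": artifact.version,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return out


def load_artifact(path: str | Path) -> ModelArtifact:
    path = Path(path)
    with open(path / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest.get("version") != ARTIFACT_VERSION:
        raise ValueError(
            f"artifact version {manifest.get('version')!r} does not match "
            f"supported version {ARTIFACT_VERSION!r}"
        )
    pipeline = joblib.load(path / "model.joblib")
    return ModelArtifact(
        task=manifest["task"],
        scheme=manifest["scheme"],
        family=manifest["family"],
        config=manifest["config"],
        pipeline=pipeline,
        classes=manifest["classes"],
        seed=manifest["seed"],
        data_hash=manifest["data_hash"],
        version=manifest["version"],
    )
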