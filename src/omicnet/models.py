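"""Model construction: the multi-branch CNN and four classical baselines.

The deep model gives each omics modality its own 1-D convolutional branch
over the encoded feature track; pooled branch representations are
concatenated, batch-normalized, and fed to a fully connected head with
dropout in every layer and Leaky-ReLU activations throughout. A softmax
output yields class probabilities for categorical phenotypes; a single
linear unit serves quantitative ones. Classical baselines (L2 logistic
regression, RBF-kernel SVM, decision tree, random forest) consume the
flattened concatenation of all encoded modalities.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .nn import MultiBranchNet
from .preprocess import DatasetBundle

BASELINE_KINDS = ("logistic_l2", "svm_rbf", "decision_tree", "random_forest")


@dataclass
class ModelSpec:
    """Architecture + training hyperparameters of the multi-branch CNN.

    All branches share the conv configuration (layer count, filters, kernel);
    the head is described by ``dense_sizes``. These defaults are starting
    points inside the tunable search space, not fitted constants.
    """

    task: str = "classification"
    n_conv_layers: int = 2
    filters: int = 16
    kernel_size: int = 5
    pooling: str = "local"  # "local" (windowed max + flatten) | "max" | "mean"
    pool_size: int = 4
    dense_sizes: tuple = (64, 16)
    dropout: float = 0.5
    leaky_slope: float = 0.01
    batch_norm: bool = True
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        self.dense_sizes = tuple(int(s) for s in self.dense_sizes)

    def to_config(self) -> dict:
        cfg = asdict(self)
        cfg["dense_sizes"] = list(self.dense_sizes)
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelSpec":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown ModelSpec keys {sorted(unknown)}")
        return cls(**cfg)


@dataclass
class ModelHandle:
    """A model plus its fitted state under one predict contract.

    ``kind`` is "multi_cnn" or one of the baseline kinds. ``predict`` paths
    are only callable once ``fitted`` is True; ``metadata`` records the loss
    bound to the task (cross-entropy for classification, mean squared error
    for regression) and the label encoding used.
    """

    kind: str
    task: str
    spec: ModelSpec | None = None
    params: dict = field(default_factory=dict)
    fitted: bool = False
    net: MultiBranchNet | None = None
    estimator: object = None
    classes: list = field(default_factory=list)
    positive_class: object = None
    metadata: dict = field(default_factory=dict)

    @property
    def is_deep(self) -> bool:
        return self.kind == "multi_cnn"

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError(f"{self.kind} model is not fitted")

    def predict_scores(self, bundle: DatasetBundle) -> np.ndarray:
        """Positive-class probability (classification) or predicted value
        (regression) for every sample in the bundle."""
        self._require_fitted()
        if self.is_deep:
            xs = bundle.arrays()
            if self.task == "classification":
                proba = self.net.predict_proba(xs)
                return proba[:, self.classes.index(self.positive_class)]
            return self.net.predict(xs)
        X = flatten_bundle(bundle).to_numpy()
        if self.task == "classification":
            proba = self.estimator.predict_proba(X)
            pos = list(self.estimator.classes_).index(self.positive_class)
            return proba[:, pos]
        return self.estimator.predict(X)

    def predict_labels(self, bundle: DatasetBundle) -> np.ndarray:
        self._require_fitted()
        if self.task == "regression":
            return self.predict_scores(bundle)
        if self.is_deep:
            proba = self.net.predict_proba(bundle.arrays())
            return np.asarray(self.classes)[proba.argmax(axis=1)]
        X = flatten_bundle(bundle).to_numpy()
        return self.estimator.predict(X)


def build_multi_cnn(spec: ModelSpec, input_shapes) -> ModelHandle:
    """Construct the multi-branch CNN for the given per-modality shapes.

    ``input_shapes`` is a list of (n_features, n_channels) pairs, one per
    modality, with 1 <= len <= 3. Rebuilding with the same spec and shapes
    yields identical initial weights.
    """
    input_shapes = list(input_shapes)
    if not 1 <= len(input_shapes) <= 3:
        raise ValueError(
            f"got {len(input_shapes)} modalities; the multi-CNN takes up to "
            "three omics types as input"
        )
    net = MultiBranchNet(
        input_shapes=input_shapes,
        task=spec.task,
        n_conv_layers=spec.n_conv_layers,
        filters=spec.filters,
        kernel_size=spec.kernel_size,
        pooling=spec.pooling,
        pool_size=spec.pool_size,
        dense_sizes=spec.dense_sizes,
        dropout=spec.dropout,
        leaky_slope=spec.leaky_slope,
        batch_norm=spec.batch_norm,
        seed=spec.seed,
    )
    loss = "cross_entropy" if spec.task == "classification" else "mean_squared_error"
    return ModelHandle(
        kind="multi_cnn",
        task=spec.task,
        spec=spec,
        net=net,
        metadata={"loss": loss, "optimizer": "adam"},
    )


def build_baseline(kind: str, task: str = "classification", params: dict | None = None) -> ModelHandle:
    """Construct one of the four classical baselines.

    Logistic regression carries an L2 penalty; the SVM uses an RBF kernel;
    tree and forest are nonparametric. Regression tasks swap in the natural
    counterparts (ridge, SVR, regression tree/forest).
    """
    params = dict(params or {})
    seed = params.pop("seed", 0)
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}")
    if task == "classification":
        makers = {
            # l1_ratio=0 is a pure L2 (ridge) penalty
            "logistic_l2": lambda: LogisticRegression(
                l1_ratio=0.0, max_iter=2000, **params
            ),
            "svm_rbf": lambda: SVC(kernel="rbf", probability=True, random_state=seed, **params),
            "decision_tree": lambda: DecisionTreeClassifier(random_state=seed, **params),
            "random_forest": lambda: RandomForestClassifier(random_state=seed, **params),
        }
        loss = "cross_entropy"
    else:
        makers = {
            "logistic_l2": lambda: Ridge(**params),
            "svm_rbf": lambda: SVR(kernel="rbf", **params),
            "decision_tree": lambda: DecisionTreeRegressor(random_state=seed, **params),
            "random_forest": lambda: RandomForestRegressor(random_state=seed, **params),
        }
        loss = "mean_squared_error"
    return ModelHandle(
        kind=kind,
        task=task,
        params={**params, "seed": seed},
        estimator=makers[kind](),
        metadata={"loss": loss},
    )


def clone_handle(handle: ModelHandle) -> ModelHandle:
    """A fresh, unfitted copy of a handle (same spec/params and seed)."""
    if handle.is_deep:
        return build_multi_cnn(handle.spec, handle.net.input_shapes)
    return build_baseline(handle.kind, handle.task, handle.params)


def flatten_bundle(bundle: DatasetBundle) -> pd.DataFrame:
    """Per sample, flatten each modality tensor feature-major (channels of a
    feature stay adjacent) and concatenate modalities in bundle order.

    Column labels are ``modality:feature`` for single-channel modalities and
    ``modality:feature:channel_symbol`` for one-hot ones, so baseline
    coefficients can be traced back to (modality, feature, channel).
    """
    blocks = []
    columns = []
    for enc in bundle.modalities:
        n, f, c = enc.tensor.shape
        blocks.append(enc.tensor.reshape(n, f * c))
        if c == 1:
            columns.extend(f"{enc.modality.name}:{feat}" for feat in enc.feature_ids)
        else:
            symbols = [str(s) for s in enc.modality.alphabet]
            columns.extend(
                f"{enc.modality.name}:{feat}:{sym}"
                for feat in enc.feature_ids
                for sym in symbols
            )
    return pd.DataFrame(
        np.concatenate(blocks, axis=1), index=bundle.sample_ids, columns=columns
    )


def bundle_layout(bundle: DatasetBundle) -> list:
    """(modality_name, feature_id, channel_symbol) per flattened column."""
    layout = []
    for enc in bundle.modalities:
        c = enc.tensor.shape[2]
        symbols = [str(s) for s in enc.modality.alphabet] if c > 1 else [None]
        for feat in enc.feature_ids:
            for sym in symbols:
                layout.append((enc.modality.name, feat, sym))
    return layout
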