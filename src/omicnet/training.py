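"""Data splitting, cross-validation, model fitting, metrics, and
hyperparameter search.

Splitting follows a 60/20/20 train/validation/test design (fractions are
configurable; remainder samples go to train first, then validation), with
stratification on by default for classification. Evaluation reports ROC/AUC
and precision-recall for categorical phenotypes, and the Pearson correlation
coefficient plus R-squared for quantitative ones; k-fold mode retrains per
fold and averages fold metrics. Hyperparameter search offers pure random
sampling and a sequential model-based (TPE-style) Bayesian mode that models
good and bad trial densities with Parzen estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    auc as sk_auc,
    log_loss,
    precision_recall_curve,
    r2_score,
    roc_curve,
)
from sklearn.model_selection import KFold, StratifiedKFold
from scipy.stats import pearsonr

from .models import ModelHandle, clone_handle, flatten_bundle
from .nn import Adam, cross_entropy_loss, mse_loss
from .preprocess import DatasetBundle


@dataclass
class SplitIndices:
    """Disjoint train/validation/test sample-ID lists."""

    train: list
    validation: list
    test: list
    fractions: tuple
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions overlap")


@dataclass
class FoldAssignment:
    """k-fold partition: sample_id -> fold index in 0..k-1."""

    k: int
    fold_of: dict
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [s for s, f in self.fold_of.items() if f == fold]

    def sizes(self) -> list:
        counts = [0] * self.k
        for f in self.fold_of.values():
            counts[f] += 1
        return counts


@dataclass
class LearningCurve:
    """Per-epoch training/validation loss (and metric) traces."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_metric: list = field(default_factory=list)
    metric_name: str = ""

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass
class MetricsReport:
    """Evaluation metrics for one split or averaged over folds."""

    task: str
    auc: float | None = None
    roc: tuple | None = None  # (fpr, tpr)
    pr: tuple | None = None  # (precision, recall)
    label_frequencies: dict = field(default_factory=dict)
    pcc: float | None = None
    r2: float | None = None
    per_fold: list = field(default_factory=list)

    @property
    def mean(self) -> dict:
        """Arithmetic mean of each per-fold metric."""
        if not self.per_fold:
            return {}
        keys = self.per_fold[0].keys()
        return {k: float(np.mean([f[k] for f in self.per_fold])) for k in keys}


@dataclass
class TuneResult:
    """Ordered trials, the best assignment found, and the best-so-far trace."""

    trials: list  # (assignment dict, objective value)
    best_params: dict
    best_value: float
    trace: list  # best-so-far objective after each trial
    direction: str
    seed: int


# ---------------------------------------------------------------------------
# splitting


def _partition_sizes(n: int, fractions) -> list:
    """floor(n*f) per partition; remainder distributed train-first."""
    sizes = [math.floor(n * f) for f in fractions]
    i = 0
    while sum(sizes) < n:
        sizes[i % len(sizes)] += 1
        i += 1
    return sizes


def split_dataset(
    bundle: DatasetBundle,
    fractions: tuple = (0.6, 0.2, 0.2),
    stratify: bool | None = None,
    seed: int = 0,
) -> SplitIndices:
    """Split a bundle's samples into train/validation/test.

    Partition sizes are floor(n * fraction) with the remainder given to
    train, then validation. Stratified mode (the default for classification)
    preserves each class's share of every partition to within one sample.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    ids = list(bundle.sample_ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    if stratify is None:
        stratify = bundle.phenotype.task == "classification"
    rng = np.random.default_rng(seed)
    sizes = _partition_sizes(n, fractions)

    if not stratify:
        perm = [ids[i] for i in rng.permutation(n)]
        train = perm[: sizes[0]]
        val = perm[sizes[0] : sizes[0] + sizes[1]]
        test = perm[sizes[0] + sizes[1] :]
        return SplitIndices(train, val, test, tuple(fractions), seed)

    labels = bundle.phenotype.labels
    by_class: dict = {}
    for s in ids:
        by_class.setdefault(labels.loc[s], []).append(s)
    for cls, members in by_class.items():
        if len(members) < 3:
            raise ValueError(
                f"class {cls!r} has only {len(members)} samples; stratified "
                "splitting needs >= 3 per class"
            )
    # per-class proportional quotas with exact global partition sizes:
    # start from floors, then hand out the remaining slots cell-by-cell in
    # decreasing order of fractional remainder.
    classes = sorted(by_class, key=str)
    quotas = {c: [math.floor(len(by_class[c]) * f) for f in fractions] for c in classes}
    row_deficit = {c: len(by_class[c]) - sum(quotas[c]) for c in classes}
    col_deficit = [sizes[p] - sum(quotas[c][p] for c in classes) for p in range(3)]
    cells = sorted(
        ((c, p) for c in classes for p in range(3)),
        key=lambda cp: (
            -(len(by_class[cp[0]]) * fractions[cp[1]] % 1.0),
            cp[1],
            str(cp[0]),
        ),
    )
    while sum(row_deficit.values()) > 0:
        progressed = False
        for c, p in cells:
            if row_deficit[c] > 0 and col_deficit[p] > 0:
                quotas[c][p] += 1
                row_deficit[c] -= 1
                col_deficit[p] -= 1
                progressed = True
        if not progressed:  # pragma: no cover - deficits always reducible
            raise RuntimeError("stratified quota allocation failed")
    parts: list = [[], [], []]
    for c in classes:
        members = list(by_class[c])
        members = [members[i] for i in rng.permutation(len(members))]
        start = 0
        for p in range(3):
            parts[p].extend(members[start : start + quotas[c][p]])
            start += quotas[c][p]
    return SplitIndices(parts[0], parts[1], parts[2], tuple(fractions), seed)


def make_folds(
    bundle: DatasetBundle, k: int = 5, stratify: bool | None = None, seed: int = 0
) -> FoldAssignment:
    """Assign every sample to one of k folds (sizes differ by at most 1)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    ids = np.asarray(bundle.sample_ids)
    if len(ids) < k:
        raise ValueError(f"cannot make {k} folds from {len(ids)} samples")
    if stratify is None:
        stratify = bundle.phenotype.task == "classification"
    if stratify:
        labels = bundle.phenotype.labels.loc[ids].to_numpy()
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(ids, labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(ids)
    fold_of = {}
    for fold, (_, test_idx) in enumerate(splits):
        for i in test_idx:
            fold_of[ids[i]] = fold
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


# ---------------------------------------------------------------------------
# fitting


def _class_indices(handle: ModelHandle, labels) -> np.ndarray:
    return np.asarray([handle.classes.index(l) for l in labels])


def train_model(
    handle: ModelHandle,
    bundle: DatasetBundle,
    split: SplitIndices,
    positive_class=None,
) -> tuple:
    """Fit a model on the train partition; returns (handle, LearningCurve).

    The multi-CNN trains with mini-batch Adam, recording training loss and
    validation loss/metric every epoch; classical baselines fit in one shot
    and yield a single-point curve. A NaN loss aborts with a diagnostic.
    """
    if handle.fitted:
        raise ValueError("model is already fitted; clone it to retrain")
    train_bundle = bundle.subset(split.train)
    val_bundle = bundle.subset(split.validation) if split.validation else None
    labels = bundle.phenotype.labels

    if handle.task == "classification":
        classes = sorted(set(labels), key=str)
        if positive_class is None:
            positive_class = "LTS" if "LTS" in classes else classes[-1]
        handle.classes = classes
        handle.positive_class = positive_class
    curve = LearningCurve(
        metric_name="auc" if handle.task == "classification" else "mse"
    )

    if not handle.is_deep:
        X = flatten_bundle(train_bundle).to_numpy()
        y = train_bundle.phenotype.labels.to_numpy()
        handle.estimator.fit(X, y)
        handle.fitted = True
        scores = handle.predict_scores(train_bundle)
        if handle.task == "classification":
            y_bin = (y == handle.positive_class).astype(int)
            curve.train_loss.append(log_loss(y_bin, scores, labels=[0, 1]))
        else:
            curve.train_loss.append(float(np.mean((scores - y.astype(float)) ** 2)))
        return handle, curve

    spec = handle.spec
    net = handle.net
    opt = Adam(net, lr=spec.learning_rate, weight_decay=spec.weight_decay)
    rng = np.random.default_rng(spec.seed + 10_000)
    xs_train = train_bundle.arrays()
    n = train_bundle.n_samples
    if handle.task == "classification":
        y_train = _class_indices(handle, train_bundle.phenotype.labels)
    else:
        y_train = train_bundle.phenotype.labels.to_numpy(dtype=float)

    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            if len(idx) < 2 and spec.batch_norm and len(idx) < n:
                continue  # batch statistics are undefined on a single sample
            batch_xs = [x[idx] for x in xs_train]
            net.zero_grad()
            logits = net.forward(batch_xs, train=True)
            if handle.task == "classification":
                loss, dlogits = cross_entropy_loss(logits, y_train[idx])
            else:
                loss, dlogits = mse_loss(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch + 1}; reduce the "
                    "learning rate or check the input encoding"
                )
            net.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
        curve.train_loss.append(float(np.mean(epoch_losses)))
        if val_bundle is not None:
            handle.fitted = True
            val_metrics = _holdout_losses(handle, val_bundle)
            handle.fitted = False
            curve.val_loss.append(val_metrics[0])
            curve.val_metric.append(val_metrics[1])
    handle.fitted = True
    return handle, curve


def _holdout_losses(handle: ModelHandle, holdout: DatasetBundle) -> tuple:
    scores = handle.predict_scores(holdout)
    y = holdout.phenotype.labels.to_numpy()
    if handle.task == "classification":
        y_bin = (y == handle.positive_class).astype(int)
        loss = log_loss(y_bin, np.clip(scores, 1e-12, 1 - 1e-12), labels=[0, 1])
        metric = (
            binary_auc(y_bin, scores) if len(np.unique(y_bin)) == 2 else float("nan")
        )
        return float(loss), float(metric)
    mse = float(np.mean((scores - y.astype(float)) ** 2))
    return mse, mse


# ---------------------------------------------------------------------------
# metrics


def binary_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by threshold sweep over unique scores + trapezoid rule."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(sk_auc(fpr, tpr))


def evaluate_model(
    trained: ModelHandle,
    bundle: DatasetBundle,
    indices=None,
    folds: FoldAssignment | None = None,
) -> MetricsReport:
    """Evaluate on a held-out index list, or k-fold retrain-and-average.

    Single mode scores the already-fitted model on ``indices`` (default: all
    bundle samples). Fold mode ignores the fitted state: for each fold a
    fresh clone is trained on the remaining folds and evaluated on the held
    fold; per-fold metrics and their arithmetic mean are reported.
    """
    if folds is not None:
        return _cross_validate(trained, bundle, folds)
    trained._require_fitted()
    if trained.task == "classification":
        truth = (
            bundle.phenotype.labels.loc[list(indices)]
            if indices is not None
            else bundle.phenotype.labels
        )
        if truth.nunique() < 2:
            raise ValueError("AUC is undefined on single-class truth")
    eval_bundle = bundle.subset(list(indices)) if indices is not None else bundle
    scores = trained.predict_scores(eval_bundle)
    y = eval_bundle.phenotype.labels.to_numpy()
    if trained.task == "classification":
        y_bin = (y == trained.positive_class).astype(int)
        fpr, tpr, _ = roc_curve(y_bin, scores)
        precision, recall, _ = precision_recall_curve(y_bin, scores)
        predicted = trained.predict_labels(eval_bundle)
        freq = {
            "true": {str(k): int(v) for k, v in zip(*np.unique(y, return_counts=True))},
            "predicted": {
                str(k): int(v) for k, v in zip(*np.unique(predicted, return_counts=True))
            },
        }
        return MetricsReport(
            task="classification",
            auc=float(sk_auc(fpr, tpr)),
            roc=(fpr, tpr),
            pr=(precision, recall),
            label_frequencies=freq,
        )
    y = y.astype(float)
    pcc = float(pearsonr(y, scores)[0]) if len(y) > 1 else float("nan")
    return MetricsReport(task="regression", pcc=pcc, r2=float(r2_score(y, scores)))


def _cross_validate(
    prototype: ModelHandle, bundle: DatasetBundle, folds: FoldAssignment
) -> MetricsReport:
    per_fold = []
    ids = bundle.sample_ids
    for fold in range(folds.k):
        test_ids = [s for s in ids if folds.fold_of[s] == fold]
        train_ids = [s for s in ids if folds.fold_of[s] != fold]
        handle = clone_handle(prototype)
        split = SplitIndices(train_ids, [], test_ids, (0.0, 0.0, 0.0), folds.seed)
        handle, _ = train_model(handle, bundle, split)
        report = evaluate_model(handle, bundle, indices=test_ids)
        if bundle.phenotype.task == "classification":
            per_fold.append({"auc": report.auc})
        else:
            per_fold.append({"pcc": report.pcc, "r2": report.r2})
    out = MetricsReport(task=bundle.phenotype.task, per_fold=per_fold)
    if bundle.phenotype.task == "classification":
        out.auc = out.mean["auc"]
    else:
        out.pcc, out.r2 = out.mean["pcc"], out.mean["r2"]
    return out


# ---------------------------------------------------------------------------
# hyperparameter search


def _sample_uniform(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, domain in space.items():
        if isinstance(domain, list):
            out[name] = domain[rng.integers(len(domain))]
        else:
            kind, low, high = _domain(domain)
            if kind == "int":
                out[name] = int(rng.integers(low, high + 1))
            else:
                out[name] = float(rng.uniform(low, high))
    return out


def _domain(domain) -> tuple:
    if len(domain) == 3 and domain[0] in ("int", "float"):
        return domain[0], domain[1], domain[2]
    low, high = domain
    return "float", low, high


def _build_parzen(points, low: float, high: float):
    """Adaptive Parzen estimator: one Gaussian per observation plus a wide
    prior component at the domain midpoint.

    Each center's bandwidth is its larger gap to the adjacent sorted
    neighbors, clipped below by width / min(100, 1 + n) so the mixture can
    sharpen as evidence accumulates without ever collapsing to a spike.
    """
    width = high - low
    mus = np.sort(np.append(np.asarray(points, dtype=float), 0.5 * (low + high)))
    n = len(mus)
    if n == 1:
        sigmas = np.array([width], dtype=float)
    else:
        left = np.diff(mus, prepend=mus[0] - (mus[1] - mus[0]))
        right = np.diff(mus, append=mus[-1] + (mus[-1] - mus[-2]))
        sigmas = np.maximum(left, right)
    floor = width / min(100.0, 1.0 + n)
    return mus, np.clip(sigmas, floor, width)


def _mixture_logpdf(x: np.ndarray, mus: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    z = (x[:, None] - mus[None, :]) / sigmas[None, :]
    dens = (np.exp(-0.5 * z * z) / (sigmas[None, :] * np.sqrt(2 * np.pi))).mean(axis=1)
    return np.log(dens + 1e-300)


def tune_hyperparameters(
    space: dict,
    objective,
    n_trials: int = 50,
    seed: int = 0,
    mode: str = "bayesian",
    direction: str = "minimize",
    n_startup: int = 10,
    n_candidates: int = 24,
    gamma: float = 0.1,
) -> TuneResult:
    """Sequential hyperparameter search over named ranges.

    ``space`` maps parameter names to (low, high) float ranges,
    ("int", low, high) integer ranges, or lists of categorical choices.
    Bayesian mode is a tree-structured-Parzen-style optimizer: after
    ``n_startup`` random trials it splits observations into a good fraction
    (``gamma``) and the rest, models each with a Parzen density, and picks
    the candidate maximizing the good/bad density ratio. The best-so-far
    trace is monotone, and a fixed seed reproduces the trial sequence.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not space:
        raise ValueError("search space is empty")
    if mode not in ("bayesian", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    if direction not in ("minimize", "maximize"):
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    sign = 1.0 if direction == "minimize" else -1.0
    trials: list = []
    failures = 0
    for t in range(n_trials):
        completed = [(a, v) for a, v in trials if np.isfinite(v)]
        if mode == "random" or t < n_startup or len(completed) < n_startup:
            assignment = _sample_uniform(space, rng)
        else:
            assignment = _tpe_propose(space, completed, sign, rng, n_candidates, gamma)
        try:
            value = float(objective(assignment))
        except Exception:
            failures += 1
            trials.append((assignment, float("nan")))
            continue
        trials.append((assignment, value))
    finished = [(a, v) for a, v in trials if np.isfinite(v)]
    if not finished:
        raise RuntimeError(
            f"objective failed on all {n_trials} trials ({failures} exceptions)"
        )
    best_params, best_value = min(finished, key=lambda av: sign * av[1])
    trace = []
    best = None
    for _, v in trials:
        if np.isfinite(v) and (best is None or sign * v < sign * best):
            best = v
        trace.append(best)
    return TuneResult(
        trials=trials,
        best_params=dict(best_params),
        best_value=best_value,
        trace=trace,
        direction=direction,
        seed=seed,
    )


def _tpe_propose(space, completed, sign, rng, n_candidates, gamma) -> dict:
    values = np.array([sign * v for _, v in completed])
    order = np.argsort(values, kind="stable")
    n_good = max(2, math.ceil(gamma * len(completed)))
    good_idx = set(order[:n_good].tolist())
    out = {}
    for name, domain in space.items():
        good = [completed[i][0][name] for i in range(len(completed)) if i in good_idx]
        bad = [completed[i][0][name] for i in range(len(completed)) if i not in good_idx]
        if isinstance(domain, list):
            choices = list(domain)
            counts_g = np.array([good.count(c) + 1.0 for c in choices])
            counts_b = np.array([bad.count(c) + 1.0 for c in choices])
            score = np.log(counts_g / counts_g.sum()) - np.log(counts_b / counts_b.sum())
            probs = counts_g / counts_g.sum()
            cand_idx = rng.choice(len(choices), size=n_candidates, p=probs)
            best = cand_idx[np.argmax(score[cand_idx])]
            out[name] = choices[best]
            continue
        kind, low, high = _domain(domain)
        gm, gs = _build_parzen(good, low, high)
        bm, bs = _build_parzen(bad if bad else [], low, high)
        idx = rng.integers(len(gm), size=n_candidates)
        cand = np.clip(gm[idx] + rng.normal(0.0, 1.0, n_candidates) * gs[idx], low, high)
        score = _mixture_logpdf(cand, gm, gs) - _mixture_logpdf(cand, bm, bs)
        pick = float(cand[np.argmax(score)])
        out[name] = int(round(pick)) if kind == "int" else pick
    return out
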