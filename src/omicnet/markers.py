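"""Saliency-based biomarker scoring, dense ranking, and gene mapping.

A feature's saliency is the mean over samples of the maximum over input
channels of the absolute gradient of the model score with respect to that
feature — the gradient is taken at the pre-softmax logit of the target class
so softmax saturation cannot flatten the signal. Classical baselines
contribute importances through their coefficients (or impurity importances)
instead. Saliencies convert to dense ranks (rank 1 = highest; ties share a
rank, ranks stay consecutive), top markers are selected tie-inclusively, and
markers with genomic positions map onto gene intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .models import ModelHandle, bundle_layout
from .omics_io import GeneAnnotation
from .preprocess import DatasetBundle


@dataclass
class SaliencyProfile:
    """Per-(modality, feature) non-negative importance scores."""

    scores: pd.DataFrame  # columns: modality, feature_id, saliency
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.scores
        required = {"modality", "feature_id", "saliency"}
        if required - set(df.columns):
            raise ValueError(f"profile needs columns {sorted(required)}")
        if df.duplicated(subset=["modality", "feature_id"]).any():
            raise ValueError("duplicate (modality, feature) in saliency profile")
        vals = df["saliency"].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("saliency values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class RankTable:
    """Saliency scores with dense ranks, sorted by decreasing saliency."""

    records: pd.DataFrame  # modality, feature_id, saliency, dense_rank


@dataclass
class MarkerSet:
    """Selected top markers and the rule that produced them."""

    records: pd.DataFrame
    rule: str


def compute_saliency(
    trained: ModelHandle,
    bundle: DatasetBundle,
    target: str | int = "predicted",
    channel_agg: str = "max",
    sample_agg: str = "mean",
) -> SaliencyProfile:
    """Gradient saliency of the multi-CNN over a sample set.

    ``target`` selects whose score is differentiated: "predicted" uses each
    sample's own predicted class; an integer selects a fixed class index
    (classification only). Per feature, the absolute input gradient is
    aggregated over channels (max by default — the strongest allele/state
    signal) and then over samples (mean by default).
    """
    if not trained.is_deep:
        raise ValueError(
            "saliency maps require the multi-CNN; use coefficient_importance "
            "for classical baselines"
        )
    trained._require_fitted()
    names = [m.modality.name for m in bundle.modalities]
    expected = [m.modality.name for m in bundle.modalities]
    if len(bundle.modalities) != len(trained.net.input_shapes):
        raise ValueError("bundle modalities do not match the trained network")
    class_index = None if target == "predicted" else int(target)
    grads = trained.net.input_gradients(bundle.arrays(), class_index=class_index)
    rows = []
    ch_fn = np.max if channel_agg == "max" else np.mean
    s_fn = np.mean if sample_agg == "mean" else np.max
    for enc, g in zip(bundle.modalities, grads):
        per_feature = s_fn(ch_fn(np.abs(g), axis=2), axis=0)
        for feat, val in zip(enc.feature_ids, per_feature):
            rows.append((enc.modality.name, feat, float(val)))
    return SaliencyProfile(
        scores=pd.DataFrame(rows, columns=["modality", "feature_id", "saliency"]),
        provenance={
            "model": trained.kind,
            "n_samples": bundle.n_samples,
            "target": target,
            "channel_agg": channel_agg,
            "sample_agg": sample_agg,
        },
    )


def coefficient_importance(trained: ModelHandle, bundle: DatasetBundle) -> SaliencyProfile:
    """Feature importance from a fitted classical baseline.

    Linear models contribute |coefficient| per flattened input column,
    aggregated back to (modality, feature) by the maximum over one-hot
    channels; trees and forests contribute impurity-based importances
    aggregated the same way. The RBF-kernel SVM exposes no per-feature
    coefficients and is rejected.
    """
    if trained.is_deep:
        raise ValueError("use compute_saliency for the multi-CNN")
    trained._require_fitted()
    est = trained.estimator
    if hasattr(est, "coef_"):
        flat = np.abs(np.asarray(est.coef_)).reshape(-1)
    elif hasattr(est, "feature_importances_"):
        flat = np.asarray(est.feature_importances_, dtype=float)
    else:
        raise ValueError(
            f"{trained.kind} exposes neither coefficients nor impurity "
            "importances (the RBF kernel is not linearizable)"
        )
    layout = bundle_layout(bundle)
    if len(flat) != len(layout):
        raise ValueError(
            f"importance length {len(flat)} does not match bundle layout {len(layout)}"
        )
    agg: dict = {}
    for (modality, feat, _channel), v in zip(layout, flat):
        key = (modality, feat)
        agg[key] = max(agg.get(key, 0.0), float(v))
    rows = [(m, f, v) for (m, f), v in agg.items()]
    return SaliencyProfile(
        scores=pd.DataFrame(rows, columns=["modality", "feature_id", "saliency"]),
        provenance={"model": trained.kind, "aggregation": "max-over-channels"},
    )


def dense_rank(profile: SaliencyProfile) -> RankTable:
    """Dense-rank saliencies: rank 1 is the largest value, ties share a
    rank, and ranks are consecutive integers."""
    if len(profile) == 0:
        raise ValueError("cannot rank an empty saliency profile")
    df = profile.scores.copy()
    df["dense_rank"] = (
        df["saliency"].rank(method="dense", ascending=False).astype(int)
    )
    df = df.sort_values(
        ["dense_rank", "modality", "feature_id"], kind="stable"
    ).reset_index(drop=True)
    return RankTable(records=df)


def select_top_markers(
    table: RankTable, k: int | None = None, saliency_threshold: float | None = None
) -> MarkerSet:
    """Select markers by top-k rank (tie-inclusive) or saliency threshold.

    Top-k keeps every record whose dense rank is at or above the rank of the
    k-th record, so ties at the boundary are all retained and the result may
    exceed k. Threshold mode keeps records with saliency >= the threshold.
    """
    df = table.records
    if (k is None) == (saliency_threshold is None):
        raise ValueError("specify exactly one of k or saliency_threshold")
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > len(df):
            warnings.warn(
                f"requested top {k} of {len(df)} markers; returning the whole table",
                stacklevel=2,
            )
            return MarkerSet(records=df.copy(), rule=f"top_k={k}")
        cutoff_rank = int(df["dense_rank"].iloc[k - 1])
        return MarkerSet(
            records=df[df["dense_rank"] <= cutoff_rank].copy(), rule=f"top_k={k}"
        )
    if not np.isfinite(saliency_threshold):
        raise ValueError("saliency_threshold must be finite")
    return MarkerSet(
        records=df[df["saliency"] >= saliency_threshold].copy(),
        rule=f"saliency>={saliency_threshold}",
    )


def _interval_distance(pos: int, start: int, end: int) -> int:
    """Distance from a point to a 0-based half-open interval (0 inside)."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def map_markers_to_genes(
    markers: MarkerSet,
    positions: Mapping[str, tuple],
    annotation: GeneAnnotation,
    mode: str = "overlap",
    max_distance: int = 0,
) -> pd.DataFrame:
    """Assign markers to genes by chromosomal position.

    Overlap mode assigns a marker to every gene interval containing its
    position; nearest mode assigns it to the closest gene within
    ``max_distance`` bp. The result is one row per gene with the best
    (minimum) dense rank among its markers; markers lacking a position or a
    matching chromosome are reported in the ``unmapped`` attribute rather
    than raising.
    """
    if mode not in ("overlap", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom = annotation.by_chromosome()
    assignments: dict = {}
    unmapped = []
    # deterministic regardless of marker input order
    records = markers.records.sort_values(
        ["modality", "feature_id"], kind="stable"
    )
    for _, row in records.iterrows():
        feat = row["feature_id"]
        if feat not in positions:
            unmapped.append((feat, "no position record"))
            continue
        chrom, pos = positions[feat]
        genes = by_chrom.get(str(chrom))
        if genes is None:
            unmapped.append((feat, f"unknown chromosome {chrom!r}"))
            continue
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        gene_ids = genes["gene_id"].to_numpy()
        if mode == "overlap":
            hits = gene_ids[(start <= pos) & (pos < end)]
        else:
            dist = np.array(
                [_interval_distance(int(pos), int(s), int(e)) for s, e in zip(start, end)]
            )
            best = dist.min() if len(dist) else None
            hits = gene_ids[dist == best] if best is not None and best <= max_distance else []
        if len(hits) == 0:
            unmapped.append((feat, "no gene within reach"))
            continue
        for gid in hits:
            entry = assignments.setdefault(gid, {"ranks": [], "markers": []})
            entry["ranks"].append(int(row["dense_rank"]))
            entry["markers"].append(feat)
    rows = [
        {
            "gene_id": gid,
            "best_rank": min(e["ranks"]),
            "n_markers": len(e["markers"]),
            "marker_ids": ";".join(sorted(e["markers"])),
        }
        for gid, e in assignments.items()
    ]
    out = pd.DataFrame(rows, columns=["gene_id", "best_rank", "n_markers", "marker_ids"])
    if len(out):
        out = out.sort_values(["best_rank", "gene_id"], kind="stable").reset_index(drop=True)
    out.attrs["unmapped"] = unmapped
    return out
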