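"""Encoding, normalization, cohort labeling, and modality merging.

Continuous modalities are z-scored per sample over their observed entries
(missing values become 0 afterwards — the row mean in z-space). Categorical
modalities (SNP genotypes, gene-level CNV states) are one-hot encoded over
their fixed alphabets, with a dedicated channel for missing SNP genotypes.
Up to three encoded modalities are merged into a :class:`DatasetBundle`,
the model input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .omics_io import (
    CANONICAL_ORDER,
    SNP_MISSING,
    GeneAnnotation,
    OmicsMatrix,
    OmicsType,
    PhenotypeTable,
    SurvivalTable,
    get_modality,
)


@dataclass
class EncodedModality:
    """A modality encoded as a samples x features x channels tensor.

    Continuous modalities use a single channel; categorical ones use one
    channel per alphabet symbol, so each (sample, feature) channel vector is
    a unit basis vector.
    """

    modality: OmicsType
    sample_ids: list
    feature_ids: list
    tensor: np.ndarray

    def __post_init__(self) -> None:
        n, f = len(self.sample_ids), len(self.feature_ids)
        if self.tensor.shape[:2] != (n, f):
            raise ValueError(
                f"tensor shape {self.tensor.shape} does not match "
                f"{n} samples x {f} features"
            )

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[2]

    def subset(self, sample_ids: Sequence[str]) -> "EncodedModality":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return EncodedModality(
            modality=self.modality,
            sample_ids=list(sample_ids),
            feature_ids=self.feature_ids,
            tensor=self.tensor[idx],
        )


@dataclass
class DatasetBundle:
    """1-3 aligned encoded modalities plus the phenotype they predict."""

    modalities: list
    phenotype: PhenotypeTable
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.modalities) <= 3:
            raise ValueError(
                f"a bundle takes 1-3 modalities, got {len(self.modalities)} "
                "(models accept combinations of up to three omics types)"
            )
        first = self.modalities[0].sample_ids
        for enc in self.modalities[1:]:
            if enc.sample_ids != first:
                raise ValueError("bundle modalities disagree on sample order")
        covered = set(self.phenotype.sample_ids)
        missing = [s for s in first if s not in covered]
        if missing:
            raise ValueError(f"phenotype lacks samples {missing[:3]}")
        # restrict + order phenotype to the bundle's samples
        self.phenotype = PhenotypeTable(
            labels=self.phenotype.labels.loc[first], task=self.phenotype.task
        )

    @property
    def sample_ids(self) -> list:
        return self.modalities[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def input_shapes(self) -> list:
        return [(len(m.feature_ids), m.n_channels) for m in self.modalities]

    def arrays(self) -> list:
        return [m.tensor for m in self.modalities]

    def subset(self, sample_ids: Sequence[str]) -> "DatasetBundle":
        return DatasetBundle(
            modalities=[m.subset(sample_ids) for m in self.modalities],
            phenotype=self.phenotype,
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class ModalityCombination:
    """An ordered subset of modality names used jointly as model input."""

    names: tuple

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("a combination needs at least one modality")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"repeated modality in combination {self.names}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    @property
    def label(self) -> str:
        return "+".join(self.names)


# ---------------------------------------------------------------------------
# operations


def zscore_normalize(matrix: OmicsMatrix, axis: str = "sample") -> OmicsMatrix:
    """Z-score a continuous modality, by default per sample across features.

    Each row's observed (non-missing) entries are transformed to
    ``(x - mean) / sd`` with the population standard deviation of that row;
    missing entries are then set to 0, and zero-variance rows become all 0.
    ``axis="feature"`` applies the same rule per column instead.
    """
    if not matrix.modality.is_continuous:
        raise ValueError(
            f"z-score normalization applies to continuous modalities, "
            f"not {matrix.modality.name}"
        )
    if axis not in ("sample", "feature"):
        raise ValueError(f"axis must be 'sample' or 'feature', got {axis!r}")
    vals = matrix.values.astype(float).to_numpy(copy=True)
    observed = ~matrix.missing_mask.to_numpy() & ~np.isnan(vals)
    vals[~observed] = np.nan
    ax = 1 if axis == "sample" else 0
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(observed, vals, np.nan), axis=ax, keepdims=True)
        sd = np.nanstd(np.where(observed, vals, np.nan), axis=ax, keepdims=True)
    out = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    out[~observed] = 0.0  # missing -> 0 == the row mean in z-space
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return OmicsMatrix(
        modality=matrix.modality, values=df, missing_mask=matrix.missing_mask.copy()
    )


def encode_continuous(matrix: OmicsMatrix) -> EncodedModality:
    """Wrap a (normalized) continuous matrix as a single-channel tensor."""
    if not matrix.modality.is_continuous:
        raise ValueError(f"{matrix.modality.name} is not continuous")
    vals = matrix.values.astype(float).to_numpy(copy=True)
    vals[np.isnan(vals)] = 0.0
    return EncodedModality(
        modality=matrix.modality,
        sample_ids=matrix.sample_ids,
        feature_ids=matrix.feature_ids,
        tensor=vals[:, :, None],
    )


def encode_categorical(matrix: OmicsMatrix) -> EncodedModality:
    """One-hot encode a SNP or CNV matrix over its fixed alphabet.

    Channel order follows the modality alphabet; every cell becomes a unit
    basis vector. Missing SNP genotypes activate the dedicated missing
    channel; missing CNV cells map to the diploid-normal (0) channel, the
    neutral state, since the five-level CNV alphabet carries no missing
    symbol and CNV data undergoes no imputation upstream.
    """
    modality = matrix.modality
    if modality.is_continuous:
        raise ValueError(f"{modality.name} is not categorical")
    alphabet = list(modality.alphabet)
    channel_of = {sym: i for i, sym in enumerate(alphabet)}
    n, f = matrix.shape
    tensor = np.zeros((n, f, len(alphabet)), dtype=float)
    vals = matrix.values.to_numpy()
    mask = matrix.missing_mask.to_numpy()
    if modality.name == "cnv":
        fallback = channel_of[0]  # diploid normal copy
    else:
        fallback = channel_of[SNP_MISSING]
    for j, feat in enumerate(matrix.feature_ids):
        for i, sample in enumerate(matrix.sample_ids):
            if mask[i, j]:
                tensor[i, j, fallback] = 1.0
                continue
            cell = vals[i, j]
            if cell not in channel_of:
                raise ValueError(
                    f"symbol {cell!r} at ({sample}, {feat}) is outside the "
                    f"{modality.name} alphabet {alphabet}"
                )
            tensor[i, j, channel_of[cell]] = 1.0
    return EncodedModality(
        modality=modality,
        sample_ids=matrix.sample_ids,
        feature_ids=matrix.feature_ids,
        tensor=tensor,
    )


def encode_modality(matrix: OmicsMatrix, normalize: bool = True) -> EncodedModality:
    """Encode either kind of modality (z-scoring continuous ones first)."""
    if matrix.modality.is_continuous:
        return encode_continuous(zscore_normalize(matrix) if normalize else matrix)
    return encode_categorical(matrix)


def filter_cpg(
    matrix: OmicsMatrix,
    annotation: GeneAnnotation,
    cpg_positions: Mapping[str, tuple],
    promoter_window: int = 2000,
) -> OmicsMatrix:
    """Keep only CpG features inside a gene or its promoter.

    A CpG at (chromosome, position) is retained when its position lies inside
    a gene interval, or within ``promoter_window`` bp upstream of the gene's
    strand-aware start. Positions are 0-based.
    """
    if matrix.modality.name != "dna_methylation":
        raise ValueError("CpG filtering applies to dna_methylation matrices")
    by_chrom = annotation.by_chromosome()
    keep = []
    for feat in matrix.feature_ids:
        if feat not in cpg_positions:
            raise ValueError(f"CpG feature {feat!r} has no position record")
        chrom, pos = cpg_positions[feat]
        genes = by_chrom.get(str(chrom))
        if genes is None:
            continue
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        strand = genes["strand"].to_numpy()
        inside = (start <= pos) & (pos < end)
        prom_fwd = (strand == "+") & (start - promoter_window <= pos) & (pos < start)
        prom_rev = (strand == "-") & (end <= pos) & (pos < end + promoter_window)
        if (inside | prom_fwd | prom_rev).any():
            keep.append(feat)
    return OmicsMatrix(
        modality=matrix.modality,
        values=matrix.values[keep],
        missing_mask=matrix.missing_mask[keep],
    )


def merge_modalities(
    modalities: Sequence[EncodedModality],
    phenotype: PhenotypeTable,
    provenance: str = "",
) -> DatasetBundle:
    """Inner-join 1-3 encoded modalities and the phenotype on sample IDs.

    The resulting sample order is the first modality's order restricted to
    the common intersection.
    """
    if not 1 <= len(modalities) <= 3:
        raise ValueError(
            f"got {len(modalities)} modalities; models accept combinations "
            "of up to three omics types"
        )
    common = set(modalities[0].sample_ids)
    for enc in modalities[1:]:
        common &= set(enc.sample_ids)
    common &= set(phenotype.sample_ids)
    ordered = [s for s in modalities[0].sample_ids if s in common]
    if not ordered:
        raise ValueError("no samples shared across all modalities and the phenotype")
    label = provenance or "+".join(m.modality.name for m in modalities)
    return DatasetBundle(
        modalities=[m.subset(ordered) for m in modalities],
        phenotype=phenotype,
        provenance=label,
    )


def enumerate_combinations(
    available: Iterable[str | OmicsType], max_order: int = 3
) -> list:
    """All modality subsets of size 1..max_order, in deterministic order.

    Order is lexicographic over the canonical modality ordering (expression
    modalities first, then SNP, then CNV), sizes ascending: six modalities at
    max order 3 give 6 + 15 + 20 = 41 combinations.
    """
    names = [get_modality(m).name for m in available]
    if not names:
        raise ValueError("no modalities supplied")
    if len(set(names)) != len(names):
        raise ValueError("repeated modality in available list")
    if max_order < 1:
        raise ValueError(f"max_order must be >= 1, got {max_order}")
    canon = {name: i for i, name in enumerate(CANONICAL_ORDER)}
    names = sorted(names, key=lambda n: canon[n])
    out = []
    for k in range(1, min(max_order, len(names)) + 1):
        for combo in itertools.combinations(names, k):
            out.append(ModalityCombination(names=combo))
    return out


def label_cohort(
    survival: SurvivalTable, threshold_years: float = 3.0
) -> PhenotypeTable:
    """Derive long-term-survival labels from survival records.

    LTS means survival strictly greater than ``threshold_years`` after
    diagnosis; non-LTS means observed death at or before the threshold.
    Samples censored at or before the threshold are excluded (their class is
    unknowable); samples censored beyond it are LTS — they are known to have
    survived past the threshold.
    """
    df = survival.data
    time = df["survival_time"]
    event = df["event"]
    excluded = (event == 0) & (time <= threshold_years)
    labels = pd.Series(
        np.where(time > threshold_years, "LTS", "non-LTS"),
        index=df.index,
    )[~excluded]
    return PhenotypeTable(labels=labels, task="classification")
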