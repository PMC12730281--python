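"""Seeded synthetic multi-omics cohorts with planted phenotype drivers.

The generator emulates the data model the pipeline expects: continuous
expression-like matrices, SNP genotype matrices over {A, C, G, T, missing},
and five-state gene-level CNV matrices, all keyed by shared sample IDs. A
small set of planted features drives the phenotype through a linear
predictor on the *encoded* values (z-space for continuous features, one-hot
state indicators for categorical ones, centered so the cohort stays roughly
balanced), optionally with pairwise interactions. Binary labels follow a
logistic model on the predictor; survival times are exponential with a rate
shrinking in the predictor, with independent exponential censoring. A
matching annotation/gene-set generator tiles non-overlapping gene intervals
along synthetic chromosomes, positions every feature inside a host gene,
and plants one pathway containing exactly the host genes of the planted
features, so marker mapping and over-representation analysis can be tested
end to end against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .omics_io import (
    GeneAnnotation,
    GeneSetCollection,
    OmicsMatrix,
    PhenotypeTable,
    SurvivalTable,
    get_modality,
)

_ACGT = ("A", "C", "G", "T")


#: Default driver positions as fractions of the feature axis: 4 expression,
#: 3 SNP, 3 CNV drivers on disjoint host genes, well separated so
#: convolutional smearing cannot merge them. At 500 features per modality
#: these land on indices 10/60/110/160, 210/260/310, and 410/440/470.
_PLANTED_FRACTIONS = {
    "gene_expression": (0.02, 0.12, 0.22, 0.32),
    "snp": (0.42, 0.52, 0.62),
    "cnv": (0.82, 0.88, 0.94),
}
_DEFAULT_EFFECT = 1.5


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults: 200 samples over three modalities (gene expression, SNP, CNV)
    with 500 features each, 10 planted features at effect size 1.5, one
    interaction pair at strength 1.0, unit noise, 2% missing cells in
    expression and SNP data, and survival with a 3-year baseline median.
    """

    n_samples: int = 200
    modalities: tuple = ("gene_expression", "snp", "cnv")
    n_features: int | dict = 500
    planted: dict | None = None  # None -> scaled default allocation
    interactions: list | None = None  # None -> first two expression drivers
    noise_sd: float = 1.0
    snp_maf_range: tuple = (0.1, 0.5)
    cnv_state_probs: tuple = (0.05, 0.15, 0.6, 0.15, 0.05)
    missing_cell_rate: float = 0.02
    missing_modality_pattern: str = "uniform"  # "uniform" | "non-uniform"
    non_uniform_missing_fraction: float = 0.15
    survival_baseline_rate: float = math.log(2.0) / 3.0  # median 3 years at eta=0
    survival_effect_scale: float = 1.0
    censoring_rate: float = 0.08
    n_random_pathways: int = 49
    random_pathway_size: int = 20
    genes_per_chromosome: int = 100
    seed: int = 0

    def features_of(self, modality: str) -> int:
        if isinstance(self.n_features, dict):
            return int(self.n_features[modality])
        return int(self.n_features)

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not 1 <= len(self.modalities) <= 3:
            raise ValueError("simulate 1-3 modalities (the model input limit)")
        for m in self.modalities:
            get_modality(m)
        probs = np.asarray(self.cnv_state_probs, dtype=float)
        if len(probs) != 5 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("cnv_state_probs must be 5 non-negative values summing to 1")
        if not 0.0 <= self.missing_cell_rate < 1.0:
            raise ValueError("missing_cell_rate must be in [0, 1)")
        if self.missing_modality_pattern not in ("uniform", "non-uniform"):
            raise ValueError("missing_modality_pattern must be uniform or non-uniform")
        if self.planted is None:
            self.planted = {
                m: [
                    (int(round(f * self.features_of(m))), _DEFAULT_EFFECT)
                    for f in _PLANTED_FRACTIONS[m]
                ]
                for m in self.modalities
                if m in _PLANTED_FRACTIONS
            }
        if self.interactions is None:
            ge = self.planted.get("gene_expression", [])
            if len(ge) >= 2:
                self.interactions = [
                    (
                        ("gene_expression", ge[0][0]),
                        ("gene_expression", ge[1][0]),
                        1.0,
                    )
                ]
            else:
                self.interactions = []
        for modality, entries in self.planted.items():
            if modality not in self.modalities:
                continue
            nf = self.features_of(modality)
            for idx, _effect in entries:
                if not 0 <= idx < nf:
                    raise ValueError(
                        f"planted feature index {idx} outside the {nf} generated "
                        f"{modality} features"
                    )

    def planted_features(self) -> dict:
        """modality -> [(feature_id, effect)] restricted to simulated modalities."""
        out = {}
        for modality in self.modalities:
            entries = self.planted.get(modality, [])
            out[modality] = [
                (_feature_id(modality, idx), effect) for idx, effect in entries
            ]
        return out


def _feature_id(modality: str, idx: int) -> str:
    prefix = {
        "gene_expression": "G",
        "mirna_expression": "MIR",
        "dna_methylation": "CPG",
        "protein_expression": "PROT",
        "snp": "SNP",
        "cnv": "CNVG",
    }[modality]
    return f"{prefix}{idx:05d}"


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    planted: dict  # modality -> [(feature_id, effect)]
    eta: pd.Series  # true linear predictor per sample
    labels: pd.Series  # logistic binary labels (LTS / non-LTS)
    lts_labels: pd.Series  # labels implied by the generated survival records
    gene_of_feature: dict  # feature_id -> host gene_id
    planted_pathway: str | None = None

    def planted_ids(self) -> list:
        return [fid for entries in self.planted.values() for fid, _ in entries]

    def planted_genes(self) -> set:
        return {self.gene_of_feature[fid] for fid in self.planted_ids()}


def generate_cohort(config: SimConfig):
    """Simulate the cohort: per-modality matrices, survival, ground truth.

    Returns ``(matrices, survival, truth)`` where ``matrices`` maps modality
    name to :class:`OmicsMatrix`. Fully reproducible under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    encoded_signals: dict = {}
    matrices: dict = {}
    raw_values: dict = {}

    for modality in config.modalities:
        nf = config.features_of(modality)
        feature_ids = [_feature_id(modality, j) for j in range(nf)]
        if get_modality(modality).is_continuous:
            # per-feature normal laws: distinct baselines and scales, as in
            # real expression matrices; the planted effect acts on the
            # standardized residual z (the feature's value in z-space)
            mu = rng.normal(0.0, 1.0, size=nf)
            sd = rng.uniform(0.5, 1.5, size=nf)
            z = rng.standard_normal((n, nf))
            raw = mu[None, :] + sd[None, :] * z
            raw_values[modality] = pd.DataFrame(
                raw, index=sample_ids, columns=feature_ids
            )
            for idx, effect in config.planted.get(modality, []):
                encoded_signals[(modality, idx)] = (z[:, idx].copy(), effect)
        elif modality == "snp":
            maf = rng.uniform(*config.snp_maf_range, size=nf)
            alleles = np.array(
                [rng.choice(len(_ACGT), size=2, replace=False) for _ in range(nf)]
            )
            is_alt = rng.random((n, nf)) < maf
            symbols = np.where(
                is_alt,
                np.array(_ACGT)[alleles[:, 1]][None, :],
                np.array(_ACGT)[alleles[:, 0]][None, :],
            )
            raw_values[modality] = pd.DataFrame(
                symbols, index=sample_ids, columns=feature_ids
            )
            for idx, effect in config.planted.get(modality, []):
                # centered and scaled to unit variance so "effect size" means
                # the same contribution scale in every modality
                p = maf[idx]
                ind = (is_alt[:, idx].astype(float) - p) / np.sqrt(p * (1 - p))
                encoded_signals[(modality, idx)] = (ind, effect)
        else:  # cnv
            probs = np.asarray(config.cnv_state_probs, dtype=float)
            states = rng.choice(np.arange(-2, 3), size=(n, nf), p=probs)
            raw_values[modality] = pd.DataFrame(
                states, index=sample_ids, columns=feature_ids
            )
            for idx, effect in config.planted.get(modality, []):
                # amplified (state >= +1) vs not, standardized like the SNPs
                prev = probs[3] + probs[4]
                ind = ((states[:, idx] >= 1).astype(float) - prev) / np.sqrt(
                    prev * (1 - prev)
                )
                encoded_signals[(modality, idx)] = (ind, effect)

    eta = np.zeros(n)
    for (modality, idx), (signal, effect) in encoded_signals.items():
        eta += effect * signal
    for (mod_a, idx_a), (mod_b, idx_b), strength in config.interactions:
        sig_a = encoded_signals.get((mod_a, idx_a))
        sig_b = encoded_signals.get((mod_b, idx_b))
        if sig_a is None or sig_b is None:
            raise ValueError(
                f"interaction references a non-planted feature: "
                f"({mod_a}, {idx_a}) x ({mod_b}, {idx_b})"
            )
        eta += strength * sig_a[0] * sig_b[0]
    eta += rng.normal(0.0, config.noise_sd, size=n)

    # logistic binary labels
    p_pos = 1.0 / (1.0 + np.exp(-eta))
    labels = pd.Series(
        np.where(rng.random(n) < p_pos, "LTS", "non-LTS"), index=sample_ids
    )

    # survival: exponential with rate shrinking in eta; exponential censoring
    rate = config.survival_baseline_rate * np.exp(-config.survival_effect_scale * eta)
    t_death = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / config.censoring_rate, size=n)
    observed = np.minimum(t_death, t_censor)
    event = (t_death <= t_censor).astype(int)
    survival = SurvivalTable(
        pd.DataFrame(
            {"survival_time": observed, "event": event},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    excluded = (event == 0) & (observed <= 3.0)
    lts = pd.Series(np.where(observed > 3.0, "LTS", "non-LTS"), index=sample_ids)[
        ~excluded
    ]

    # missingness: cell-level holes, then (optionally) whole-modality dropout
    for modality in config.modalities:
        values = raw_values[modality]
        mask = pd.DataFrame(False, index=values.index, columns=values.columns)
        if config.missing_cell_rate > 0 and modality != "cnv":
            holes = rng.random(values.shape) < config.missing_cell_rate
            mask |= holes
            if get_modality(modality).is_continuous:
                values = values.mask(holes, np.nan)
            else:
                values = values.mask(holes, "missing")
        matrices[modality] = OmicsMatrix(
            modality=get_modality(modality), values=values, missing_mask=mask
        )

    if config.missing_modality_pattern == "non-uniform":
        for modality in config.modalities[1:]:
            drop = rng.random(n) < config.non_uniform_missing_fraction
            keep = [s for s, d in zip(sample_ids, drop) if not d]
            m = matrices[modality]
            matrices[modality] = OmicsMatrix(
                modality=m.modality,
                values=m.values.loc[keep],
                missing_mask=m.missing_mask.loc[keep],
            )

    gene_of = _gene_of_feature(config)
    truth = GroundTruth(
        planted=config.planted_features(),
        eta=pd.Series(eta, index=sample_ids),
        labels=labels,
        lts_labels=lts,
        gene_of_feature=gene_of,
    )
    return matrices, survival, truth


def phenotype_from_truth(truth: GroundTruth) -> PhenotypeTable:
    """The classification phenotype implied by the logistic labels."""
    return PhenotypeTable(labels=truth.labels.copy(), task="classification")


# ---------------------------------------------------------------------------
# annotation / gene sets


def _n_genes(config: SimConfig) -> int:
    return max(config.features_of(m) for m in config.modalities)


def _gene_index_of(config: SimConfig, modality: str, idx: int) -> int:
    return idx % _n_genes(config)


def _gene_of_feature(config: SimConfig) -> dict:
    out = {}
    for modality in config.modalities:
        for j in range(config.features_of(modality)):
            out[_feature_id(modality, j)] = f"GENE{_gene_index_of(config, modality, j):05d}"
    return out


def generate_annotation_and_sets(config: SimConfig):
    """Deterministic gene tiling, feature positions, and gene sets.

    Genes are tiled without overlap along synthetic chromosomes (1 kb gene,
    1 kb gap). Every feature is positioned inside its host gene, so position
    mapping has full coverage. One pathway contains exactly the host genes
    of the planted features; the remaining pathways are random draws.

    Returns ``(annotation, positions, collection)`` with ``positions``
    mapping modality name -> {feature_id: (chromosome, position)}.
    """
    n_genes = _n_genes(config)
    per_chrom = config.genes_per_chromosome
    gene_len, gap = 1000, 1000
    rows = []
    for g in range(n_genes):
        chrom = f"chr{g // per_chrom + 1}"
        start = (g % per_chrom) * (gene_len + gap) + gap
        rows.append(
            (chrom, start, start + gene_len, "+" if g % 2 == 0 else "-", f"GENE{g:05d}")
        )
    annotation = GeneAnnotation(
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "strand", "gene_id"])
    )
    by_id = {r[4]: r for r in rows}

    gene_of = _gene_of_feature(config)
    positions: dict = {}
    for modality in config.modalities:
        pos_map = {}
        for j in range(config.features_of(modality)):
            fid = _feature_id(modality, j)
            chrom, start, end, _, _ = by_id[gene_of[fid]]
            offset = 100 + 37 * (j // n_genes)  # distinct spots if genes are reused
            pos_map[fid] = (chrom, start + min(offset, end - start - 1))
        positions[modality] = pos_map

    planted_genes = sorted(
        {gene_of[fid] for entries in config.planted_features().values() for fid, _ in entries}
    )
    all_genes = [f"GENE{g:05d}" for g in range(n_genes)]
    sets = {}
    descriptions = {}
    if planted_genes:
        sets["PATH_PLANTED"] = frozenset(planted_genes)
        descriptions["PATH_PLANTED"] = "host genes of the planted drivers"
    rng = np.random.default_rng(config.seed + 7)
    for p in range(config.n_random_pathways):
        members = rng.choice(n_genes, size=config.random_pathway_size, replace=False)
        pid = f"PATH{p:04d}"
        sets[pid] = frozenset(all_genes[g] for g in members)
        descriptions[pid] = "random background pathway"
    collection = GeneSetCollection(sets=sets, descriptions=descriptions)
    return annotation, positions, collection


# ---------------------------------------------------------------------------
# fixture tree


def write_cohort(config: SimConfig, out_dir) -> dict:
    """Write the full CSV/GMT/BED fixture tree for the CLI workflow.

    Returns a manifest of written paths. Same config (and seed) twice gives
    byte-identical files.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, survival, truth = generate_cohort(config)
    annotation, positions, collection = generate_annotation_and_sets(config)
    truth.planted_pathway = "PATH_PLANTED" if truth.planted_ids() else None
    paths = {}
    for modality, matrix in matrices.items():
        path = out / f"{modality}.csv"
        values = matrix.values.copy()
        values = values.mask(matrix.missing_mask, "")
        values.index.name = "sample_id"
        values.to_csv(path, float_format="%.10g")
        paths[modality] = path
    surv = survival.data.copy()
    surv.index.name = "sample_id"
    surv.to_csv(out / "survival.csv", float_format="%.10g")
    paths["survival"] = out / "survival.csv"
    pheno = truth.labels.rename("label").to_frame()
    pheno.index.name = "sample_id"
    pheno.to_csv(out / "phenotype.csv")
    paths["phenotype"] = out / "phenotype.csv"
    for modality, pos_map in positions.items():
        path = out / f"positions_{modality}.csv"
        pd.DataFrame(
            [(fid, c, p) for fid, (c, p) in pos_map.items()],
            columns=["feature_id", "chromosome", "position"],
        ).to_csv(path, index=False)
        paths[f"positions_{modality}"] = path
    bed = out / "annotation.bed"
    with open(bed, "w") as fh:
        for _, r in annotation.records.iterrows():
            fh.write(
                f"{r['chromosome']}\t{r['start']}\t{r['end']}\t{r['gene_id']}\t0\t{r['strand']}\n"
            )
    paths["annotation"] = bed
    gmt = out / "genesets.gmt"
    with open(gmt, "w") as fh:
        for pid in collection.sets:
            genes = "\t".join(sorted(collection.sets[pid]))
            fh.write(f"{pid}\t{collection.descriptions.get(pid, '')}\t{genes}\n")
    paths["genesets"] = gmt
    return paths
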