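"""Synthetic AML single-cell / bulk data generator.

Emulates the statistical structure the downstream analysis assumes, so every
stage of the pipeline can be exercised without restricted-access patient data:

- multi-cell-type samples whose AML-immature fraction differs by planted
  transcriptomic subtype (class I high, class II low, Beta-distributed),
- heterozygous somatic-mutation transmission: mutated cells emit mut/ref
  alleles per UMI as Bernoulli(0.5), wild-type cells emit ref, with per-read
  sequencing-error flips,
- a planted gene-expression signature that separates the two subtypes only
  within AML-immature cells,
- bulk profiles as cell-type mixtures, so variable composition dominates
  bulk variance over the planted immature-cell signal.

Counts are drawn from per-cell-type negative-binomial centroids. The
generator does not attempt realistic transcriptome biology (no pathway
structure, doublets or ambient RNA); it targets the relative-expression
structure the estimators and classifiers rely on.

All randomness flows from a single seed via named child streams, so outputs
are byte-identical across runs at a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cells",
    "simulate_genotype_reads",
    "simulate_bulk",
    "simulate_variant_candidates",
    "make_concordance_fixture",
    "write_dataset",
]

#: cell types that must be present in any configured vocabulary
REQUIRED_CELLTYPES = (
    "HSC",
    "LMPP",
    "GMP",
    "Monocyte",
    "Erythroid",
    "T",
    "B",
    "NK",
    "AML_immature",
)

DEFAULT_CELLTYPES = (
    "HSC",
    "LMPP",
    "GMP",
    "Monocyte",
    "Erythroid",
    "Dendritic",
    "NK",
    "T",
    "B",
    "AML_immature",
)

# baseline marrow-MNC composition used for the non-immature remainder of an
# AML sample and for NBM samples (HSC/LMPP are rare in unsorted MNCs)
_BASE_COMPOSITION = {
    "HSC": 0.015,
    "LMPP": 0.025,
    "GMP": 0.10,
    "Monocyte": 0.25,
    "Erythroid": 0.12,
    "Dendritic": 0.03,
    "NK": 0.07,
    "T": 0.28,
    "B": 0.11,
}

# clone membership probability per cell type in an AML sample; AML_immature
# is forced to 1 (the immature blast compartment IS the clone), differentiated
# myeloid cells are mostly clonal, lymphoid cells are not
DEFAULT_MUTATED_FRACTION = {
    "AML_immature": 1.0,
    "GMP": 0.9,
    "Monocyte": 0.8,
    "Dendritic": 0.5,
    "Erythroid": 0.15,
    "HSC": 0.2,
    "LMPP": 0.3,
    "T": 0.0,
    "B": 0.0,
    "NK": 0.0,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are chosen to mirror the study conditions the pipeline targets:
    class I samples are blast-rich (Beta(17, 3): mean immature fraction 0.85),
    class II samples are blast-poor and heterogeneous (Beta(2.0, 4.2): median
    ~0.30, wide range), heterozygous alleles transmit at 0.5, and roughly
    half of the cells yield no genotype reads (0.53 dropout, matching a 47%
    genotyping yield).
    """

    n_samples_per_class: int = 15
    n_nbm_samples: int = 4
    n_cells_per_sample: int = 1000
    n_genes: int = 1500
    celltype_names: tuple[str, ...] = DEFAULT_CELLTYPES
    #: per-class Beta(a, b) for the AML-immature cell fraction
    immature_fraction_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"I": (17.0, 3.0), "II": (2.0, 4.2)}
    )
    signature_size: int = 60
    signature_effect: float = 1.5  # log2 fold change, class-specific, immature only
    # the planted subtype genes are leukemic-stem-program genes: strongly
    # expressed in the immature blast compartment in both classes, partially
    # in normal progenitors (HSC/LMPP/GMP), near baseline in mature cells
    signature_baseline_lfc: float = 2.0
    signature_progenitor_lfc: float = 1.0
    het_allele_prob: float = 0.5
    error_rate: float = 0.005
    reads_per_umi_mean: float = 3.0
    umis_per_cell_per_variant_mean: float = 2.0
    n_het_variants_per_sample: int = 2
    genotyping_dropout: float = 0.53
    dropout_mode: str = "cell"  # "cell" or "umi"
    mutated_fraction_by_celltype: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATED_FRACTION)
    )
    # expression model
    mean_library_size: float = 2000.0
    library_sigma: float = 0.3  # lognormal sigma of per-cell library size
    nb_dispersion: float = 10.0  # NB shape theta; var = mu + mu^2/theta
    marker_fraction: float = 0.05  # fraction of genes marking each cell type
    marker_lfc: float = 2.5  # log2 effect of cell-type markers
    # stemness/progenitor program: genes coherently elevated in all immature
    # types (HSC, LMPP, GMP, AML_immature) versus mature types, the dominant
    # axis any immature-vs-mature contrast picks up
    immature_program_fraction: float = 0.05
    immature_program_lfc: float = 3.0
    sample_lfc_sd: float = 0.15  # per-sample random log2 effect on every gene
    n_mito_genes: int = 20
    mito_fraction_mean: float = 0.07  # expected baseline mitochondrial read share
    low_quality_fraction: float = 0.03
    predicted_type_error: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("het_allele_prob", self.het_allele_prob),
            ("error_rate", self.error_rate),
            ("genotyping_dropout", self.genotyping_dropout),
            ("low_quality_fraction", self.low_quality_fraction),
            ("predicted_type_error", self.predicted_type_error),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name, value in (
            ("n_samples_per_class", self.n_samples_per_class),
            ("n_cells_per_sample", self.n_cells_per_sample),
            ("n_genes", self.n_genes),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        missing = set(REQUIRED_CELLTYPES) - set(self.celltype_names)
        if missing:
            raise ValueError(f"celltype_names is missing required types: {sorted(missing)}")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size cannot exceed n_genes")
        for frac in self.mutated_fraction_by_celltype.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("mutated_fraction_by_celltype values must be in [0, 1]")
        if self.dropout_mode not in ("cell", "umi"):
            raise ValueError("dropout_mode must be 'cell' or 'umi'")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic cells."""

    celltype: pd.Series  # per cell, indexed by cell_id
    mutated: pd.Series  # per cell, bool: clone membership
    sample_class: pd.Series  # per sample: "I", "II" or "NBM"
    immature_fraction: pd.Series  # per AML sample: drawn Beta fraction
    class1_up_genes: list[str]
    class2_up_genes: list[str]
    het_variants: dict[str, list[str]]  # sample -> targeted heterozygous variant ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "celltype": self.celltype.to_dict(),
            "mutated": {k: bool(v) for k, v in self.mutated.items()},
            "sample_class": self.sample_class.to_dict(),
            "immature_fraction": self.immature_fraction.to_dict(),
            "class1_up_genes": self.class1_up_genes,
            "class2_up_genes": self.class2_up_genes,
            "het_variants": self.het_variants,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    # one named child stream per operation so stages are independently reproducible
    return np.random.default_rng(np.random.SeedSequence((int(seed) % (2**31), stream)))


def _gene_names(config: SimulationConfig) -> list[str]:
    names = [f"MT-G{i}" for i in range(config.n_mito_genes)]
    names += [f"GENE{i:05d}" for i in range(config.n_genes - config.n_mito_genes)]
    return names


def _build_centroids(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame, list[str], list[str]]:
    """Per-cell-type expression centroids (probability vectors over genes).

    Every cell type gets a block of marker genes at ``marker_lfc``; the
    AML_immature centroid starts from the HSC/LMPP geometric mean (it is an
    aberrant immature state that resembles those types) plus its own markers.
    Returns (centroid matrix [type x gene], gene metadata, class1-up genes,
    class2-up genes).
    """
    types = list(config.celltype_names)
    n_genes = config.n_genes
    genes = _gene_names(config)
    base_logw = rng.normal(0.0, 1.0, size=n_genes)
    # pin the MT- block so the expected mito share hits mito_fraction_mean
    # regardless of how many genes the panel has
    non_mt_weight = np.exp2(base_logw[config.n_mito_genes :]).sum()
    f = config.mito_fraction_mean
    mt_total = f / (1.0 - f) * non_mt_weight
    base_logw[: config.n_mito_genes] = np.log2(mt_total / config.n_mito_genes) + rng.normal(
        0.0, 0.2, size=config.n_mito_genes
    )

    n_markers = max(1, int(round(config.marker_fraction * n_genes)))
    n_program = int(round(config.immature_program_fraction * n_genes))
    assignable = np.arange(config.n_mito_genes, n_genes)
    rng.shuffle(assignable)
    needed = n_markers * len(types) + config.signature_size + n_program
    if needed > assignable.size:
        raise ValueError("n_genes too small for the requested marker/signature blocks")

    logw = np.tile(base_logw, (len(types), 1))
    # mild cell-type-specific wobble on every gene
    logw += rng.normal(0.0, 0.2, size=logw.shape)
    marker_of: dict[str, np.ndarray] = {}
    pos = 0
    for ti, t in enumerate(types):
        block = assignable[pos : pos + n_markers]
        pos += n_markers
        logw[ti, block] += config.marker_lfc
        marker_of[t] = block

    # AML_immature resembles HSC/LMPP but is its own state
    imm = types.index("AML_immature")
    hsc, lmpp = types.index("HSC"), types.index("LMPP")
    logw[imm] = 0.5 * (logw[hsc] + logw[lmpp]) + rng.normal(0.0, 0.2, size=n_genes)
    logw[imm, marker_of["AML_immature"]] += config.marker_lfc

    program_block = assignable[pos : pos + n_program]
    pos += n_program
    for t in ("HSC", "LMPP", "GMP", "AML_immature"):
        logw[types.index(t), program_block] += config.immature_program_lfc

    sig_block = assignable[pos : pos + config.signature_size]
    half = config.signature_size // 2
    class1_idx, class2_idx = sig_block[:half], sig_block[half:]
    # stem-program baseline shared by both classes; the class-specific effect
    # is applied per sample at simulation time
    logw[imm, sig_block] += config.signature_baseline_lfc
    for t in ("HSC", "LMPP", "GMP"):
        logw[types.index(t), sig_block] += config.signature_progenitor_lfc

    var = pd.DataFrame(
        {
            "mt": [g.startswith("MT-") for g in genes],
            "signature_class": "",
        },
        index=pd.Index(genes, name="gene"),
    )
    gene_arr = np.asarray(genes)
    var["immature_program"] = False
    var.loc[gene_arr[program_block], "immature_program"] = True
    var.loc[gene_arr[class1_idx], "signature_class"] = "I"
    var.loc[gene_arr[class2_idx], "signature_class"] = "II"
    for t, block in marker_of.items():
        var.loc[gene_arr[block], "marker_of"] = t

    centroids = np.exp2(logw)
    centroids /= centroids.sum(axis=1, keepdims=True)
    return centroids, var, list(gene_arr[class1_idx]), list(gene_arr[class2_idx])


def _sample_composition(
    config: SimulationConfig, rng: np.random.Generator, sample_class: str
) -> tuple[float, dict[str, float]]:
    """Cell-type proportions for one sample: immature fraction from the
    class Beta, remainder Dirichlet around the baseline marrow composition."""
    base = {t: _BASE_COMPOSITION.get(t, 0.01) for t in config.celltype_names if t != "AML_immature"}
    if sample_class == "NBM":
        # normal references are CD34-enriched: progenitors are well represented
        for t in ("HSC", "LMPP", "GMP"):
            if t in base:
                base[t] *= 3.0
    tot = sum(base.values())
    alpha = np.array([base[t] / tot for t in base]) * 30.0
    rest = rng.dirichlet(alpha)
    if sample_class == "NBM":
        f_imm = 0.0
    else:
        a, b = config.immature_fraction_params[sample_class]
        f_imm = float(rng.beta(a, b))
    props = {t: (1.0 - f_imm) * p for t, p in zip(base, rest)}
    props["AML_immature"] = f_imm
    return f_imm, props


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, theta: float
) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and shape theta (var = mu + mu^2/theta)."""
    lam = rng.gamma(theta, mu / theta)
    return rng.poisson(lam)


def simulate_cells(config: SimulationConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate the synthetic single-cell cohort.

    Returns an AnnData (cells x genes, raw counts in ``X``) whose ``obs``
    carries the observable metadata the pipeline consumes (sample_id, origin,
    QC metrics, predicted cell type, cluster id, 2-D embedding in
    ``obsm['X_embed']``), plus a :class:`SyntheticTruth` with the hidden state.

    Observable conventions mirror the real workflow: AML-immature cells are
    *predicted* HSC or LMPP (a normal-marrow reference knows no such state)
    and sit in one sample-specific cluster each, so the cluster-level
    relabeling rule is what recovers them. A small fraction of cells is
    emitted as low-quality (tiny library or mitochondrial-heavy) so QC has
    something to remove.
    """
    rng = _child_rng(config.seed, 1)
    centroids, var, class1_up, class2_up = _build_centroids(config, rng)
    types = list(config.celltype_names)
    type_index = {t: i for i, t in enumerate(types)}
    genes = var.index.to_numpy()
    sig_cols = {
        "I": var.index.get_indexer(class1_up),
        "II": var.index.get_indexer(class2_up),
    }

    samples: list[tuple[str, str]] = []
    for c in ("I", "II"):
        samples += [(f"AML_{c}_{i:02d}", c) for i in range(config.n_samples_per_class)]
    samples += [(f"NBM_{i:02d}", "NBM") for i in range(config.n_nbm_samples)]

    # embedding: one Gaussian blob per cell type; AML-immature blobs offset per sample
    embed_centers = {t: rng.normal(0.0, 8.0, size=2) for t in types}

    X_blocks: list[sp.csr_matrix] = []
    obs_rows: list[pd.DataFrame] = []
    truth_type: list[pd.Series] = []
    truth_mut: list[pd.Series] = []
    imm_fracs: dict[str, float] = {}
    sample_class: dict[str, str] = {}

    for sample_id, cls in samples:
        sample_class[sample_id] = cls
        f_imm, props = _sample_composition(config, rng, cls)
        if cls != "NBM":
            imm_fracs[sample_id] = f_imm
        n = config.n_cells_per_sample
        ct = rng.choice(types, size=n, p=np.array([props[t] for t in types]))
        rows = np.array([type_index[t] for t in ct])
        mu_frac = centroids[rows].copy()

        if cls in ("I", "II"):
            imm_mask = ct == "AML_immature"
            mu_frac[np.ix_(imm_mask, sig_cols[cls])] *= 2.0**config.signature_effect
        # per-sample random effect on every gene (biological sample-to-sample noise)
        mu_frac *= 2.0 ** rng.normal(0.0, config.sample_lfc_sd, size=config.n_genes)
        mu_frac /= mu_frac.sum(axis=1, keepdims=True)

        lib = config.mean_library_size * rng.lognormal(0.0, config.library_sigma, size=n)
        lowq = rng.random(n) < config.low_quality_fraction
        lowq_kind = rng.random(n) < 0.5  # True: starved library, False: mito-heavy
        lib[lowq & lowq_kind] *= 0.05
        counts = _nb_counts(rng, mu_frac * lib[:, None], config.nb_dispersion)
        # mito-heavy low-quality cells: inflate the MT- block past the QC cut
        heavy = np.where(lowq & ~lowq_kind)[0]
        if heavy.size:
            mt_extra = counts[heavy].sum(axis=1, keepdims=True) * 0.25
            counts[heavy, : config.n_mito_genes] += rng.poisson(
                np.maximum(mt_extra / config.n_mito_genes, 0.1),
                size=(heavy.size, config.n_mito_genes),
            )

        cell_ids = [f"{sample_id}:C{i:04d}" for i in range(n)]
        total = counts.sum(axis=1)
        mito = counts[:, : config.n_mito_genes].sum(axis=1)
        pct_mito = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)

        predicted = ct.astype(object).copy()
        imm_mask = ct == "AML_immature"
        predicted[imm_mask] = rng.choice(["HSC", "LMPP"], size=int(imm_mask.sum()), p=[0.6, 0.4])
        flip = (rng.random(n) < config.predicted_type_error) & ~imm_mask
        if flip.any():
            pool = [t for t in types if t != "AML_immature"]
            predicted[flip] = rng.choice(pool, size=int(flip.sum()))

        cluster = np.array([f"CT_{t}" for t in ct], dtype=object)
        cluster[imm_mask] = f"AMLIMM_{sample_id}"

        xy = np.stack([embed_centers[t] for t in ct]) + rng.normal(0.0, 1.2, size=(n, 2))
        if cls != "NBM":
            xy[imm_mask] += rng.normal(0.0, 4.0, size=2)  # sample-specific immature blob

        obs_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "origin": "NBM" if cls == "NBM" else "AML",
                    "n_genes_detected": (counts > 0).sum(axis=1),
                    "pct_mito": pct_mito,
                    "predicted_type": predicted,
                    "cluster_id": cluster,
                    "embed_x": xy[:, 0],
                    "embed_y": xy[:, 1],
                },
                index=pd.Index(cell_ids, name="cell_id"),
            )
        )
        X_blocks.append(sp.csr_matrix(counts))

        if cls == "NBM":
            mut = np.zeros(n, dtype=bool)
        else:
            p_mut = np.array([config.mutated_fraction_by_celltype.get(t, 0.0) for t in ct])
            mut = rng.random(n) < p_mut
            mut[imm_mask] = True  # the immature compartment is the clone, always
        truth_type.append(pd.Series(ct, index=cell_ids))
        truth_mut.append(pd.Series(mut, index=cell_ids))

    obs = pd.concat(obs_rows)
    adata = ad.AnnData(
        X=sp.vstack(X_blocks).tocsr(),
        obs=obs.drop(columns=["embed_x", "embed_y"]),
        var=var.copy(),
    )
    adata.obsm["X_embed"] = obs[["embed_x", "embed_y"]].to_numpy()

    het_variants = {
        s: [f"{s}:v{j}" for j in range(config.n_het_variants_per_sample)]
        for s, c in samples
        if c != "NBM"
    }
    truth = SyntheticTruth(
        celltype=pd.concat(truth_type).rename("celltype"),
        mutated=pd.concat(truth_mut).rename("mutated"),
        sample_class=pd.Series(sample_class, name="sample_class"),
        immature_fraction=pd.Series(imm_fracs, name="immature_fraction", dtype=float),
        class1_up_genes=class1_up,
        class2_up_genes=class2_up,
        het_variants=het_variants,
    )
    return adata, truth


def simulate_genotype_reads(
    cells: ad.AnnData, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Emit a read-level genotype table for the targeted heterozygous variants.

    For each AML cell and each variant targeted in its sample, a Poisson
    number of UMIs is drawn; each UMI carries a true allele (mutated cell:
    ``mut`` with probability ``het_allele_prob``; wild-type cell: ``ref``)
    and emits ``1 + Poisson`` reads, each flipped independently at
    ``error_rate``. Dropout removes whole cells (``dropout_mode='cell'``) or
    individual UMIs (``'umi'``) at rate ``genotyping_dropout``, emulating the
    roughly-half genotyping yield of the targeted assay.

    Returns a DataFrame with columns cell_barcode, umi, variant_id, allele.
    """
    rng = _child_rng(config.seed, 2)
    obs = cells.obs
    out: dict[str, list] = {"cell_barcode": [], "umi": [], "variant_id": [], "allele": []}

    aml_cells = obs.index[obs["origin"] == "AML"]
    mutated = truth.mutated
    for cell_id in aml_cells:
        sample = obs.at[cell_id, "sample_id"]
        variants = truth.het_variants.get(sample, [])
        if not variants:
            continue
        if config.dropout_mode == "cell" and rng.random() < config.genotyping_dropout:
            continue
        is_mut_cell = bool(mutated.get(cell_id, False))
        for variant in variants:
            n_umis = rng.poisson(config.umis_per_cell_per_variant_mean)
            for u in range(n_umis):
                if config.dropout_mode == "umi" and rng.random() < config.genotyping_dropout:
                    continue
                true_mut = is_mut_cell and (rng.random() < config.het_allele_prob)
                n_reads = 1 + rng.poisson(max(config.reads_per_umi_mean - 1.0, 0.0))
                flips = rng.random(n_reads) < config.error_rate
                umi_id = f"{cell_id}:{variant}:U{u}"
                for fl in flips:
                    allele = ("ref" if true_mut else "mut") if fl else ("mut" if true_mut else "ref")
                    out["cell_barcode"].append(cell_id)
                    out["umi"].append(umi_id)
                    out["variant_id"].append(variant)
                    out["allele"].append(allele)
    return pd.DataFrame(out)


def simulate_bulk(cells: ad.AnnData, samples: list[str] | None = None) -> pd.DataFrame:
    """Per-sample pseudobulk, counts-per-million normalized.

    Sums raw counts over each sample's cells and scales columns to 1e6.
    Composition differences between samples therefore propagate directly into
    the bulk profiles, which is exactly the confounding the state-space
    analysis is designed to sidestep. Returns genes x samples.
    """
    obs = cells.obs
    wanted = samples if samples is not None else list(pd.unique(obs["sample_id"]))
    cols = {}
    X = cells.X
    for s in wanted:
        mask = (obs["sample_id"] == s).to_numpy()
        if not mask.any():
            raise ValueError(f"sample {s!r} has no cells")
        total = np.asarray(X[mask].sum(axis=0)).ravel()
        cols[s] = 1e6 * total / total.sum()
    return pd.DataFrame(cols, index=cells.var_names)


def simulate_variant_candidates(seed: int, n_random: int = 60) -> pd.DataFrame:
    """Variant-candidate table spanning the pass/fail boundaries of every
    caller-specific quality filter, plus random rows and a skin-panel flag.

    Columns follow the candidate schema consumed by
    :mod:`amlss.somatic_filters`: per-caller scores (qss, qsi, tlod,
    somaticscore, ad, vaf) and the four genotype log-likelihoods the
    freebayes somatic score is computed from.
    """
    rng = _child_rng(seed, 3)
    rows: list[dict] = []

    def add(caller, vclass, **kw):
        row = {
            "caller": caller,
            "variant_class": vclass,
            "qss": np.nan,
            "qsi": np.nan,
            "tlod": np.nan,
            "somaticscore": np.nan,
            "ad": np.nan,
            "vaf": np.nan,
            "gl_t_t": np.nan,
            "gl_t_n": np.nan,
            "gl_n_n": np.nan,
            "gl_n_t": np.nan,
            "in_skin_panel": False,
        }
        row.update(kw)
        rows.append(row)

    # deterministic boundary rows: value exactly at each threshold and just under
    for qss in (100, 99, 300, 299, 500):
        add("strelka2", "snv", qss=qss)
        add("strelka1", "snv", qss=qss)
    for qsi in (30, 29, 60, 59, 100, 99, 150):
        add("strelka1", "indel", qsi=qsi)
        add("strelka2", "indel", qsi=qsi)
    for tlod in (30, 29.9, 80):
        add("mutect2", "snv", tlod=tlod)
    for ssc in (60, 59, 300, 299, 400):
        # GLs arranged so the somatic score equals ssc exactly
        add("freebayes", "snv", gl_t_t=0.0, gl_t_n=-float(ssc) / 2, gl_n_n=0.0, gl_n_t=-float(ssc) / 2)
    for ss in (30, 29, 90):
        add("manta", "sv", somaticscore=ss)
    for adp, vaf in ((10, 0.10), (10, 0.101), (9, 0.5), (25, 0.4)):
        add("pindel", "indel", ad=adp, vaf=vaf)

    for i in range(n_random):
        caller = rng.choice(["strelka1", "strelka2", "mutect2", "freebayes", "manta", "pindel"])
        if caller in ("strelka1", "strelka2"):
            vclass = rng.choice(["snv", "indel"])
            add(
                caller,
                vclass,
                qss=float(rng.integers(0, 600)) if vclass == "snv" else np.nan,
                qsi=float(rng.integers(0, 250)) if vclass == "indel" else np.nan,
                in_skin_panel=bool(rng.random() < 0.2),
            )
        elif caller == "mutect2":
            add(caller, "snv", tlod=float(rng.uniform(0, 100)), in_skin_panel=bool(rng.random() < 0.2))
        elif caller == "freebayes":
            gl = -rng.uniform(0, 200, size=4)
            add(caller, "snv", gl_t_t=gl[0], gl_t_n=gl[1], gl_n_n=gl[2], gl_n_t=gl[3],
                in_skin_panel=bool(rng.random() < 0.2))
        elif caller == "manta":
            add(caller, "sv", somaticscore=float(rng.integers(0, 120)), in_skin_panel=bool(rng.random() < 0.2))
        else:
            add(caller, "indel", ad=int(rng.integers(0, 60)), vaf=float(rng.uniform(0, 1)),
                in_skin_panel=bool(rng.random() < 0.2))

    df = pd.DataFrame(rows)
    df.insert(0, "variant_id", [f"var{i:04d}" for i in range(len(df))])
    chrom = rng.integers(1, 23, size=len(df))
    pos = rng.integers(1_000, 5_000_000, size=len(df))
    bases = np.array(list("ACGT"))
    df.insert(1, "chrom", [f"chr{c}" for c in chrom])
    df.insert(2, "pos", pos)
    df.insert(3, "ref", rng.choice(bases, size=len(df)))
    df.insert(4, "alt", rng.choice(bases, size=len(df)))
    return df


def make_concordance_fixture(
    seed: int,
    n_samples: int = 370,
    n_discordant: int = 55,
    n_discordant_unclassified: int = 49,
) -> tuple[pd.Series, pd.Series]:
    """Paired call sets with a planted discordance structure.

    Builds two classifications of the same cohort that agree on
    ``n_samples - n_discordant`` samples, with
    ``n_discordant_unclassified`` of the discordances moving to or from the
    unclassified group and the remainder swapping class I and class II.
    Used to exercise :func:`amlss.subtype_signatures.concordance_report`.
    """
    if n_discordant_unclassified > n_discordant:
        raise ValueError("n_discordant_unclassified cannot exceed n_discordant")
    rng = _child_rng(seed, 4)
    ids = [f"S{i:03d}" for i in range(n_samples)]
    base = rng.choice(["class_I", "class_II", "unclassified"], size=n_samples, p=[0.32, 0.37, 0.31])
    a = pd.Series(base, index=ids, name="truth")
    b = a.copy().rename("predicted")

    order = rng.permutation(n_samples)
    n_swap = n_discordant - n_discordant_unclassified
    swapped = 0
    to_uncl = 0
    for i in order:
        if swapped < n_swap and a.iloc[i] in ("class_I", "class_II"):
            b.iloc[i] = "class_II" if a.iloc[i] == "class_I" else "class_I"
            swapped += 1
        elif to_uncl < n_discordant_unclassified:
            if a.iloc[i] == "unclassified":
                b.iloc[i] = rng.choice(["class_I", "class_II"])
            else:
                b.iloc[i] = "unclassified"
            to_uncl += 1
        if swapped == n_swap and to_uncl == n_discordant_unclassified:
            break
    return a, b


def write_dataset(
    out_dir: str | Path,
    cells: ad.AnnData,
    truth: SyntheticTruth,
    reads: pd.DataFrame | None = None,
    bulk: pd.DataFrame | None = None,
) -> None:
    """Write the synthetic dataset as plain-text files.

    Layout: ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` (MatrixMarket
    triplet of raw counts, genes x cells), ``cells.tsv`` (metadata incl.
    embedding), ``genotype_reads.tsv``, ``bulk.tsv``, ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from scipy.io import mmwrite

    mmwrite(str(out / "matrix.mtx"), sp.csr_matrix(cells.X).T.astype(np.int64))
    pd.Series(cells.var_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cells.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = cells.obs.copy()
    meta["embed_x"] = cells.obsm["X_embed"][:, 0]
    meta["embed_y"] = cells.obsm["X_embed"][:, 1]
    meta.to_csv(out / "cells.tsv", sep="\t")
    if reads is not None:
        reads.to_csv(out / "genotype_reads.tsv", sep="\t", index=False)
    if bulk is not None:
        bulk.to_csv(out / "bulk.tsv", sep="\t")
    truth.to_json(out / "truth.json")
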