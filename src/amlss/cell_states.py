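"""Single-cell state-space operations.

Covers the rule-based stages of the workflow: quality-control filtering,
the cluster-level "AML immature" relabeling rule, per-sample composition
summaries, a reference-centroid label-transfer utility, group-wise
expression averaging, and hexagonal projection summaries of 2-D embeddings
with read-count masking.

Upstream embedding construction (PCA/UMAP/knn force graphs) and graph-based
clustering are consumed as inputs, not recomputed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from amlss import genotyping

__all__ = [
    "qc_filter",
    "label_transfer_centroid",
    "relabel_aml_immature",
    "composition_table",
    "hexbin_projection",
    "hex_assign",
    "average_expression_by_group",
    "sample_celltype_averages",
    "normalize_log1p_cp10k",
]

#: QC thresholds: cells with fewer than 200 informative genes, or more than
#: 15% of detected transcripts from mitochondrial genes, are excluded.
#: "Informative genes" is taken as genes with nonzero counts. Both bounds
#: are strict, so a cell at exactly 200 genes and exactly 15% is kept.
QC_MIN_GENES = 200
QC_MAX_PCT_MITO = 15.0


def qc_filter(
    cells: pd.DataFrame,
    min_genes: int = QC_MIN_GENES,
    max_pct_mito: float = QC_MAX_PCT_MITO,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-quality cells.

    ``cells`` needs ``n_genes_detected`` and ``pct_mito`` (percent, 0-100)
    columns. Returns ``(kept, removed)``; ``removed`` carries a ``reason``
    column (``low_genes``, ``high_mito``, or both joined with ``;``).
    Negative metrics raise ``ValueError``.
    """
    ng = cells["n_genes_detected"]
    pm = cells["pct_mito"]
    if (ng < 0).any() or (pm < 0).any():
        bad = cells.index[(ng < 0) | (pm < 0)][:5].tolist()
        raise ValueError(f"negative QC metrics for cells {bad}")
    low_genes = ng < min_genes
    high_mito = pm > max_pct_mito
    drop = low_genes | high_mito
    removed = cells[drop].copy()
    reason = np.where(
        low_genes[drop] & high_mito[drop],
        "low_genes;high_mito",
        np.where(low_genes[drop], "low_genes", "high_mito"),
    )
    removed["reason"] = reason
    return cells[~drop].copy(), removed


def normalize_log1p_cp10k(X) -> np.ndarray:
    """Library-size normalize to counts-per-10k, then log1p (dense output)."""
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(1e4 * X / lib)


def label_transfer_centroid(
    query_X,
    query_genes: list[str],
    ref_X,
    ref_genes: list[str],
    ref_labels,
    normalize: bool = True,
) -> pd.DataFrame:
    """Assign each query cell the label of its best-correlated reference centroid.

    A lightweight stand-in for reference-based cell-type prediction: both
    matrices are CP10k-log1p normalized over the shared gene universe, a mean
    profile (centroid) is computed per reference label, and each query cell
    receives the label of the centroid with the highest Pearson correlation,
    reported as ``confidence``. Query cells with zero variance over the
    shared genes are labeled ``"unassigned"``.

    Returns a DataFrame with columns ``predicted_type`` and ``confidence``.
    """
    shared = [g for g in query_genes if g in set(ref_genes)]
    if not shared:
        raise ValueError("query and reference share no genes")
    qidx = pd.Index(query_genes).get_indexer(shared)
    ridx = pd.Index(ref_genes).get_indexer(shared)

    Q = normalize_log1p_cp10k(query_X)[:, qidx] if normalize else np.asarray(query_X)[:, qidx]
    R = normalize_log1p_cp10k(ref_X)[:, ridx] if normalize else np.asarray(ref_X)[:, ridx]
    labels = np.asarray(ref_labels)
    cents = np.stack([R[labels == lab].mean(axis=0) for lab in pd.unique(labels)])
    cent_labels = pd.unique(labels)

    Qc = Q - Q.mean(axis=1, keepdims=True)
    Cc = cents - cents.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(Qc, axis=1)
    cn = np.linalg.norm(Cc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Qc @ Cc.T) / np.outer(qn, cn)
    best = np.nanargmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)
    pred = cent_labels[best].astype(object)
    conf = corr[np.arange(len(pred)), best]
    degenerate = qn == 0
    pred[degenerate] = "unassigned"
    conf = np.where(degenerate, np.nan, conf)
    return pd.DataFrame({"predicted_type": pred, "confidence": conf})


def relabel_aml_immature(
    cells: pd.DataFrame,
    aml_fraction_min: float = 0.80,
    immature_majority: float = 0.50,
    immature_source_types: tuple[str, ...] = ("HSC", "LMPP"),
    new_label: str = "AML_immature",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cluster-level AML-immature relabeling rule.

    A cluster is relabeled when strictly more than 80% of its cells come
    from AML samples AND the combined share of cells predicted HSC or LMPP
    strictly exceeds one half ("majority" read as combined share, not
    plurality). Every cell of a qualifying cluster gets ``predicted_type``
    set to ``AML_immature``; all other cells are untouched.

    Returns ``(relabeled cells, decision log)`` where the log has one row
    per cluster with its fractions and the decision. Idempotent: AML_immature
    is not in ``immature_source_types``, so an already-relabeled cluster
    fails the majority condition and is left as is only if re-run — to keep
    re-runs stable the rule also skips clusters already uniformly labeled
    ``new_label``.
    """
    cells = cells.copy()
    log_rows = []
    for cluster, sub in cells.groupby("cluster_id", sort=True, observed=True):
        n = len(sub)
        if n == 0:
            log_rows.append({"cluster_id": cluster, "n_cells": 0, "frac_aml": np.nan,
                             "frac_immature_pred": np.nan, "relabeled": False, "note": "empty"})
            continue
        already = (sub["predicted_type"] == new_label).all()
        frac_aml = (sub["origin"] == "AML").mean()
        frac_imm = sub["predicted_type"].isin(immature_source_types).mean()
        relabel = already or (frac_aml > aml_fraction_min and frac_imm > immature_majority)
        if relabel and not already:
            cells.loc[sub.index, "predicted_type"] = new_label
        log_rows.append(
            {
                "cluster_id": cluster,
                "n_cells": n,
                "frac_aml": frac_aml,
                "frac_immature_pred": frac_imm,
                "relabeled": bool(relabel),
                "note": "already_relabeled" if already else "",
            }
        )
    return cells, pd.DataFrame(log_rows)


def composition_table(
    cells: pd.DataFrame, celltype_col: str = "predicted_type"
) -> pd.DataFrame:
    """Per-sample cell-type proportions (rows sum to 1)."""
    return pd.crosstab(cells["sample_id"], cells[celltype_col], normalize="index")


def hex_assign(xy: np.ndarray, hex_size: float) -> np.ndarray:
    """Axial (q, r) coordinates of the pointy-top hexagon containing each point.

    ``hex_size`` is the hexagon circumradius. Uses fractional axial
    coordinates followed by cube rounding, the standard exact point-to-hex
    assignment, so binning is a true partition of the plane.
    """
    xy = np.asarray(xy, dtype=float)
    if not np.isfinite(xy).all():
        bad = np.where(~np.isfinite(xy).all(axis=1))[0][:10].tolist()
        raise ValueError(f"non-finite embedding coordinates at rows {bad}")
    x, y = xy[:, 0] / hex_size, xy[:, 1] / hex_size
    qf = np.sqrt(3.0) / 3.0 * x - y / 3.0
    rf = 2.0 / 3.0 * y
    sf = -qf - rf
    q, r, s = np.round(qf), np.round(rf), np.round(sf)
    dq, dr, ds = np.abs(q - qf), np.abs(r - rf), np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return np.stack([q, r], axis=1).astype(int)


def hexbin_projection(
    cells: pd.DataFrame,
    xy: np.ndarray,
    calls: pd.DataFrame,
    het_variants,
    hex_size: float = 1.0,
    display_min_fraction: float = 0.001,
    mask_max_reads: int = genotyping.MASK_MAX_READS,
) -> pd.DataFrame:
    """Hexagonal summary of an embedding with mutated-fraction shading.

    Cells are binned on a pointy-top axial hex lattice; each hexagon gets its
    cell count and the heterozygous-corrected mutated-cell fraction computed
    by :func:`amlss.genotyping.estimate_mutated_fraction` with the hexagon as
    the group. Display semantics follow the figure conventions: hexagons
    supported by ``mask_max_reads`` or fewer genotype reads are
    ``masked_low_reads`` ("brown"); hexagons that do not exceed
    ``display_min_fraction`` of the grand total of cells (default 0.1%) are
    ``hidden_low_count``; the rest are ``shown``. Low-read masking takes
    precedence when both apply.

    Returns a DataFrame with columns ``q``, ``r``, ``n_cells``, ``n_m``,
    ``n_r``, ``P``, ``masked``, ``low_count``, ``display``.
    """
    hexes = hex_assign(xy, hex_size)
    hex_id = pd.Series(
        [f"{q},{r}" for q, r in hexes], index=cells.index, name="hex"
    )
    est = genotyping.estimate_mutated_fraction(
        calls, hex_id, het_variants, mask_max_reads=mask_max_reads
    )
    n_cells = hex_id.value_counts()
    out = est.copy()
    out["n_cells"] = n_cells.reindex(out.index).fillna(0).astype(int)
    total = int(out["n_cells"].sum())
    out["low_count"] = out["n_cells"] <= display_min_fraction * total
    out["display"] = np.where(
        out["masked"], "masked_low_reads", np.where(out["low_count"], "hidden_low_count", "shown")
    )
    qr = out.index.to_series().str.split(",", expand=True).astype(int)
    out.insert(0, "q", qr[0].to_numpy())
    out.insert(1, "r", qr[1].to_numpy())
    return out.reset_index(drop=True)[
        ["q", "r", "n_cells", "n_m", "n_r", "P", "masked", "low_count", "display"]
    ]


def average_expression_by_group(X, genes: list[str], groups) -> pd.DataFrame:
    """Arithmetic mean expression per group (groups x genes).

    ``groups`` is one label per cell (row of ``X``); empty groups simply have
    no row. Sparse input stays sparse until the per-group division.
    """
    groups = pd.Series(list(groups))
    if len(groups) != (X.shape[0] if hasattr(X, "shape") else len(X)):
        raise ValueError("groups must have one label per cell")
    codes, labels = pd.factorize(groups)  # tuples allowed as group keys
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))), shape=(len(labels), len(codes))
    )
    sums = np.asarray((ind @ sp.csr_matrix(X)).todense()) if sp.issparse(X) else ind @ np.asarray(X, dtype=float)
    counts = np.bincount(codes, minlength=len(labels)).astype(float)
    means = np.asarray(sums) / counts[:, None]
    return pd.DataFrame(means, index=pd.Index(labels, name="group"), columns=genes)


def sample_celltype_averages(
    X,
    genes: list[str],
    obs: pd.DataFrame,
    celltype_col: str = "predicted_type",
    sample_col: str = "sample_id",
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-(sample, cell type) mean expression on the linear CP10k scale.

    Groups with fewer than ``min_cells`` cells are dropped: averages over a
    handful of cells are dominated by detection noise and would otherwise
    inject floor-level outliers into downstream differential tests.
    Returns a DataFrame with a (sample, cell type) MultiIndex over genes.
    """
    linear = np.expm1(normalize_log1p_cp10k(X))
    keys = list(zip(obs[sample_col], obs[celltype_col]))
    avg = average_expression_by_group(linear, genes, keys)
    counts = pd.Series(keys).value_counts()
    mask = np.array([counts[k] >= min_cells for k in avg.index])
    avg = avg[mask]
    avg.index = pd.MultiIndex.from_tuples(avg.index, names=[sample_col, celltype_col])
    return avg
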