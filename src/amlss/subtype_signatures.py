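"""NPM1 class I / class II expression-signature derivation and classification.

The signature is built in three stages on per-(sample, cell type) average
expression profiles:

1. Within each class, genes up-regulated in immature cell types
   (AML immature, GMP, LMPP) versus mature types (monocytes, erythroid,
   dendritic, NK, T, B) are selected by two-sample t-test with
   Benjamini-Hochberg control (defaults: class I q < 2.25e-5 capped at 548
   genes; class II q < 3e-5 capped at 389).
2. The two selections are unioned.
3. Within the union, genes differentially expressed between the
   AML-immature compartments of the two classes are kept at q < 0.05 and
   split into class-I-up and class-II-up lists by the sign of the mean
   difference; genes with notable expression outside the AML-immature
   compartment can be excluded so that bulk cell-type composition does not
   leak into the classifier.

Bulk samples are then classified by a signed nearest-centroid score on
gene-wise z-scored expression, with an "unclassified" call when the margin
between the class scores is too small — the behaviour expected for
blast-poor samples whose bulk profile carries little immature signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignatureSet",
    "BulkClassification",
    "bh_qvalues",
    "immature_vs_mature_select",
    "derive_signature",
    "shortlist_30",
    "log2_threshold_transform",
    "variance_filter",
    "hierarchical_cluster",
    "classify_bulk",
    "classify_bulk_by_clustering",
    "concordance_report",
    "IMMATURE_TYPES",
    "MATURE_TYPES",
]

#: cell types treated as immature / mature in the stage-1 contrast
IMMATURE_TYPES = ("AML_immature", "GMP", "LMPP")
MATURE_TYPES = ("Monocyte", "Erythroid", "Dendritic", "NK", "T", "B")

CALL_LEVELS = ("class_I", "class_II", "unclassified")


@dataclass
class SignatureSet:
    """Ordered up-gene lists per class plus derivation provenance."""

    class1_up: list[str]
    class2_up: list[str]
    unclassified_up: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.class1_up) & set(self.class2_up)
        if overlap:
            raise ValueError(f"class1_up and class2_up overlap: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> list[str]:
        out = list(self.class1_up) + list(self.class2_up)
        if self.unclassified_up:
            out += list(self.unclassified_up)
        return out

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {
                    "class1_up": self.class1_up,
                    "class2_up": self.class2_up,
                    "unclassified_up": self.unclassified_up,
                    "provenance": self.provenance,
                },
                indent=1,
            )
        )


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _ttest_frame(a: np.ndarray, b: np.ndarray, genes, equal_var: bool) -> pd.DataFrame:
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    out = pd.DataFrame(
        {
            "gene": genes,
            "group_mean_a": a.mean(axis=0),
            "group_mean_b": b.mean(axis=0),
            "t_statistic": t,
            "p_value": p,
        }
    )
    # constant genes give nan t/p; treat as no evidence
    out["p_value"] = out["p_value"].fillna(1.0)
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    return out


def immature_vs_mature_select(
    avg: pd.DataFrame,
    class_samples: list[str],
    n_top: int,
    q_max: float,
    immature_types: tuple[str, ...] = IMMATURE_TYPES,
    mature_types: tuple[str, ...] = MATURE_TYPES,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Select genes up-regulated in immature cell types within one class.

    ``avg`` is a per-(sample, cell type) average expression matrix (rows
    MultiIndex (sample_id, celltype), columns genes, log scale). The
    observations entering the two-sample t-test are those averages for the
    given class samples, grouped into immature versus mature cell types.
    Genes with a positive immature-minus-mature difference and BH
    ``q < q_max`` are returned, ordered by ascending q (ties broken by gene
    id), capped at ``n_top``.

    Returns ``(per-gene DE table, selected gene list)``.
    """
    sub = avg.loc[avg.index.get_level_values(0).isin(class_samples)]
    ct = sub.index.get_level_values(1)
    a = sub[ct.isin(immature_types)].to_numpy(dtype=float)
    b = sub[ct.isin(mature_types)].to_numpy(dtype=float)
    if a.shape[0] < 2:
        raise ValueError("immature group has fewer than 2 observations")
    if b.shape[0] < 2:
        raise ValueError("mature group has fewer than 2 observations")
    de = _ttest_frame(a, b, list(avg.columns), equal_var)
    up = de[(de["group_mean_a"] > de["group_mean_b"]) & (de["q_value"] < q_max)]
    up = up.sort_values(["q_value", "gene"], kind="mergesort")
    selected = up["gene"].head(n_top).tolist()
    return de, selected


def log2_threshold_transform(matrix, floor: float = 0.01):
    """Log2 transform with a lower threshold: values below ``floor`` are
    raised to ``floor`` first. Negative input raises ``ValueError``."""
    arr = np.asarray(matrix, dtype=float)
    if (arr < 0).any():
        raise ValueError("log2_threshold_transform requires nonnegative input")
    out = np.log2(np.maximum(arr, floor))
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass
class SelectionParams:
    """Stage-1 selection settings for one class (defaults are the production
    values: 548 genes at q<2.25e-5 for class I, 389 at q<3e-5 for class II)."""

    n_top: int
    q_max: float


DEFAULT_CLASS1_SELECTION = SelectionParams(n_top=548, q_max=2.25e-5)
DEFAULT_CLASS2_SELECTION = SelectionParams(n_top=389, q_max=3e-5)


def derive_signature(
    avg: pd.DataFrame,
    sample_class: pd.Series,
    celltype_means: pd.DataFrame | None = None,
    class1_selection: SelectionParams = DEFAULT_CLASS1_SELECTION,
    class2_selection: SelectionParams = DEFAULT_CLASS2_SELECTION,
    stage3_q_max: float = 0.05,
    cross_celltype_max_fraction: float | None = 0.5,
    immature_label: str = "AML_immature",
    equal_var: bool = True,
) -> SignatureSet:
    """Derive the class I / class II signature from per-group averages.

    Parameters
    ----------
    avg
        Per-(sample, cell type) average expression, log scale (rows
        MultiIndex (sample_id, celltype), columns genes).
    sample_class
        Mapping sample_id -> "I" / "II" (other values ignored).
    celltype_means
        Optional cell type x gene mean matrix on the *linear* scale, pooled
        over AML samples, used for the cross-cell-type exclusion: a gene is
        dropped when its mean in any non-AML-immature cell type exceeds
        ``cross_celltype_max_fraction`` of its AML-immature mean. Pass
        ``cross_celltype_max_fraction=None`` to skip.

    Stages: per-class immature-vs-mature selection; union; t-test between
    the classes' AML-immature profiles restricted to the union with BH over
    the union family only; split by sign of the class I minus class II mean.
    Provenance records the size of every stage.
    """
    class1 = sample_class.index[sample_class == "I"].tolist()
    class2 = sample_class.index[sample_class == "II"].tolist()
    _, sel1 = immature_vs_mature_select(
        avg, class1, class1_selection.n_top, class1_selection.q_max, equal_var=equal_var
    )
    _, sel2 = immature_vs_mature_select(
        avg, class2, class2_selection.n_top, class2_selection.q_max, equal_var=equal_var
    )
    union = sorted(set(sel1) | set(sel2))
    if not union:
        raise ValueError("stage-1 selections are empty; no union to test")

    imm = avg.xs(immature_label, level=1)
    a = imm.loc[imm.index.isin(class1), union].to_numpy(dtype=float)
    b = imm.loc[imm.index.isin(class2), union].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 samples with AML_immature profiles per class")
    de = _ttest_frame(a, b, union, equal_var)
    hits = de[de["q_value"] < stage3_q_max]

    n_before_exclusion = len(hits)
    excluded: list[str] = []
    if cross_celltype_max_fraction is not None and celltype_means is not None:
        imm_mean = celltype_means.loc[immature_label]
        others = celltype_means.drop(index=immature_label)
        leaky = others.max(axis=0) > cross_celltype_max_fraction * imm_mean
        excluded = [g for g in hits["gene"] if leaky.get(g, False)]
        hits = hits[~hits["gene"].isin(excluded)]

    up1 = hits[hits["t_statistic"] > 0].sort_values(["q_value", "gene"], kind="mergesort")
    up2 = hits[hits["t_statistic"] < 0].sort_values(["q_value", "gene"], kind="mergesort")
    return SignatureSet(
        class1_up=up1["gene"].tolist(),
        class2_up=up2["gene"].tolist(),
        provenance={
            "n_class1_selected": len(sel1),
            "n_class2_selected": len(sel2),
            "n_union": len(union),
            "n_stage3_hits": n_before_exclusion,
            "n_cross_celltype_excluded": len(excluded),
            "n_final": len(hits),
            "class1_selection": vars(class1_selection),
            "class2_selection": vars(class2_selection),
            "stage3_q_max": stage3_q_max,
            "cross_celltype_max_fraction": cross_celltype_max_fraction,
        },
    )


def shortlist_30(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_per_group: int = 10,
    groups: tuple[str, ...] = CALL_LEVELS,
) -> SignatureSet:
    """Compact marker list: the top overexpressed genes of each of the three
    call groups (class I, class II, unclassified).

    ``expr`` is samples x genes on the log scale; ``labels`` assigns each
    sample to one of ``groups``. For each group, genes are ranked by the
    mean log-fold-change of that group versus the other two pooled and the
    top ``n_per_group`` taken; ranks 11+ backfill if a gene was already
    claimed by an earlier group, so the concatenated list has exactly
    ``3 * n_per_group`` distinct genes. Ties break lexicographically.
    """
    labels = labels.reindex(expr.index)
    per_group: dict[str, list[str]] = {}
    taken: set[str] = set()
    for g in groups:
        in_g = expr[labels == g]
        out_g = expr[labels.isin([x for x in groups if x != g])]
        if len(in_g) == 0 or len(out_g) == 0:
            raise ValueError(f"group {g!r} has no samples")
        lfc = in_g.mean(axis=0) - out_g.mean(axis=0)
        ranked = lfc.sort_values(ascending=False, kind="mergesort")
        ranked = ranked.loc[sorted(ranked.index, key=lambda x: (-ranked[x], x))]
        if len(ranked) < n_per_group:
            raise ValueError(f"fewer than {n_per_group} rankable genes for group {g!r}")
        picks = [g_ for g_ in ranked.index if g_ not in taken][:n_per_group]
        if len(picks) < n_per_group:
            raise ValueError("not enough distinct genes to fill the shortlist")
        per_group[g] = picks
        taken |= set(picks)
    return SignatureSet(
        class1_up=per_group[groups[0]],
        class2_up=per_group[groups[1]],
        unclassified_up=per_group[groups[2]],
        provenance={"n_per_group": n_per_group, "groups": list(groups)},
    )


def variance_filter(matrix: pd.DataFrame, fraction_of_max_sd: float) -> list[str]:
    """Keep genes whose standard deviation across samples is at least
    ``fraction_of_max_sd`` times the largest gene SD.

    ``matrix`` is genes x samples (log scale). An all-constant matrix yields
    an empty list with a warning.
    """
    sd = matrix.std(axis=1, ddof=1)
    max_sd = sd.max()
    if not np.isfinite(max_sd) or max_sd == 0:
        warnings.warn("variance_filter: all genes are constant; returning no genes")
        return []
    return matrix.index[sd >= fraction_of_max_sd * max_sd].tolist()


@dataclass
class ClusterResult:
    linkage: np.ndarray
    order: list[str]
    labels: pd.Series | None


def hierarchical_cluster(matrix: pd.DataFrame, k: int | None = None) -> ClusterResult:
    """Agglomerative clustering of samples on 1 - Pearson correlation.

    Rows (genes) are z-scored first so every gene contributes on the same
    scale; sample-sample distance is correlation distance and linkage is
    average, a standard configuration for expression heatmaps. ``matrix`` is
    genes x samples. Returns the scipy linkage matrix, the dendrogram leaf
    order, and flat cluster labels when ``k`` is given.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    z = matrix.sub(matrix.mean(axis=1), axis=0)
    sd = matrix.std(axis=1, ddof=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    d = ssd.pdist(z.T.to_numpy(), metric="correlation")
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    Z = sch.linkage(d, method="average")
    order = [matrix.columns[i] for i in sch.leaves_list(Z)]
    labels = None
    if k is not None:
        flat = sch.fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=matrix.columns, name="cluster")
    return ClusterResult(linkage=Z, order=order, labels=labels)


@dataclass
class BulkClassification:
    """Per-sample calls with scores; ``frame`` has one row per sample with
    columns call, score_I, score_II, margin."""

    frame: pd.DataFrame

    @property
    def calls(self) -> pd.Series:
        return self.frame["call"]


#: default score margin (in gene-wise z units) below which a bulk sample is
#: left unclassified; sized so synthetic blast-poor samples (immature
#: fraction under ~15%) mostly fail to reach a call
DEFAULT_MARGIN = 0.4


def classify_bulk(
    bulk: pd.DataFrame,
    signature: SignatureSet,
    margin_threshold: float = DEFAULT_MARGIN,
    min_overlap: float = 0.5,
    score_floor: float = 0.0,
) -> BulkClassification:
    """Signed nearest-centroid classification of bulk samples.

    ``bulk`` is genes x samples (log scale recommended). Expression is
    z-scored per gene across samples — making the call invariant to gene-wise
    affine rescaling — and each sample scores
    ``score_I = mean z over class-I-up genes - mean z over class-II-up
    genes`` (``score_II`` is its negation). The call is the score sign when
    ``|score_I| >= margin_threshold``, with a rejection floor: the winning
    half's own mean-z must reach ``score_floor``, so a sample that resembles
    neither centroid (the blast-poor situation, where both signature halves
    are depressed) is left unclassified rather than assigned to whichever
    half it is less unlike. Fails if less than ``min_overlap`` of the
    signature genes are present.
    """
    present = [g for g in signature.class1_up + signature.class2_up if g in bulk.index]
    need = len(signature.class1_up) + len(signature.class2_up)
    if need == 0:
        raise ValueError("signature has no genes")
    if len(present) < min_overlap * need:
        raise ValueError(
            f"only {len(present)}/{need} signature genes present in bulk matrix "
            f"(needs >= {min_overlap:.0%})"
        )
    sub = bulk.loc[present]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1).replace(0, 1.0), axis=0)
    g1 = [g for g in signature.class1_up if g in z.index]
    g2 = [g for g in signature.class2_up if g in z.index]
    if not g1 or not g2:
        raise ValueError("one of the signature halves has no genes in the bulk matrix")
    s1 = z.loc[g1].mean(axis=0)
    s2 = z.loc[g2].mean(axis=0)
    score_i = s1 - s2
    call = np.where(
        (np.abs(score_i) < margin_threshold) | (np.maximum(s1, s2) < score_floor),
        "unclassified",
        np.where(score_i > 0, "class_I", "class_II"),
    )
    frame = pd.DataFrame(
        {
            "call": call,
            "score_I": score_i,
            "score_II": -score_i,
            "margin": np.abs(score_i),
        },
        index=bulk.columns.rename("sample_id"),
    )
    return BulkClassification(frame=frame)


def classify_bulk_by_clustering(
    bulk: pd.DataFrame, signature: SignatureSet, k: int = 2
) -> pd.Series:
    """Clustering-route classification, for parity with heatmap-based calls.

    Samples are hierarchically clustered on the signature genes and each
    flat cluster is assigned the class whose centroid score dominates within
    it (majority of the mean ``score_I`` sign). No unclassified call is made
    on this route unless a cluster's mean score is exactly zero.
    """
    present = [g for g in signature.genes if g in bulk.index]
    res = hierarchical_cluster(bulk.loc[present], k=k)
    scores = classify_bulk(bulk, signature, margin_threshold=0.0).frame["score_I"]
    out = pd.Series(index=bulk.columns, dtype=object, name="call")
    for cl in res.labels.unique():
        members = res.labels.index[res.labels == cl]
        mean_score = scores.loc[members].mean()
        out.loc[members] = (
            "class_I" if mean_score > 0 else "class_II" if mean_score < 0 else "unclassified"
        )
    return out


def concordance_report(calls_a: pd.Series, calls_b: pd.Series) -> dict:
    """Agreement structure between two call sets over common samples.

    Returns a dict with the 3x3 confusion matrix (rows: ``calls_a``), the
    total and agreeing counts, the overall agreement fraction, and the split
    of discordances into those involving the unclassified group versus
    class I <-> class II swaps.
    """
    common = calls_a.index.intersection(calls_b.index)
    if len(common) == 0:
        raise ValueError("call sets share no sample ids")
    a, b = calls_a.loc[common], calls_b.loc[common]
    confusion = (
        pd.crosstab(a, b)
        .reindex(index=CALL_LEVELS, columns=CALL_LEVELS, fill_value=0)
        .rename_axis(index="calls_a", columns="calls_b")
    )
    agree = int(np.diag(confusion.to_numpy()).sum())
    n = int(len(common))
    disc = a != b
    involves_uncl = disc & ((a == "unclassified") | (b == "unclassified"))
    return {
        "confusion": confusion,
        "n_samples": n,
        "n_agree": agree,
        "agreement": agree / n,
        "n_discordant": int(disc.sum()),
        "n_discordant_unclassified": int(involves_uncl.sum()),
        "n_class_swap": int((disc & ~involves_uncl).sum()),
    }
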