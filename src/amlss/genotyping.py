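"""Single-cell targeted mutation genotyping (scRNAmut-seq style analysis).

The entry point is a read-level table of allele observations keyed by
(cell barcode, UMI, variant). Each UMI is genotyped by majority vote over its
reads; ties are called ambiguous and excluded downstream. The proportion of
mutated cells in an arbitrary cell group is then estimated from UMIs covering
heterozygous somatic variants as

    P = (n_m / (n_m + n_r)) / 0.5

where n_m and n_r are the mutated / reference UMI counts pooled over all
heterozygous variants and cells in the group, and 0.5 is the expected allele
fraction if every cell in the group carried one mutated allele. P is clipped
to [0, 1]; groups supported by three or fewer genotyped UMIs are masked
rather than estimated.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "call_umi_genotypes",
    "estimate_mutated_fraction",
    "per_celltype_fraction_matrix",
    "MASK_MAX_READS",
    "HET_EXPECTED_ALLELE_FRACTION",
]

logger = logging.getLogger(__name__)

#: groups (or hexagons, or sample x cell-type entries) supported by this many
#: genotyped UMIs or fewer are masked instead of estimated
MASK_MAX_READS = 3

#: expected mutant-allele fraction in a fully mutated heterozygous population
HET_EXPECTED_ALLELE_FRACTION = 0.5

_KEY = ["cell_barcode", "umi", "variant_id"]


def call_umi_genotypes(reads: pd.DataFrame) -> pd.DataFrame:
    """Majority-vote genotype per (cell_barcode, umi, variant_id).

    Parameters
    ----------
    reads
        Read-level table with columns ``cell_barcode``, ``umi``,
        ``variant_id`` and ``allele`` (values ``"mut"`` / ``"ref"``); the key
        may repeat, one row per read.

    Returns
    -------
    One row per distinct key with columns ``call`` (``"mutated"``,
    ``"reference"`` or ``"ambiguous"`` on ties), ``n_mut_reads`` and
    ``n_ref_reads``. Read counts are conserved: the two count columns sum to
    the number of input reads. An empty input yields an empty table.
    """
    required = set(_KEY + ["allele"])
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"reads table is missing columns: {sorted(missing)}")
    if len(reads) == 0:
        return pd.DataFrame(
            columns=_KEY + ["call", "n_mut_reads", "n_ref_reads"]
        )
    bad = set(reads["allele"].unique()) - {"mut", "ref"}
    if bad:
        raise ValueError(f"invalid allele values: {sorted(bad)}")

    grp = reads.assign(_is_mut=(reads["allele"] == "mut")).groupby(_KEY, sort=False)
    calls = grp["_is_mut"].agg(n_mut_reads="sum", n_total="size").reset_index()
    calls["n_ref_reads"] = calls.pop("n_total") - calls["n_mut_reads"]
    calls["call"] = np.select(
        [calls["n_mut_reads"] > calls["n_ref_reads"], calls["n_mut_reads"] < calls["n_ref_reads"]],
        ["mutated", "reference"],
        default="ambiguous",
    )
    return calls[_KEY + ["call", "n_mut_reads", "n_ref_reads"]]


def estimate_mutated_fraction(
    calls: pd.DataFrame,
    groups: Mapping[str, object] | pd.Series,
    het_variants: set[str] | list[str],
    mask_max_reads: int = MASK_MAX_READS,
) -> pd.DataFrame:
    """Heterozygous-corrected mutated-cell fraction per cell group.

    UMIs covering any heterozygous variant, from any cell mapped to the
    group, are pooled; ambiguous calls are excluded. For each group the
    estimator is ``P = min(1, (n_m / (n_m + n_r)) / 0.5)``. Groups with
    ``n_m + n_r <= mask_max_reads`` are returned with ``masked=True`` and
    ``P = NaN`` — including groups with no reads at all, which is not an
    error.

    Parameters
    ----------
    calls
        Output of :func:`call_umi_genotypes`.
    groups
        Mapping (or Series) from cell barcode to group id. Cells absent from
        the mapping are ignored; every group id in the mapping yields a row
        even if none of its cells has reads.
    het_variants
        Variant ids confirmed heterozygous; calls on other variants are
        dropped (the 0.5 correction is only valid for het sites).

    Returns
    -------
    DataFrame indexed by ``group_id`` with columns ``n_m``, ``n_r``, ``P``,
    ``masked``, ``n_cells_with_reads``.
    """
    het = set(het_variants)
    if not het:
        raise ValueError("het_variants must be non-empty")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups

    use = calls[
        calls["variant_id"].isin(het)
        & (calls["call"] != "ambiguous")
        & calls["cell_barcode"].isin(groups.index)
    ].copy()
    use["group_id"] = groups.reindex(use["cell_barcode"]).to_numpy()

    all_groups = pd.Index(pd.unique(groups), name="group_id")
    agg = (
        use.assign(_mut=use["call"] == "mutated")
        .groupby("group_id")
        .agg(
            n_m=("_mut", "sum"),
            n_total=("_mut", "size"),
            n_cells_with_reads=("cell_barcode", "nunique"),
        )
        .reindex(all_groups, fill_value=0)
    )
    out = pd.DataFrame(index=all_groups)
    out["n_m"] = agg["n_m"].astype(int)
    out["n_r"] = (agg["n_total"] - agg["n_m"]).astype(int)
    total = out["n_m"] + out["n_r"]
    out["masked"] = total <= mask_max_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (out["n_m"] / total) / HET_EXPECTED_ALLELE_FRACTION
    out["P"] = np.where(out["masked"], np.nan, np.minimum(p, 1.0))
    out["n_cells_with_reads"] = agg["n_cells_with_reads"].astype(int)
    return out


def per_celltype_fraction_matrix(
    calls: pd.DataFrame,
    cell_table: pd.DataFrame,
    het_variants: Mapping[str, list[str]] | set[str] | list[str],
    celltype_col: str = "predicted_type",
    mask_max_reads: int = MASK_MAX_READS,
) -> pd.DataFrame:
    """Mutated-cell fraction per (sample, cell type).

    Cell barcodes present in ``calls`` but absent from ``cell_table`` are
    excluded with a logged warning (they would otherwise be unattributable).
    Entries with three or fewer genotyped UMIs are masked; (sample, cell type)
    combinations with no cells are simply absent, so the heatmap distinction
    between "too few reads" and "cell type not present" is preserved.

    ``het_variants`` may be a flat collection of variant ids or a per-sample
    mapping (the union is used; variant ids are sample-scoped upstream).

    Returns a long-form DataFrame with columns ``sample_id``, ``celltype``,
    ``n_m``, ``n_r``, ``P``, ``masked``, ``n_cells_with_reads`` — one row per
    (sample, cell type) that has at least one cell.
    """
    if isinstance(het_variants, Mapping):
        het: set[str] = set()
        for v in het_variants.values():
            het |= set(v)
    else:
        het = set(het_variants)

    unknown = ~calls["cell_barcode"].isin(cell_table.index)
    n_unknown = int(unknown.sum())
    if n_unknown:
        logger.warning(
            "excluding %d UMI calls from %d unknown cell barcodes",
            n_unknown,
            calls.loc[unknown, "cell_barcode"].nunique(),
        )
        calls = calls[~unknown]

    key = pd.Series(
        list(zip(cell_table["sample_id"], cell_table[celltype_col])), index=cell_table.index
    )
    est = estimate_mutated_fraction(calls, key, het, mask_max_reads=mask_max_reads)
    est = est.reset_index()
    est.insert(0, "sample_id", [g[0] for g in est["group_id"]])
    est.insert(1, "celltype", [g[1] for g in est["group_id"]])
    return est.drop(columns="group_id")
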