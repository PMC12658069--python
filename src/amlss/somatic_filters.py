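"""Bulk somatic-variant post-processing.

Three steps sit downstream of the external tumor/normal callers (strelka
v1/v2, Mutect2, freebayes, manta, pindel — running them is out of scope):

1. a freebayes-style somatic score computed from the four genotype
   log-likelihoods, ``SSC = T.GL(T) - T.GL(N) + N.GL(N) - N.GL(T)``,
2. per-caller quality filtering, with a stricter dialect for deep targeted
   PCR data than for whole-exome data,
3. cohort-wide germline subtraction against a panel of cultured skin
   biopsies: a candidate matching ANY skin variant (not only the same
   patient's) is removed as suspected germline.

The thresholds live in a data-driven table so alternative cut-offs can be
supplied; the shipped defaults are the production values (see
``DEFAULT_THRESHOLDS``). All ">=" cuts are inclusive; the pindel VAF cut is
strict, i.e. the VAF must exceed 10%.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "somatic_score",
    "filter_candidates",
    "subtract_germline",
    "normalize_variant_key",
    "load_subtype_table",
    "DEFAULT_THRESHOLDS",
    "CALLERS",
]

CALLERS = ("strelka1", "strelka2", "mutect2", "freebayes", "manta", "pindel")

_GL_FIELDS = ("gl_t_t", "gl_t_n", "gl_n_n", "gl_n_t")

# rule table: dialect -> (caller, variant_class or None=any) -> list of
# (rule_name, field, operator, threshold); "ssc" is computed from the GLs
DEFAULT_THRESHOLDS: dict[str, dict[tuple[str, str | None], list[tuple[str, str, str, float]]]] = {
    "wes": {
        ("strelka1", "snv"): [("strelka1_snv_qss>=100", "qss", ">=", 100)],
        ("strelka2", "snv"): [("strelka2_snv_qss>=100", "qss", ">=", 100)],
        ("strelka1", "indel"): [("strelka1_indel_qsi>=30", "qsi", ">=", 30)],
        ("strelka2", "indel"): [("strelka2_indel_qsi>=100", "qsi", ">=", 100)],
        ("mutect2", None): [("mutect2_tlod>=30", "tlod", ">=", 30)],
        ("freebayes", None): [("freebayes_ssc>=60", "ssc", ">=", 60)],
        ("manta", None): [("manta_somaticscore>=30", "somaticscore", ">=", 30)],
        ("pindel", None): [
            ("pindel_ad>=10", "ad", ">=", 10),
            ("pindel_vaf>0.1", "vaf", ">", 0.10),
        ],
    },
    "targeted_pcr": {
        ("strelka1", "snv"): [("strelka1_snv_qss>=300", "qss", ">=", 300)],
        ("strelka2", "snv"): [("strelka2_snv_qss>=300", "qss", ">=", 300)],
        ("strelka1", "indel"): [("strelka1_indel_qsi>=60", "qsi", ">=", 60)],
        ("strelka2", "indel"): [("strelka2_indel_qsi>=100", "qsi", ">=", 100)],
        ("mutect2", None): [("mutect2_tlod>=30", "tlod", ">=", 30)],
        ("freebayes", None): [("freebayes_ssc>=300", "ssc", ">=", 300)],
        ("manta", None): [("manta_somaticscore>=30", "somaticscore", ">=", 30)],
        ("pindel", None): [
            ("pindel_ad>=10", "ad", ">=", 10),
            ("pindel_vaf>0.1", "vaf", ">", 0.10),
        ],
    },
}


def somatic_score(v: Mapping[str, float] | pd.Series) -> float:
    """Somatic score from tumor/normal genotype likelihoods.

    ``SSC = T.GL(T) - T.GL(N) + N.GL(N) - N.GL(T)`` where ``T.GL(x)`` is the
    tumor sample's genotype likelihood under genotype ``x`` and ``N.GL(x)``
    the normal sample's. The formula is scale-agnostic (log10 or phred
    likelihoods both work) and antisymmetric under swapping the tumor and
    normal roles. Raises ``ValueError`` naming the field if any likelihood
    is missing.
    """
    vals = {}
    for f in _GL_FIELDS:
        x = v.get(f) if isinstance(v, Mapping) else v.get(f, None)
        if x is None or (isinstance(x, float) and np.isnan(x)):
            raise ValueError(f"somatic_score: missing genotype likelihood field {f!r}")
        vals[f] = float(x)
    return vals["gl_t_t"] - vals["gl_t_n"] + vals["gl_n_n"] - vals["gl_n_t"]


def _rules_for(
    table: dict, caller: str, variant_class: str
) -> list[tuple[str, str, str, float]]:
    if (caller, variant_class) in table:
        return table[(caller, variant_class)]
    if (caller, None) in table:
        return table[(caller, None)]
    raise KeyError(caller)


def filter_candidates(
    rows: pd.DataFrame,
    dialect: str,
    thresholds: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-caller quality filters for the chosen dialect.

    Parameters
    ----------
    rows
        Candidate table with at least ``caller`` and ``variant_class``
        columns plus the score fields each caller requires. Freebayes rows
        need the four ``gl_*`` likelihoods, from which the somatic score is
        computed on the fly.
    dialect
        ``"wes"`` or ``"targeted_pcr"`` (the latter uses stricter strelka
        and freebayes cut-offs).

    Returns
    -------
    ``(kept, removed)`` — an order-stable, disjoint partition of the input;
    ``removed`` carries a ``reason`` column naming the first failed rule.
    Unknown callers raise ``ValueError``.
    """
    if dialect not in DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {list(DEFAULT_THRESHOLDS)}")
    table = (thresholds or DEFAULT_THRESHOLDS)[dialect]

    keep_mask = np.ones(len(rows), dtype=bool)
    reasons: list[str | None] = [None] * len(rows)
    for i, (_, row) in enumerate(rows.iterrows()):
        caller = row["caller"]
        if caller not in CALLERS:
            raise ValueError(f"unknown caller {caller!r}")
        rules = _rules_for(table, caller, row.get("variant_class"))
        for name, fld, op, cut in rules:
            value = somatic_score(row) if fld == "ssc" else row.get(fld)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                keep_mask[i], reasons[i] = False, f"{name}:missing_{fld}"
                break
            ok = value >= cut if op == ">=" else value > cut
            if not ok:
                keep_mask[i], reasons[i] = False, name
                break
    kept = rows[keep_mask].copy()
    removed = rows[~keep_mask].copy()
    removed["reason"] = [r for r in reasons if r is not None]
    return kept, removed


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Canonical (chrom, pos, ref, alt) key: minimal, left-aligned, 1-based.

    Shared suffix bases are trimmed first, then shared prefix bases (keeping
    at least one base on each allele and advancing ``pos`` per trimmed prefix
    base), following VCF normalization convention so the same event is
    comparable across patients and callers.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (str(chrom), int(pos), ref, alt)


def subtract_germline(
    rows: pd.DataFrame, skin_panel: Iterable[tuple]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove candidates present in the cultured-skin panel of normals.

    The panel is cohort-wide: a candidate is removed if its normalized key
    matches a skin variant from ANY patient, not only the matched biopsy.
    ``rows`` must carry ``chrom``, ``pos``, ``ref``, ``alt`` columns; panel
    entries are (chrom, pos, ref, alt) tuples (normalized on entry).

    Returns ``(kept, removed)``, an order-stable disjoint partition.
    """
    panel = {normalize_variant_key(*k) for k in skin_panel}
    keys = [
        normalize_variant_key(c, p, r, a)
        for c, p, r, a in zip(rows["chrom"], rows["pos"], rows["ref"], rows["alt"])
    ]
    in_panel = np.array([k in panel for k in keys], dtype=bool)
    removed = rows[in_panel].copy()
    if len(removed):
        removed["reason"] = "in_skin_panel"
    return rows[~in_panel].copy(), removed


def load_subtype_table(path: str | Path) -> pd.DataFrame:
    """Load a static genomic-subtype assignment table (TSV).

    Expected columns: ``sample_id`` (or ``gene``) and ``subtype``. This is a
    taxonomy lookup, not a computation; subtype definitions come from
    published classification schemes.
    """
    df = pd.read_csv(path, sep="\t")
    if "subtype" not in df.columns:
        raise ValueError("subtype table must have a 'subtype' column")
    return df
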