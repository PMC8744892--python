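"""Tissue specificity of enhancer repertoires and target-gene programs.

Two tissues' eRNA-producing site sets are compared at the site layer
(genomic overlap at 1 bp resolution) and at the gene layer (identity of
each site's nearest expressed gene).  A gene can be shared between
tissues even when no site overlaps — distinct tissue-specific enhancers
converging on the same target — and such convergent genes are flagged
explicitly.  Differential gene programs are compared as sets of regulated
(induced or repressed) genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import intersect_sets


@dataclass
class TissueOverlapReport:
    """Two-sided overlap counts with per-side specificity percentages."""

    size_a: int
    size_b: int
    a_only: int
    b_only: int
    shared_a: int
    shared_b: int
    pct_specific_a: float
    pct_specific_b: float
    shared_ids: list = field(default_factory=list)
    convergent_ids: list = field(default_factory=list)


def _pct(part: int, whole: int) -> float:
    return float("nan") if whole == 0 else 100.0 * part / whole


def compare_sites(egbs_a: pd.DataFrame, egbs_b: pd.DataFrame) -> TissueOverlapReport:
    """Overlap two tissues' eGBS sets at 1 bp resolution."""
    rep = intersect_sets(egbs_a, egbs_b, min_bp=1)
    return TissueOverlapReport(
        size_a=len(egbs_a), size_b=len(egbs_b),
        a_only=rep.a_only, b_only=rep.b_only,
        shared_a=rep.shared_a, shared_b=rep.shared_b,
        pct_specific_a=_pct(rep.a_only, len(egbs_a)),
        pct_specific_b=_pct(rep.b_only, len(egbs_b)),
        shared_ids=rep.shared_a_index,
    )


def compare_target_genes(
    annotated_a: pd.DataFrame, annotated_b: pd.DataFrame
) -> TissueOverlapReport:
    """Compare nearest-gene repertoires of two tissues' eGBS.

    Inputs are nearest-expressed-gene annotations (one row per site with
    ``chrom start end nearest_gene``), each produced against its own
    tissue's expressed-gene universe.  A shared gene whose supporting
    sites do not overlap across tissues (at 1 bp) is flagged convergent.
    """
    genes_a = set(annotated_a["nearest_gene"].dropna())
    genes_b = set(annotated_b["nearest_gene"].dropna())
    shared = sorted(genes_a & genes_b)

    site_rep = intersect_sets(annotated_a, annotated_b, min_bp=1)
    overlapping_a = annotated_a.loc[site_rep.shared_a_index, "nearest_gene"].dropna()
    overlapping_b = annotated_b.loc[site_rep.shared_b_index, "nearest_gene"].dropna()
    site_backed = set(overlapping_a) & set(overlapping_b)
    convergent = sorted(g for g in shared if g not in site_backed)

    return TissueOverlapReport(
        size_a=len(genes_a), size_b=len(genes_b),
        a_only=len(genes_a - genes_b), b_only=len(genes_b - genes_a),
        shared_a=len(shared), shared_b=len(shared),
        pct_specific_a=_pct(len(genes_a - genes_b), len(genes_a)),
        pct_specific_b=_pct(len(genes_b - genes_a), len(genes_b)),
        shared_ids=shared, convergent_ids=convergent,
    )


def de_specificity(de_a: pd.DataFrame, de_b: pd.DataFrame) -> tuple[float, float]:
    """Percent of each tissue's regulated genes exclusive to that tissue.

    Inputs carry a ``reg_class`` column (from
    :func:`ernascope.diffexp.classify_regulation`); regulated = induced or
    repressed.  Returns ``(pct_specific_a, pct_specific_b)``; a tissue
    with no regulated gene reports NaN.
    """
    reg_a = set(de_a.index[de_a["reg_class"].isin(["induced", "repressed"])])
    reg_b = set(de_b.index[de_b["reg_class"].isin(["induced", "repressed"])])
    pa = _pct(len(reg_a - reg_b), len(reg_a))
    pb = _pct(len(reg_b - reg_a), len(reg_b))
    return pa, pb
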