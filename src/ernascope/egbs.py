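"""Calling eRNA-producing binding sites (eGBS) by two complementary routes.

The *transcript-based* route starts from assembled nascent transcripts:
expressed transcripts that overlap no gene feature and lie more than 1 kb
from any TSS are intergenic nascent RNAs (iRNAs), and those overlapping a
known intergenic binding site by >= 1 bp are the eRNAs (several
transcripts may point at one site).

The *site-centric* route counts nascent fragments in fixed windows (four
nucleosomes, 588 bp) around every reproducible binding site, removes
undetected sites, applies the 5th-percentile expression gate over all
sites and samples of both conditions, and keeps the intergenic survivors.
It is the more sensitive of the two and is the default downstream set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, IntersectReport, classify_location, intersect_sets
from .quantify import CountMatrix, expression_gate, tpm


@dataclass
class EGBSResult:
    """Site-centric call set with the gate threshold that produced it."""

    calls: pd.DataFrame  # index: site_id; columns erna_expressed, intergenic
    threshold: float


def call_transcript_based(
    transcripts: pd.DataFrame,
    genes: list[GeneModel],
    igbs: pd.DataFrame,
    tss_distance: int = 1000,
    promoter_halfwidth: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Identify eRNAs from assembled transcripts.

    ``transcripts`` needs ``chrom start end`` plus a boolean ``expressed``
    column (from :func:`ernascope.quantify.expression_gate`); ``igbs`` is
    the intergenic reproducible peak set.  Returns ``(irnas, ernas,
    sites)``: the intergenic expressed transcripts, the subset overlapping
    a binding site by >= 1 bp, and the distinct sites they hit.
    """
    expressed = transcripts[transcripts["expressed"].astype(bool)]
    is_intergenic = []
    for _, rec in expressed.iterrows():
        iv = GenomicInterval(str(rec["chrom"]), int(rec["start"]), int(rec["end"]))
        is_intergenic.append(
            classify_location(iv, genes, tss_distance, promoter_halfwidth) == "intergenic"
        )
    irnas = expressed[np.array(is_intergenic, bool)] if len(expressed) else expressed
    if len(irnas) == 0 or len(igbs) == 0:
        return irnas, irnas.iloc[0:0], igbs.iloc[0:0]
    report = intersect_sets(irnas, igbs, min_bp=1)
    ernas = irnas.loc[report.shared_a_index]
    sites = igbs.loc[report.shared_b_index]
    return irnas, ernas, sites


def call_gbs_based(
    gbs_counts: CountMatrix,
    intergenic: pd.Series,
    percentile: float = 5.0,
    zero_policy: str = "any",
) -> EGBSResult:
    """Site-centric eGBS calling from windowed nascent counts.

    Sites undetected in the nascent libraries are removed first:
    ``zero_policy="any"`` (default) drops a site with a zero count in any
    sample, ``"all"`` only drops sites with zero counts throughout.  The
    survivors pass the TPM percentile gate (pooled over all samples of
    both conditions), and intergenic gated sites are the eGBS.
    """
    counts = gbs_counts.counts
    if zero_policy == "any":
        detected = (counts > 0).all(axis=1)
    elif zero_policy == "all":
        detected = counts.sum(axis=1) > 0
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    sub = CountMatrix(
        counts.loc[detected],
        gbs_counts.library_size,
        gbs_counts.feature_length.loc[detected],
        gbs_counts.sample_meta,
    )
    expr = tpm(sub)
    threshold, gated = expression_gate(expr, percentile=percentile)
    inter = intergenic.reindex(counts.index).fillna(False).astype(bool)
    erna = pd.Series(False, index=counts.index)
    erna.loc[gated.index[gated]] = True
    calls = pd.DataFrame(
        {
            "detected": detected,
            "passed_gate": erna,
            "intergenic": inter,
            "erna_expressed": erna & inter,
        },
        index=counts.index,
    )
    return EGBSResult(calls, threshold)


def combine_approaches(
    transcript_sites: pd.DataFrame,
    gbs_sites: pd.DataFrame,
    downstream: str = "gbs",
) -> tuple[IntersectReport, pd.DataFrame]:
    """Venn counts of the two call sets at 1 bp resolution plus the
    downstream analysis set (the site-centric set by default, the union of
    both when ``downstream="union"``)."""
    report = intersect_sets(transcript_sites, gbs_sites, min_bp=1)
    if downstream == "gbs":
        chosen = gbs_sites.copy()
    elif downstream == "union":
        only_a = transcript_sites.drop(index=report.shared_a_index)
        chosen = pd.concat([gbs_sites, only_a], ignore_index=True)
    else:
        raise ValueError(f"unknown downstream choice {downstream!r}")
    return report, chosen


def designate_polyA(
    total_transcripts: pd.DataFrame, polya_transcripts: pd.DataFrame
) -> pd.Series:
    """Flag total-library transcripts detected in the polyA-enriched library.

    A transcript is polyadenylated iff it overlaps a polyA-library
    transcript by >= 1 bp at the same locus.
    """
    if len(total_transcripts) == 0:
        return pd.Series(dtype=bool)
    if len(polya_transcripts) == 0:
        return pd.Series(False, index=total_transcripts.index)
    report = intersect_sets(total_transcripts, polya_transcripts, min_bp=1)
    out = pd.Series(False, index=total_transcripts.index)
    out.loc[report.shared_a_index] = True
    return out


def classify_chromatin(
    egbs: pd.DataFrame,
    atac_peaks: pd.DataFrame,
    k27ac_peaks: pd.DataFrame,
    k4me1_peaks: pd.DataFrame,
    min_bp: int = 10,
) -> pd.Series:
    """Active/poised/other chromatin state of each eRNA-producing site.

    active: accessible (ATAC) + H3K4me1 + H3K27ac; poised: accessible +
    H3K4me1 without H3K27ac; everything else is "other".  Mark peak sets
    must already be replicate-reproducible; overlaps use the ``min_bp``
    (10 bp) intersection rule.
    """
    def hits(marks: pd.DataFrame) -> pd.Series:
        if len(egbs) == 0 or len(marks) == 0:
            return pd.Series(False, index=egbs.index)
        rep = intersect_sets(egbs, marks, min_bp=min_bp)
        s = pd.Series(False, index=egbs.index)
        s.loc[rep.shared_a_index] = True
        return s

    has_atac, has_k27, has_k4 = hits(atac_peaks), hits(k27ac_peaks), hits(k4me1_peaks)
    out = pd.Series("other", index=egbs.index, dtype=object)
    out[has_atac & has_k4 & ~has_k27] = "poised"
    out[has_atac & has_k4 & has_k27] = "active"
    return out
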