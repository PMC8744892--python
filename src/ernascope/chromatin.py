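"""Reads-in-peaks normalisation and chromatin-feature dynamics at enhancers.

ChIP-style assays differ in both sequencing depth and signal-to-noise
(immunoprecipitation efficiency).  The reads-in-peaks (RiP) ratio — the
fraction of a sample's fragments falling into the assay's peak union —
captures both.  Size factors are the scaled reciprocal of the RiP ratio:
all ratios are divided by the smallest one (which thus maps to factor 1),
and factors are the reciprocals of the scaled ratios, so every factor is
<= 1.  These factors replace the internally estimated ones in the NB
differential test, which is the substitution mechanism the differential
binding analysis relies on.

Downstream, per-assay log2 fold-changes at differentially transcribed
enhancer sites are correlated with the eRNA fold-changes (Spearman), and
their distributions are compared between regulation groups with a
Kolmogorov-Smirnov gate followed, only when the gate opens, by a
Wilcoxon-Mann-Whitney test against the unchanged reference group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import SizeFactors, nb_wald_test
from .intervals import build_trees, merge_intervals
from .quantify import CountMatrix

#: significance tiers used when reporting stratified tests
STAR_LEVELS = ((1e-5, "***"), (1e-3, "**"), (0.1, "*"))


@dataclass
class RiPFactors:
    """Reads-in-peaks ratios and the size factors derived from them."""

    rip: pd.Series  # raw in-union fraction per sample
    scaled_rip: pd.Series  # rip / min(rip); the smallest sample maps to 1
    size_factor: pd.Series  # 1 / scaled_rip, all <= 1
    peak_union_id: str = ""

    def as_size_factors(self) -> SizeFactors:
        return SizeFactors(self.size_factor.copy(), "rip_reciprocal")


def peak_union(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Merged union of peaks across all replicates and conditions."""
    if not peak_sets:
        raise ValueError("need at least one peak set")
    return merge_intervals(pd.concat(peak_sets, ignore_index=True))


def rip_factors(
    fragments: dict[str, pd.DataFrame],
    union: pd.DataFrame,
    peak_union_id: str = "",
) -> RiPFactors:
    """Compute RiP ratios and reciprocal size factors for one assay.

    ``fragments`` maps sample ids to fragment frames; a fragment is in
    peaks when it overlaps the union by >= 1 bp.  Raises when a sample has
    no fragments or none in peaks.
    """
    trees = build_trees(union)
    rip = {}
    for sample, frags in fragments.items():
        if len(frags) == 0:
            raise ValueError(f"sample {sample} has no fragments")
        n_in = 0
        for chrom, s, e in zip(frags["chrom"], frags["start"], frags["end"]):
            tree = trees.get(str(chrom))
            if tree is not None and tree.overlaps(int(s), int(e)):
                n_in += 1
        if n_in == 0:
            raise ValueError(f"sample {sample} has zero reads in peaks")
        rip[sample] = n_in / len(frags)
    rip_s = pd.Series(rip)
    scaled = rip_s / rip_s.min()
    return RiPFactors(rip_s, scaled, 1.0 / scaled, peak_union_id)


def differential_features(
    assay_counts: dict[str, CountMatrix | pd.DataFrame],
    assay_factors: dict[str, SizeFactors],
    condition: dict[str, pd.Series | list],
    site_groups: pd.Series,
    levels: tuple[str, str] = ("control", "treated"),
) -> pd.DataFrame:
    """Differential occupancy per assay at regulated enhancer windows.

    ``site_groups`` maps site_id -> regulation class of its eRNA
    (induced/repressed/unchanged); only those sites are analysed.  Every
    assay needs >= 2 replicates per condition.  Returns one row per site
    with ``erna_group`` and per-assay ``<assay>_log2fc / _pvalue / _padj``
    columns.
    """
    keep = site_groups.dropna()
    keep = keep[keep.isin(["induced", "repressed", "unchanged"])]
    out = pd.DataFrame({"erna_group": keep})
    for assay, counts in assay_counts.items():
        mat = counts.counts if isinstance(counts, CountMatrix) else counts
        cond = pd.Series(list(condition[assay]), index=mat.columns)
        for level in levels:
            if (cond == level).sum() < 2:
                raise ValueError(f"assay {assay}: fewer than 2 replicates for {level!r}")
        res = nb_wald_test(mat, cond, size_factors=assay_factors[assay], levels=levels)
        res = res.reindex(keep.index)
        out[f"{assay}_log2fc"] = res["log2fc"]
        out[f"{assay}_pvalue"] = res["pvalue"]
        out[f"{assay}_padj"] = res["padj"]
    return out


def correlate_changes(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Spearman matrix over log2 fold-change columns.

    Average ranks on ties; constant columns yield NaN against every
    partner (their rank correlation is undefined).  The matrix is
    symmetric with a unit diagonal.
    """
    if columns is None:
        columns = [c for c in table.columns if c.endswith("_log2fc")]
    if len(table) < 3:
        raise ValueError("need at least 3 sites to correlate")
    k = len(columns)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        xi = table[columns[i]].to_numpy(float)
        if np.nanstd(xi) > 0:
            mat[i, i] = 1.0
        for j in range(i + 1, k):
            xj = table[columns[j]].to_numpy(float)
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue
            rho = stats.spearmanr(xi[ok], xj[ok]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=columns, columns=columns)


def _stars(p: float) -> str:
    for cut, mark in STAR_LEVELS:
        if p < cut:
            return mark
    return ""


def stratified_tests(
    table: pd.DataFrame,
    value_columns: list[str] | None = None,
    group_column: str = "erna_group",
    reference: str = "unchanged",
    gate_alpha: float = 0.05,
) -> pd.DataFrame:
    """KS-gated Wilcoxon-Mann-Whitney tests of each group against reference.

    Stage 1 compares each non-reference group's per-assay log2FC
    distribution to the reference with a two-sample Kolmogorov-Smirnov
    test; stage 2 runs the two-sided WMW (exact null for small tie-free
    groups, otherwise the normal approximation with tie and continuity
    correction) only where the KS p-value falls below ``gate_alpha``.  Groups smaller than 2 report NaN.  Stars follow
    p < 0.1 / 1e-3 / 1e-5.
    """
    if value_columns is None:
        value_columns = [c for c in table.columns if c.endswith("_log2fc")]
    groups = [g for g in table[group_column].dropna().unique() if g != reference]
    ref = table[table[group_column] == reference]
    rows = []
    for col in value_columns:
        ref_vals = ref[col].dropna().to_numpy()
        for g in sorted(groups):
            vals = table.loc[table[group_column] == g, col].dropna().to_numpy()
            row = {"assay": col.replace("_log2fc", ""), "group": g,
                   "n_group": len(vals), "n_reference": len(ref_vals)}
            if len(vals) < 2 or len(ref_vals) < 2:
                row.update(ks_pvalue=np.nan, gate_open=False,
                           wmw_pvalue=np.nan, stars="")
            else:
                ks = stats.ks_2samp(vals, ref_vals)
                gate_open = bool(ks.pvalue < gate_alpha)
                row.update(ks_pvalue=float(ks.pvalue), gate_open=gate_open)
                if gate_open:
                    # exact null for small tie-free groups, tie/continuity
                    # corrected normal approximation otherwise
                    wmw = stats.mannwhitneyu(
                        vals, ref_vals, alternative="two-sided", method="auto"
                    )
                    row.update(wmw_pvalue=float(wmw.pvalue), stars=_stars(float(wmw.pvalue)))
                else:
                    row.update(wmw_pvalue=np.nan, stars="")
            rows.append(row)
    return pd.DataFrame(rows)
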