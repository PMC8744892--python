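"""Fragment counting, windowed TPM, and the percentile expression gate.

Counting follows paired-end nascent-RNA practice: a fragment contributes
when its mapping quality is at least 20 and its length lies in
[50, 1000] bp; counting is unstranded and a fragment is credited to every
window it overlaps by >= 1 bp.  The library size of a sample is the number
of fragments passing the filters genome-wide, not only those in windows.

TPM here is the windowed variant

    tpm[f, s] = counts[f, s] * 1000 / (library_size[s] * length[f])

applied verbatim.  It omits the conventional per-sample renormalisation to
a million; because the downstream expression gate is a within-experiment
percentile, the monotone rescaling changes no call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import build_trees

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Integer fragment counts (features x samples) with sample metadata."""

    counts: pd.DataFrame  # index: feature_id, columns: sample_id
    library_size: pd.Series  # per sample
    feature_length: pd.Series  # per feature, bp
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)  # assay/condition/replicate

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.library_size.index.equals(self.counts.columns):
            self.library_size = self.library_size.reindex(self.counts.columns)
        if not self.feature_length.index.equals(self.counts.index):
            self.feature_length = self.feature_length.reindex(self.counts.index)
        if (self.feature_length <= 0).any():
            raise ValueError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionTable:
    """TPM matrix plus the per-feature mean and the gate verdict."""

    tpm: pd.DataFrame
    mean_expression: pd.Series
    expressed: pd.Series | None = None
    threshold: float | None = None


def _passing_mask(
    frags: pd.DataFrame, min_mapq: int, min_frag: int, max_frag: int
) -> tuple[pd.DataFrame, int]:
    """Coerce raw fragment records; return (clean numeric frame, n_malformed)."""
    n = len(frags)
    start = pd.to_numeric(frags["start"], errors="coerce")
    end = pd.to_numeric(frags["end"], errors="coerce")
    mapq = pd.to_numeric(frags["mapq"], errors="coerce")
    ok = start.notna() & end.notna() & mapq.notna() & (start >= 0) & (end > start)
    ok &= frags["chrom"].notna() & (frags["chrom"].astype(str) != "")
    n_malformed = int(n - ok.sum())
    clean = pd.DataFrame(
        {
            "chrom": frags["chrom"].astype(str)[ok],
            "start": start[ok].astype(int),
            "end": end[ok].astype(int),
            "mapq": mapq[ok].astype(float),
        }
    )
    length = clean["end"] - clean["start"]
    keep = (clean["mapq"] >= min_mapq) & (length >= min_frag) & (length <= max_frag)
    return clean.loc[keep], n_malformed


def count_fragments(
    fragments: dict[str, pd.DataFrame],
    windows: pd.DataFrame,
    min_mapq: int = 20,
    min_frag: int = 50,
    max_frag: int = 1000,
    sample_meta: pd.DataFrame | None = None,
    nominal_length: int | None = None,
    max_malformed_frac: float = 0.10,
) -> CountMatrix:
    """Count filtered fragments per window for each sample.

    Parameters
    ----------
    fragments
        Mapping sample_id -> fragment frame (``chrom start end name mapq
        strand``); values may be strings straight from disk.
    windows
        BED-like frame; its ``name`` column (or positional index) becomes
        the feature id.
    nominal_length
        When given, every feature's length is recorded as this constant
        (the fixed-window convention) instead of ``end - start``.

    A fragment overlapping k windows is counted once in each of them.
    Malformed records are skipped and tallied; more than
    ``max_malformed_frac`` of a sample malformed is a hard error.
    """
    windows = windows.reset_index(drop=True)
    if "name" in windows.columns and windows["name"].nunique() == len(windows):
        feature_ids = windows["name"].astype(str).tolist()
    else:
        feature_ids = [f"window_{i}" for i in range(len(windows))]
    trees = build_trees(windows)

    mat = np.zeros((len(windows), len(fragments)), dtype=int)
    libsize = {}
    for j, (sample, frags) in enumerate(fragments.items()):
        clean, n_malformed = _passing_mask(frags, min_mapq, min_frag, max_frag)
        if len(frags) and n_malformed / len(frags) > max_malformed_frac:
            raise ValueError(
                f"sample {sample}: {n_malformed}/{len(frags)} malformed fragment records"
            )
        if n_malformed:
            log.warning("sample %s: skipped %d malformed fragment records", sample, n_malformed)
        libsize[sample] = len(clean)
        for chrom, sub in clean.groupby("chrom", sort=False):
            tree = trees.get(str(chrom))
            if tree is None:
                continue
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                for hit in tree.overlap(int(s), int(e)):
                    mat[hit.data, j] += 1

    counts = pd.DataFrame(mat, index=feature_ids, columns=list(fragments))
    if nominal_length is not None:
        lengths = pd.Series(nominal_length, index=counts.index, dtype=int)
    else:
        lengths = pd.Series(
            (windows["end"] - windows["start"]).to_numpy(int), index=counts.index
        )
    meta = sample_meta if sample_meta is not None else pd.DataFrame(index=list(fragments))
    return CountMatrix(counts, pd.Series(libsize), lengths, meta)


def tpm(counts: CountMatrix) -> ExpressionTable:
    """Windowed TPM: ``counts * 1000 / (library_size * length)``.

    Raises if any library size is zero.  The per-feature mean is taken
    over all samples (both conditions pooled).
    """
    lib = counts.library_size.astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    vals = counts.counts.to_numpy(float) * 1000.0 / (
        lib.to_numpy()[None, :] * counts.feature_length.to_numpy(float)[:, None]
    )
    table = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionTable(tpm=table, mean_expression=table.mean(axis=1))


def expression_gate(
    expr: ExpressionTable, percentile: float = 5.0, strict: bool = True
) -> tuple[float, pd.Series]:
    """Flag features whose mean expression clears the percentile gate.

    Zero-mean features are removed before the threshold is taken: the
    threshold is the ``percentile``-th linear-interpolation percentile of
    the *non-zero* means, and a feature is expressed iff its mean is
    strictly above it.  Degenerate inputs where strictness would empty the
    set (single feature, or all means equal) fall back to ``>=`` with a
    warning.  Returns ``(threshold, expressed mask over all features)``.
    """
    means = expr.mean_expression
    nonzero = means[means > 0]
    if len(nonzero) == 0:
        raise ValueError("all features have zero mean expression")
    threshold = float(np.percentile(nonzero.to_numpy(), percentile))
    expressed = (means > threshold) if strict else (means >= threshold)
    if strict and not expressed.any():
        log.warning(
            "strict gate at threshold %g keeps no feature; falling back to >=", threshold
        )
        expressed = means >= threshold
    expr.expressed = expressed & (means > 0)
    expr.threshold = threshold
    return threshold, expr.expressed
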