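"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is handled natively in the package's internal 0-based half-open
convention.  GTF is written 1-based closed (the format's convention) and
converted back on read (start − 1).  Count matrices are TSV with feature
ids as the index and sample ids as columns; provenance travels in JSON
sidecars next to every written table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .intervals import BED6_COLUMNS, GeneModel, GenomicInterval

FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "mapq", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3–BED6 into a frame with the standard six columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a fragment BED (MAPQ in the score column) without validation.

    Malformed records are the caller's concern: :func:`ernascope.quantify.
    count_fragments` skips and tallies them.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=FRAGMENT_COLUMNS, dtype=str,
    )
    return df


def write_fragments(df: pd.DataFrame, path: str | Path) -> None:
    df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_gtf(genes: list[GeneModel], path: str | Path, source: str = "ernascope") -> None:
    """Write gene models as GTF (1-based, closed intervals).

    Emits ``gene`` plus exon/intron/UTR features; promoters are not GTF
    features and are written separately as BED.
    """
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; expressed "{str(g.expressed).lower()}";'
            fh.write(
                "\t".join(
                    [g.span.chrom, source, "gene", str(g.span.start + 1), str(g.span.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            for kind, iv in g.features:
                if kind == "promoter":
                    continue
                fh.write(
                    "\t".join(
                        [iv.chrom, source, kind, str(iv.start + 1), str(iv.end),
                         ".", g.strand, ".", attrs]
                    )
                    + "\n"
                )


def _parse_gtf_attrs(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip('"')
    return out


def read_gtf(path: str | Path, promoter_halfwidth: int = 1000) -> list[GeneModel]:
    """Rebuild :class:`GeneModel` objects from a GTF file.

    The TSS is the 5' end of the gene span; a promoter feature of
    ``promoter_halfwidth`` bp on either side of each TSS is synthesised
    (clipped to the gene span, which by construction extends past the TSS).
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, kind, start, end, _score, strand, _frame, attrs = line.rstrip("\n").split("\t")
            info = _parse_gtf_attrs(attrs)
            gid = info["gene_id"]
            rec = genes.setdefault(gid, {"features": [], "span": None, "strand": strand,
                                         "chrom": chrom, "expressed": True})
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if kind == "gene":
                rec["span"] = iv
                rec["expressed"] = info.get("expressed", "true") == "true"
            else:
                rec["features"].append((kind, iv))
    out = []
    for gid, rec in genes.items():
        span = rec["span"]
        if span is None:
            raise ValueError(f"gene {gid} has features but no gene record")
        tss = [span.start if rec["strand"] == "+" else span.end - 1]
        feats = list(rec["features"])
        for pos in tss:
            s = max(span.start, pos - promoter_halfwidth)
            e = min(span.end, pos + promoter_halfwidth)
            if s < e:
                feats.append(("promoter", GenomicInterval(span.chrom, s, e, rec["strand"])))
        out.append(GeneModel(gid, span, tss, feats, rec["expressed"]))
    return out


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(table_path: str | Path, payload: dict) -> Path:
    """Write a JSON provenance sidecar next to a written table."""
    side = Path(str(table_path) + ".json")
    with open(side, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return side
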