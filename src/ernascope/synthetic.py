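"""Synthetic two-tissue nascent-transcription experiments with known truth.

The generator emulates the data structure of a glucocorticoid-response
study: a small multi-chromosome genome with gene models, two-replicate
ChIP peak sets per tissue with controlled reproducibility and cross-tissue
sharing, negative-binomial fragment counts at genes and at binding-site
windows (a configurable subset of intergenic sites carries true eRNA
transcription with induced/repressed/unchanged condition effects), and
chromatin-feature counts whose condition log2 fold-changes are mixed with
the eRNA fold-changes at a configurable target Spearman correlation.

Everything is driven by one :class:`SimConfig`; an identical config
produces byte-identical outputs.  Placement is slot-based: genes and
binding sites occupy disjoint genomic slots with >= 1 kb spacing between
site centers, so fixed-width counting windows around distinct sites never
overlap and truth bookkeeping stays exact.

Counts follow NB(mu * s_j * 2^(x_j * lfc), alpha) with var = mu + alpha *
mu^2, where x_j is 1 for treated samples.  Fragments are emitted as BED
records with a mapping-quality column; a configurable fraction violates
the MAPQ/length filters so the counting stage is genuinely exercised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval

CONDITIONS = ("control", "treated")
CHROMATIN_ASSAYS = (
    "ATAC", "H3K27ac", "H3K4me1", "H3K4me2", "H3K4me3",
    "BRD4", "RNAP2", "SETD1A", "CXXC1",
)

_PROMOTER_PAD = 1000
_INTERGENIC_SLOT = 1400
_GENIC_SLOT = 700
_SLOT_MARGIN = 300


class SimulationInfeasibleError(RuntimeError):
    """Raised when a configuration cannot be realised, naming the constraint."""


def _default_feature_corr() -> dict[str, float]:
    return {
        "ATAC": 0.75, "H3K27ac": 0.75, "BRD4": 0.75,
        "H3K4me1": 0.2, "H3K4me2": 0.2, "H3K4me3": 0.2,
        "RNAP2": 0.6, "SETD1A": 0.5, "CXXC1": 0.5,
    }


@dataclass
class SimConfig:
    """All tunables of one synthetic experiment.

    Defaults describe the reference study condition: 625 sites per tissue
    of which 80% are intergenic and 80% replicate-reproducible, half of
    the reproducible intergenic sites truly eRNA-producing, 60 induced and
    60 repressed at |log2FC| = 2, three replicates per condition for the
    nascent libraries and two for each chromatin assay.
    """

    # genome
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 60
    frac_genes_expressed: float = 0.8
    # peaks
    n_peaks_per_tissue: int = 625
    frac_reproducible: float = 0.8
    frac_intergenic: float = 0.8
    frac_shared_tissue: float = 0.1
    peak_width_min: int = 150
    peak_width_max: int = 400
    jitter: int = 50
    # eRNA truth
    frac_ernaproducing: float = 0.5
    n_induced: int = 60
    n_repressed: int = 60
    lfc_induced: float = 2.0
    lfc_repressed: float = 2.0
    # counts
    nb_mean_gene: float = 100.0
    nb_mean_erna: float = 50.0
    background_ratio: float = 50.0  # mu_background = nb_mean_erna / background_ratio
    nb_mean_feature: float = 30.0
    nb_dispersion: float = 0.1
    libsize_sigma: float = 0.15
    n_replicates_nascent: int = 3
    n_replicates_chromatin: int = 2
    # chromatin structure
    feature_corr: dict[str, float] = field(default_factory=_default_feature_corr)
    frac_active: float = 0.658
    frac_poised: float = 0.287
    mark_background_rate: float = 0.2
    # genes / transcripts
    frac_genes_induced: float = 0.1
    frac_genes_repressed: float = 0.1
    gene_lfc: float = 1.5
    frac_gene_program_shared: float = 0.4
    frac_polyA: float = 0.576
    frac_erna_polyA: float = 0.002
    frac_two_transcripts: float = 0.3
    n_decoy_transcripts: int = 50
    # fragment realisation
    frag_len_min: int = 150
    frag_len_max: int = 400
    frac_bad_fragments: float = 0.05
    frac_background_fragments: float = 0.2
    n_rip_fragments: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        props = {
            "frac_reproducible": self.frac_reproducible,
            "frac_intergenic": self.frac_intergenic,
            "frac_shared_tissue": self.frac_shared_tissue,
            "frac_ernaproducing": self.frac_ernaproducing,
            "frac_genes_expressed": self.frac_genes_expressed,
            "frac_polyA": self.frac_polyA,
            "frac_active": self.frac_active,
            "frac_poised": self.frac_poised,
        }
        for name, v in props.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_chromosomes", "chrom_length", "n_peaks_per_tissue",
                     "n_replicates_nascent", "n_replicates_chromatin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0 or self.n_induced < 0 or self.n_repressed < 0:
            raise ValueError("counts must be non-negative")
        if self.nb_dispersion < 0 or self.nb_mean_gene < 0 or self.nb_mean_erna < 0:
            raise ValueError("NB parameters must be non-negative")
        if 2 * self.jitter >= self.peak_width_min:
            raise ValueError(
                f"jitter {self.jitter} exceeds half the minimum peak width "
                f"{self.peak_width_min}; replicate overlap would not be guaranteed"
            )
        n_rep_int = round(round(self.n_peaks_per_tissue * self.frac_intergenic)
                          * self.frac_reproducible)
        n_erna = round(n_rep_int * self.frac_ernaproducing)
        if self.n_induced + self.n_repressed > n_erna:
            raise ValueError(
                f"n_induced + n_repressed = {self.n_induced + self.n_repressed} exceeds "
                f"the {n_erna} true eRNA-producing reproducible intergenic sites"
            )

    @property
    def mu_background(self) -> float:
        return self.nb_mean_erna / self.background_ratio


@dataclass
class SimTruth:
    """Ground-truth bookkeeping of one simulated experiment."""

    sites: pd.DataFrame  # one row per underlying site
    genes: pd.DataFrame  # one row per gene
    transcripts: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    rip: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # one independent, order-insensitive stream per stage
    return np.random.default_rng([config.seed, stage])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB with var = mu + alpha mu^2; Poisson in the alpha -> 0 limit."""
    mu = np.asarray(mu, float)
    if (mu < 0).any() or alpha < 0:
        raise ValueError("negative NB mean or dispersion")
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


# ---------------------------------------------------------------------------
# genome

def simulate_genome(config: SimConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Place non-overlapping gene models leaving >= 3 kb intergenic gaps.

    Each gene carries a 1 kb promoter pad on the TSS side inside its span,
    5'/3' UTRs, 2-4 exons with introns between, and an ``expressed`` flag
    on a deterministic fraction of genes.
    """
    rng = _rng(config, 0)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    chroms = list(chrom_sizes)
    genes: list[GeneModel] = []
    cursors = {c: 2000 for c in chroms}
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        tx_len = int(rng.integers(3000, 7001))
        strand = "+" if rng.random() < 0.5 else "-"
        footprint = tx_len + _PROMOTER_PAD
        start = cursors[chrom]
        end = start + footprint
        if end > config.chrom_length - 2000:
            raise SimulationInfeasibleError(
                f"gene {i} does not fit on {chrom}: footprint end {end} exceeds "
                f"usable length {config.chrom_length - 2000}; reduce n_genes or "
                f"increase chrom_length"
            )
        if strand == "+":
            tx_start, tx_end = start + _PROMOTER_PAD, end
            tss = tx_start
        else:
            tx_start, tx_end = start, start + tx_len
            tss = tx_end - 1
        feats = _gene_features(chrom, tx_start, tx_end, strand, rng)
        prom_s = max(start, tss - _PROMOTER_PAD)
        prom_e = min(end, tss + _PROMOTER_PAD)
        feats.append(("promoter", GenomicInterval(chrom, prom_s, prom_e, strand)))
        gid = f"gene{i:04d}"
        genes.append(GeneModel(gid, GenomicInterval(chrom, start, end, strand),
                               [tss], feats, expressed=True))
        cursors[chrom] = end + 3000 + int(rng.integers(0, 2001))
    # expressed flags: deterministic count, randomly assigned
    n_expr = round(config.frac_genes_expressed * config.n_genes)
    order = rng.permutation(config.n_genes)
    expressed = set(order[:n_expr])
    for k, g in enumerate(genes):
        g.expressed = k in expressed
    return genes, chrom_sizes


def _gene_features(chrom: str, tx_start: int, tx_end: int, strand: str,
                   rng: np.random.Generator) -> list[tuple[str, GenomicInterval]]:
    length = tx_end - tx_start
    n_exons = int(rng.integers(2, 5))
    utr5, utr3, exon = 200, 300, 300
    fixed = utr5 + utr3 + n_exons * exon
    n_introns = n_exons - 1
    intron = (length - fixed) // n_introns
    blocks: list[tuple[str, int]] = [("five_prime_utr", utr5)]
    for k in range(n_exons):
        blocks.append(("exon", exon))
        if k < n_introns:
            blocks.append(("intron", intron))
    blocks.append(("three_prime_utr", utr3))
    if strand == "-":
        blocks = blocks[::-1]
    feats, pos = [], tx_start
    for kind, size in blocks:
        end = min(pos + size, tx_end)
        if kind == blocks[-1][0] and size == blocks[-1][1]:
            end = tx_end if pos + size >= tx_end - n_introns else end
        feats.append((kind, GenomicInterval(chrom, pos, max(end, pos + 1), strand)))
        pos = end
    # absorb rounding remainder into the last block
    kind, iv = feats[-1]
    if iv.end < tx_end:
        feats[-1] = (kind, GenomicInterval(chrom, iv.start, tx_end, strand))
    return feats


def _transcribed_region(gene: GeneModel) -> tuple[int, int]:
    coords = [(iv.start, iv.end) for k, iv in gene.features if k != "promoter"]
    return min(s for s, _ in coords), max(e for _, e in coords)


def _intergenic_slots(config: SimConfig, genes: list[GeneModel],
                      chrom_sizes: dict[str, int]) -> list[tuple[str, int, int]]:
    slots = []
    for chrom, size in chrom_sizes.items():
        spans = sorted((g.span.start, g.span.end) for g in genes if g.span.chrom == chrom)
        edges = [(0, spans[0][0] if spans else size)]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            edges.append((e1, s2))
        if spans:
            edges.append((spans[-1][1], size))
        for gap_s, gap_e in edges:
            lo, hi = gap_s + _SLOT_MARGIN, gap_e - _SLOT_MARGIN
            k = max(0, (hi - lo) // _INTERGENIC_SLOT)
            for j in range(int(k)):
                slots.append((chrom, lo + j * _INTERGENIC_SLOT,
                              lo + (j + 1) * _INTERGENIC_SLOT))
    return slots


def _genic_slots(genes: list[GeneModel]) -> list[tuple[str, int, int]]:
    slots = []
    for g in genes:
        tx_s, tx_e = _transcribed_region(g)
        k = (tx_e - tx_s) // _GENIC_SLOT
        for j in range(int(k)):
            slots.append((g.span.chrom, tx_s + j * _GENIC_SLOT, tx_s + (j + 1) * _GENIC_SLOT))
    return slots


# ---------------------------------------------------------------------------
# peaks

def simulate_peaks(
    config: SimConfig, genes: list[GeneModel], chrom_sizes: dict[str, int]
) -> tuple[dict[tuple[str, int], pd.DataFrame], pd.DataFrame]:
    """Emit two-replicate peak sets for two tissues plus the site truth table.

    Returns ``(peaks, sites)`` where ``peaks[(tissue, rep)]`` is a BED6
    frame (tissue in {"A", "B"}, rep in {1, 2}) and ``sites`` holds one
    row per underlying site with its tissue membership, reproducibility,
    intergenic flag, eRNA truth, true log2FC and regulation class.
    """
    rng = _rng(config, 1)
    n_peaks = config.n_peaks_per_tissue
    n_shared = round(config.frac_shared_tissue * n_peaks)
    n_int = round(config.frac_intergenic * n_peaks)
    n_shared_int = round(config.frac_intergenic * n_shared)
    n_shared_gen = n_shared - n_shared_int
    n_only_int = n_int - n_shared_int
    n_only_gen = (n_peaks - n_int) - n_shared_gen

    int_slots = _intergenic_slots(config, genes, chrom_sizes)
    gen_slots = _genic_slots(genes)
    need_int = n_shared_int + 2 * n_only_int
    need_gen = n_shared_gen + 2 * n_only_gen
    if need_int > len(int_slots):
        raise SimulationInfeasibleError(
            f"need {need_int} intergenic site slots but the genome layout offers "
            f"{len(int_slots)}; increase chrom_length or n_chromosomes"
        )
    if need_gen > len(gen_slots):
        raise SimulationInfeasibleError(
            f"need {need_gen} genic site slots but the gene models offer "
            f"{len(gen_slots)}; increase n_genes or gene length"
        )

    int_pick = [int_slots[i] for i in rng.permutation(len(int_slots))[:need_int]]
    gen_pick = [gen_slots[i] for i in rng.permutation(len(gen_slots))[:need_gen]]

    rows = []

    def _emit(slots, intergenic, membership_plan):
        for slot, member in zip(slots, membership_plan):
            chrom, lo, hi = slot
            w = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
            wiggle = (hi - lo - w) // 2 - config.jitter - 10
            off = int(rng.integers(-wiggle, wiggle + 1)) if wiggle > 0 else 0
            start = lo + (hi - lo - w) // 2 + off
            rows.append({
                "site_id": f"site{len(rows):05d}", "chrom": chrom,
                "start": start, "end": start + w,
                "tissues": member, "intergenic": intergenic,
            })

    _emit(int_pick[:n_shared_int], True, ["AB"] * n_shared_int)
    _emit(int_pick[n_shared_int:n_shared_int + n_only_int], True, ["A"] * n_only_int)
    _emit(int_pick[n_shared_int + n_only_int:], True, ["B"] * n_only_int)
    _emit(gen_pick[:n_shared_gen], False, ["AB"] * n_shared_gen)
    _emit(gen_pick[n_shared_gen:n_shared_gen + n_only_gen], False, ["A"] * n_only_gen)
    _emit(gen_pick[n_shared_gen + n_only_gen:], False, ["B"] * n_only_gen)
    sites = pd.DataFrame(rows)

    # reproducibility: exact counts per (tissue, intergenic) stratum
    for tissue in ("A", "B"):
        flag = np.zeros(len(sites), dtype=bool)
        member = sites["tissues"].str.contains(tissue)
        for intergenic in (True, False):
            stratum = np.flatnonzero(member & (sites["intergenic"] == intergenic))
            k = round(config.frac_reproducible * len(stratum))
            chosen = stratum[rng.permutation(len(stratum))[:k]]
            flag[chosen] = True
        sites[f"reproducible_{tissue}"] = flag

    # eRNA truth among reproducible intergenic sites; shared sites keep one flag
    erna = np.zeros(len(sites), dtype=bool)
    cand_a = np.flatnonzero(sites["reproducible_A"] & sites["intergenic"]
                            & sites["tissues"].str.contains("A"))
    n_erna_a = round(config.frac_ernaproducing * len(cand_a))
    erna[cand_a[rng.permutation(len(cand_a))[:n_erna_a]]] = True
    cand_b = np.flatnonzero(sites["reproducible_B"] & sites["intergenic"]
                            & sites["tissues"].str.contains("B"))
    n_erna_b = round(config.frac_ernaproducing * len(cand_b))
    already = int(erna[cand_b].sum())
    fill = np.array([i for i in cand_b[rng.permutation(len(cand_b))]
                     if not erna[i] and sites.loc[i, "tissues"] == "B"], dtype=int)
    erna[fill[:max(0, n_erna_b - already)]] = True
    sites["true_erna_A"] = erna & sites["tissues"].str.contains("A") & sites["reproducible_A"]
    sites["true_erna_B"] = erna & sites["tissues"].str.contains("B") & sites["reproducible_B"]

    # regulation truth for the analysis tissue (A)
    lfc = np.zeros(len(sites))
    reg = np.where(sites["true_erna_A"], "unchanged", "none").astype(object)
    erna_a = np.flatnonzero(sites["true_erna_A"])
    order = erna_a[rng.permutation(len(erna_a))]
    lfc[order[:config.n_induced]] = config.lfc_induced
    reg[order[:config.n_induced]] = "induced"
    lfc[order[config.n_induced:config.n_induced + config.n_repressed]] = -config.lfc_repressed
    reg[order[config.n_induced:config.n_induced + config.n_repressed]] = "repressed"
    sites["true_lfc"] = lfc
    sites["reg_class"] = reg

    # chromatin class for true eRNA sites of tissue A
    cls = np.full(len(sites), "none", dtype=object)
    n_active = round(config.frac_active * len(erna_a))
    n_poised = round(config.frac_poised * len(erna_a))
    shuffled = erna_a[rng.permutation(len(erna_a))]
    cls[shuffled[:n_active]] = "active"
    cls[shuffled[n_active:n_active + n_poised]] = "poised"
    cls[shuffled[n_active + n_poised:]] = "other"
    sites["chromatin_class"] = cls

    peaks = {}
    for tissue in ("A", "B"):
        member = sites["tissues"].str.contains(tissue)
        rep_rows: dict[int, list[dict]] = {1: [], 2: []}
        for i in np.flatnonzero(member):
            rec = sites.iloc[i]
            base = {"chrom": rec["chrom"], "name": rec["site_id"],
                    "score": 0.0, "strand": "."}
            if rec[f"reproducible_{tissue}"]:
                d1, d2 = rng.integers(-config.jitter, config.jitter + 1, size=2)
                rep_rows[1].append({**base, "start": int(rec["start"]), "end": int(rec["end"])})
                rep_rows[2].append({**base, "start": int(rec["start"] + d1),
                                    "end": int(rec["end"] + d2)})
            else:
                target = 1 if rng.random() < 0.5 else 2
                rep_rows[target].append({**base, "start": int(rec["start"]), "end": int(rec["end"])})
        for rep in (1, 2):
            df = pd.DataFrame(rep_rows[rep],
                              columns=["chrom", "start", "end", "name", "score", "strand"])
            peaks[(tissue, rep)] = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return peaks, sites


# ---------------------------------------------------------------------------
# genes / transcripts truth

def _gene_truth(config: SimConfig, genes: list[GeneModel],
                rng: np.random.Generator) -> pd.DataFrame:
    df = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.span.chrom for g in genes],
        "expressed": [g.expressed for g in genes],
    })
    n_expr_idx = np.flatnonzero(df["expressed"])
    n_reg = round(config.frac_genes_induced * len(n_expr_idx))
    n_rep = round(config.frac_genes_repressed * len(n_expr_idx))
    for tissue in ("A", "B"):
        df[f"true_lfc_{tissue}"] = 0.0
    # shared program: a deterministic fraction of each tissue's regulated
    # genes is common to both tissues, same direction
    order = n_expr_idx[rng.permutation(len(n_expr_idx))]
    n_shared_ind = round(config.frac_gene_program_shared * n_reg)
    n_shared_rep = round(config.frac_gene_program_shared * n_rep)
    pos = 0

    def take(k):
        nonlocal pos
        out = order[pos:pos + k]
        pos += k
        return out

    shared_ind = take(n_shared_ind)
    shared_rep = take(n_shared_rep)
    a_ind = take(n_reg - n_shared_ind)
    a_rep = take(n_rep - n_shared_rep)
    b_ind = take(n_reg - n_shared_ind)
    b_rep = take(n_rep - n_shared_rep)
    for idx, col, sign in [
        (shared_ind, "true_lfc_A", 1), (shared_ind, "true_lfc_B", 1),
        (shared_rep, "true_lfc_A", -1), (shared_rep, "true_lfc_B", -1),
        (a_ind, "true_lfc_A", 1), (a_rep, "true_lfc_A", -1),
        (b_ind, "true_lfc_B", 1), (b_rep, "true_lfc_B", -1),
    ]:
        df.loc[idx, col] = sign * config.gene_lfc
    df["polyA"] = False
    expr_idx = np.flatnonzero(df["expressed"])
    n_pa = round(config.frac_polyA * len(expr_idx))
    df.loc[expr_idx[rng.permutation(len(expr_idx))[:n_pa]], "polyA"] = True
    return df


def _transcript_truth(config: SimConfig, genes: list[GeneModel], gene_truth: pd.DataFrame,
                      sites: pd.DataFrame, chrom_sizes: dict[str, int],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Nascent transcript spans: genic per expressed gene, 1-2 per true eRNA
    site, plus intergenic decoys at unused intergenic locations."""
    rows = []
    gmap = {g.gene_id: g for g in genes}
    for _, rec in gene_truth.iterrows():
        if not rec["expressed"]:
            continue
        g = gmap[rec["gene_id"]]
        tx_s, tx_e = _transcribed_region(g)
        rows.append({
            "transcript_id": f"tx_{rec['gene_id']}", "chrom": g.span.chrom,
            "start": tx_s, "end": tx_e, "origin": "gene", "source_id": rec["gene_id"],
            "mu": config.nb_mean_gene, "true_lfc": rec["true_lfc_A"],
            "polyA": bool(rec["polyA"]),
        })
    for _, rec in sites[sites["true_erna_A"]].iterrows():
        n_tx = 2 if rng.random() < config.frac_two_transcripts else 1
        for t in range(n_tx):
            ext_l = int(rng.integers(0, 151))
            ext_r = int(rng.integers(0, 151))
            rows.append({
                "transcript_id": f"tx_{rec['site_id']}_{t}", "chrom": rec["chrom"],
                "start": int(rec["start"]) - ext_l, "end": int(rec["end"]) + ext_r,
                "origin": "erna", "source_id": rec["site_id"],
                "mu": config.nb_mean_erna / n_tx, "true_lfc": rec["true_lfc"],
                "polyA": bool(rng.random() < config.frac_erna_polyA),
            })
    # decoys: intergenic transcripts away from any site
    used = set(zip(sites["chrom"], sites["start"] // _INTERGENIC_SLOT))
    placed = 0
    for chrom, size in chrom_sizes.items():
        pos = size - 5000
        while placed < config.n_decoy_transcripts and pos > size - 200_000:
            rows.append({
                "transcript_id": f"tx_decoy{placed:03d}", "chrom": chrom,
                "start": pos, "end": pos + int(rng.integers(300, 800)),
                "origin": "decoy", "source_id": "",
                "mu": config.nb_mean_erna / 2.0, "true_lfc": 0.0, "polyA": False,
            })
            placed += 1
            pos -= 2000
        if placed >= config.n_decoy_transcripts:
            break
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counts

def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for cond in CONDITIONS:
        for r in range(1, config.n_replicates_nascent + 1):
            rows.append({"sample_id": f"nascent_{cond}_r{r}", "assay": "nascent",
                         "condition": cond, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    config: SimConfig,
    genes: list[GeneModel],
    sites: pd.DataFrame,
    gene_truth: pd.DataFrame,
    transcripts: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Draw NB count matrices for every assay.

    Returns ``(counts, truth)``; ``counts`` maps matrix names
    (``nascent_gbs_A``, ``transcript_total``, ``transcript_polyA``,
    ``genes_A``, ``genes_B``, and one per chromatin assay) to integer
    frames.  Per-sample true scale factors and per-assay RiP ratios are
    recorded on the returned truth.
    """
    rng = _rng(config, 2)
    alpha = config.nb_dispersion
    n_rep = config.n_replicates_nascent
    nascent_samples = [f"nascent_{c}_r{r}" for c in CONDITIONS for r in range(1, n_rep + 1)]
    treated = np.array([1 if "treated" in s else 0 for s in nascent_samples])
    sf_nascent = np.exp(rng.normal(0.0, config.libsize_sigma, len(nascent_samples)))

    counts: dict[str, pd.DataFrame] = {}
    sample_rows = [
        {"sample_id": s, "assay": "nascent", "condition": c, "true_size_factor": f}
        for s, c, f in zip(nascent_samples,
                           [c for c in CONDITIONS for _ in range(n_rep)], sf_nascent)
    ]

    # nascent counts at reproducible tissue-A site windows
    rep_a = sites[sites["reproducible_A"] & sites["tissues"].str.contains("A")]
    gene_expr = dict(zip(gene_truth["gene_id"], gene_truth["expressed"]))
    site_gene = _host_gene(rep_a, genes)
    mu_base = np.where(
        rep_a["true_erna_A"], config.nb_mean_erna,
        np.where(rep_a["intergenic"], config.mu_background,
                 [config.nb_mean_erna if gene_expr.get(g, False) else config.mu_background
                  for g in site_gene]),
    )
    lfc = rep_a["true_lfc"].to_numpy()
    mu = mu_base[:, None] * sf_nascent[None, :] * 2.0 ** (treated[None, :] * lfc[:, None])
    counts["nascent_gbs_A"] = pd.DataFrame(
        _nb_draw(rng, mu, alpha), index=rep_a["site_id"].to_numpy(), columns=nascent_samples
    )

    # background transcription at non-eRNA intergenic sites (fragment source)
    bg_a = rep_a[rep_a["intergenic"] & ~rep_a["true_erna_A"]]
    mu_bg = np.full((len(bg_a), len(nascent_samples)), config.mu_background) * sf_nascent[None, :]
    counts["background_sites_A"] = pd.DataFrame(
        _nb_draw(rng, mu_bg, alpha), index=bg_a["site_id"].to_numpy(), columns=nascent_samples
    )

    # tissue-B site counts (no condition effect simulated for tissue B)
    rep_b = sites[sites["reproducible_B"] & sites["tissues"].str.contains("B")]
    sf_b = np.exp(rng.normal(0.0, config.libsize_sigma, len(nascent_samples)))
    site_gene_b = _host_gene(rep_b, genes)
    mu_base_b = np.where(
        rep_b["true_erna_B"], config.nb_mean_erna,
        np.where(rep_b["intergenic"], config.mu_background,
                 [config.nb_mean_erna if gene_expr.get(g, False) else config.mu_background
                  for g in site_gene_b]),
    )
    counts["nascent_gbs_B"] = pd.DataFrame(
        _nb_draw(rng, mu_base_b[:, None] * sf_b[None, :], alpha),
        index=rep_b["site_id"].to_numpy(),
        columns=[s.replace("nascent_", "nascentB_") for s in nascent_samples],
    )

    # transcript-level nascent counts (total and polyA libraries)
    mu_tx = transcripts["mu"].to_numpy()[:, None] * sf_nascent[None, :] * 2.0 ** (
        treated[None, :] * transcripts["true_lfc"].to_numpy()[:, None]
    )
    counts["transcript_total"] = pd.DataFrame(
        _nb_draw(rng, mu_tx, alpha), index=transcripts["transcript_id"].to_numpy(),
        columns=nascent_samples,
    )
    pa = transcripts[transcripts["polyA"]]
    counts["transcript_polyA"] = counts["transcript_total"].loc[pa["transcript_id"]].copy()

    # gene-level counts per tissue
    for tissue in ("A", "B"):
        cols = [f"gene{tissue}_{c}_r{r}" for c in CONDITIONS for r in range(1, n_rep + 1)]
        sf_g = np.exp(rng.normal(0.0, config.libsize_sigma, len(cols)))
        tr = np.array([1 if "treated" in c else 0 for c in cols])
        mu_g = np.where(gene_truth["expressed"], config.nb_mean_gene, 0.05)
        lfc_g = gene_truth[f"true_lfc_{tissue}"].to_numpy()
        mu_mat = mu_g[:, None] * sf_g[None, :] * 2.0 ** (tr[None, :] * lfc_g[:, None])
        counts[f"genes_{tissue}"] = pd.DataFrame(
            _nb_draw(rng, mu_mat, alpha), index=gene_truth["gene_id"].to_numpy(), columns=cols
        )
        sample_rows += [
            {"sample_id": s, "assay": f"genes_{tissue}",
             "condition": "treated" if t else "control", "true_size_factor": f}
            for s, t, f in zip(cols, tr, sf_g)
        ]

    # chromatin-feature counts with LFCs mixed toward the eRNA LFC
    lfc_diff = lfc[np.array(rep_a["reg_class"].isin(["induced", "repressed"]))]
    sigma = float(np.std(lfc_diff)) if len(lfc_diff) else 1.0
    rip_rows = []
    feat_lfc_cols = {}
    for assay in CHROMATIN_ASSAYS:
        rho = config.feature_corr.get(assay, 0.0)
        eps = rng.normal(0.0, sigma if sigma > 0 else 1.0, len(rep_a))
        f_lfc = rho * lfc + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        feat_lfc_cols[assay] = f_lfc
        cols = [f"{assay}_{c}_r{r}" for c in CONDITIONS
                for r in range(1, config.n_replicates_chromatin + 1)]
        tr = np.array([1 if "treated" in c else 0 for c in cols])
        rip = rng.uniform(0.08, 0.30, len(cols))
        sf_c = rip.min() / rip  # reciprocal reads-in-peaks model: scale == size factor
        mu_c = config.nb_mean_feature * sf_c[None, :] * 2.0 ** (tr[None, :] * f_lfc[:, None])
        counts[assay] = pd.DataFrame(
            _nb_draw(rng, mu_c, alpha), index=rep_a["site_id"].to_numpy(), columns=cols
        )
        rip_rows += [
            {"assay": assay, "sample_id": s, "true_rip": r_,
             "condition": "treated" if t else "control", "true_size_factor": f}
            for s, r_, t, f in zip(cols, rip, tr, sf_c)
        ]

    site_truth = sites.copy()
    for assay, f_lfc in feat_lfc_cols.items():
        col = pd.Series(np.nan, index=sites.index)
        col.loc[rep_a.index] = f_lfc
        site_truth[f"true_lfc_{assay}"] = col
    truth = SimTruth(
        sites=site_truth,
        genes=gene_truth,
        transcripts=transcripts,
        samples=pd.DataFrame(sample_rows).set_index("sample_id"),
        rip=pd.DataFrame(rip_rows),
    )
    return counts, truth


def _host_gene(sites: pd.DataFrame, genes: list[GeneModel]) -> list[str]:
    """Gene id whose span contains each site's center ('' when intergenic)."""
    out = []
    for _, rec in sites.iterrows():
        center = (int(rec["start"]) + int(rec["end"])) // 2
        hit = ""
        for g in genes:
            if g.span.chrom == rec["chrom"] and g.span.start <= center < g.span.end:
                hit = g.gene_id
                break
        out.append(hit)
    return out


# ---------------------------------------------------------------------------
# fragment realisation

def realize_fragments(
    config: SimConfig,
    windows: pd.DataFrame,
    counts: pd.DataFrame,
    chrom_sizes: dict[str, int],
    stage: int = 3,
) -> dict[str, pd.DataFrame]:
    """Emit per-sample fragment BED frames whose filtered window counts
    reproduce ``counts`` exactly.

    Each counted fragment passes the MAPQ/length filters and lies wholly
    inside its (non-overlapping) window.  On top, each sample receives a
    fraction of filter-violating fragments (low MAPQ, or out-of-bounds
    length) and of passing background fragments far from every window;
    neither group changes window counts, but background inflates the
    library size as in real data.
    """
    rng = _rng(config, stage)
    win = windows.reset_index(drop=True)
    by_sample: dict[str, pd.DataFrame] = {}
    bg_chrom = list(chrom_sizes)[0]
    bg_limit = chrom_sizes[bg_chrom]
    for sample in counts.columns:
        rows = []
        col = counts[sample].to_numpy()
        for (chrom, ws, we), c in zip(zip(win["chrom"], win["start"], win["end"]), col):
            ws, we = int(ws), int(we)
            span = we - ws
            for _ in range(int(c)):
                length = int(rng.integers(config.frag_len_min,
                                          min(config.frag_len_max, span) + 1))
                start = ws + int(rng.integers(0, span - length + 1))
                rows.append((chrom, start, start + length, 60))
        n_good = len(rows)
        n_bad = int(round(config.frac_bad_fragments * n_good))
        for _ in range(n_bad):
            start = int(rng.integers(0, bg_limit - 2000))
            if rng.random() < 0.5:
                rows.append((bg_chrom, start, start + 200, int(rng.integers(0, 20))))
            else:
                bad_len = int(rng.integers(1100, 1500)) if rng.random() < 0.5 \
                    else int(rng.integers(20, 50))
                rows.append((bg_chrom, start, start + bad_len, 60))
        n_bg = int(round(config.frac_background_fragments * n_good))
        for _ in range(n_bg):
            # stacked far beyond any simulated window
            start = bg_limit - 1500 + int(rng.integers(0, 200))
            rows.append((bg_chrom, start, start + 200, 60))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq"])
        df["name"] = [f"frag{k}" for k in range(len(df))]
        df["strand"] = "."
        by_sample[sample] = df[["chrom", "start", "end", "name", "mapq", "strand"]]
    return by_sample


def realize_rip_fragments(
    config: SimConfig,
    union: pd.DataFrame,
    rip: pd.Series,
    chrom_sizes: dict[str, int],
    stage: int = 4,
) -> dict[str, pd.DataFrame]:
    """Per-sample fragment sets whose in-union fraction equals each RiP ratio."""
    rng = _rng(config, stage)
    union = union.reset_index(drop=True)
    bg_chrom = list(chrom_sizes)[0]
    bg_limit = chrom_sizes[bg_chrom]
    out = {}
    for sample, r in rip.items():
        n_in = int(round(config.n_rip_fragments * float(r)))
        n_out = config.n_rip_fragments - n_in
        rows = []
        which = rng.integers(0, len(union), n_in)
        for k in which:
            ws, we = int(union.loc[k, "start"]), int(union.loc[k, "end"])
            length = min(150, we - ws)
            start = ws + int(rng.integers(0, max(1, we - ws - length + 1)))
            rows.append((union.loc[k, "chrom"], start, start + length, 60))
        for _ in range(n_out):
            start = bg_limit - 1800 + int(rng.integers(0, 300))
            rows.append((bg_chrom, start, start + 100, 60))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq"])
        df["name"] = [f"frag{k}" for k in range(len(df))]
        df["strand"] = "."
        out[sample] = df[["chrom", "start", "end", "name", "mapq", "strand"]]
    return out


# ---------------------------------------------------------------------------
# chromatin mark peak sets

def simulate_mark_peaks(
    config: SimConfig, sites: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Reproducible ATAC/H3K27ac/H3K4me1 peak sets realising the truth classes.

    Active sites carry all three marks, poised sites lack H3K27ac, "other"
    true-eRNA sites carry at most DNA accessibility; non-eRNA sites pick up
    each mark independently at a background rate.  Peaks coincide with the
    site span (+- small jitter), so the 10 bp intersection rule holds by
    construction.
    """
    rng = _rng(config, 5)
    rep_a = sites[sites["reproducible_A"] & sites["tissues"].str.contains("A")]
    out = {}
    for mark in ("ATAC", "H3K4me1", "H3K27ac"):
        rows = []
        for _, rec in rep_a.iterrows():
            cls = rec["chromatin_class"]
            if cls == "active":
                has = True
            elif cls == "poised":
                has = mark != "H3K27ac"
            elif cls == "other":
                has = mark == "ATAC" and rng.random() < 0.5
            else:
                has = rng.random() < config.mark_background_rate
            if has:
                d = int(rng.integers(-config.jitter, config.jitter + 1))
                rows.append({"chrom": rec["chrom"], "start": int(rec["start"]) + d,
                             "end": int(rec["end"]) + d,
                             "name": f"{mark}_{rec['site_id']}", "score": 0.0, "strand": "."})
        out[mark] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                                "score", "strand"])
    return out


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SimulatedExperiment:
    config: SimConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    peaks: dict[tuple[str, int], pd.DataFrame]
    counts: dict[str, pd.DataFrame]
    truth: SimTruth
    mark_peaks: dict[str, pd.DataFrame]


def simulate_experiment(config: SimConfig | None = None) -> SimulatedExperiment:
    """Run every generator stage in order and bundle the results."""
    config = config or SimConfig()
    genes, chrom_sizes = simulate_genome(config)
    peaks, sites = simulate_peaks(config, genes, chrom_sizes)
    rng = _rng(config, 6)
    gene_truth = _gene_truth(config, genes, rng)
    transcripts = _transcript_truth(config, genes, gene_truth, sites, chrom_sizes, rng)
    counts, truth = simulate_counts(config, genes, sites, gene_truth, transcripts)
    mark_peaks = simulate_mark_peaks(config, sites)
    return SimulatedExperiment(config, genes, chrom_sizes, peaks, counts, truth, mark_peaks)


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)
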