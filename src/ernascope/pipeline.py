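"""End-to-end orchestration: one config in, one reproducible run directory out.

Stages run in dependency order — cistrome construction, fragment
quantification, eGBS calling (both routes), differential eRNA expression
with transcriptome-substituted size factors, chromatin-feature dynamics
under reads-in-peaks normalisation, and the two-tissue comparison.  Every
written table gets a JSON sidecar with the stage name, package version,
config hash and input hashes; reruns with the same config are
byte-identical.  Execution is single-process and every stage output is a
plain file, so any stage can also be run standalone through the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromatin import correlate_changes, differential_features, peak_union, rip_factors, stratified_tests
from .diffexp import classify_regulation, median_of_ratios, nb_wald_test
from .egbs import call_gbs_based, call_transcript_based, classify_chromatin, combine_approaches, designate_polyA
from .intervals import annotate_nearest_expressed_gene, remove_blacklisted, reproducible_peaks, windows_around
from .io import read_bed, read_fragments, read_gtf, write_bed, write_counts_tsv, write_fragments, write_gtf, write_sidecar
from .quantify import CountMatrix, count_fragments, expression_gate, tpm
from .synthetic import (
    CHROMATIN_ASSAYS,
    SimConfig,
    realize_fragments,
    realize_rip_fragments,
    simulate_experiment,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of a run, with the analysis defaults pinned.

    Window widths: 588 bp (four nucleosomes) for site-centric eRNA
    detection, 1000 bp for differential counting; overlaps at 1 bp for
    peak/transcript intersections and 10 bp for chromatin-mark
    intersections; the expression gate at the 5th percentile
    (linear-interpolation quantile, strict >); fold-change 1.5 and BH
    alpha 0.05 for regulation calls; fragment filters MAPQ >= 20 and
    length in [50, 1000]; promoters TSS +- 1000 bp; RiP scaling anchored
    at the minimum ratio.
    """

    outdir: str = "run"
    seed: int = 0
    simulate: bool = False
    sim_overrides: dict = field(default_factory=dict)
    # file inputs (non-simulate mode)
    gtf: str | None = None
    rep1: str | None = None
    rep2: str | None = None
    blacklist: str | None = None
    fragments: dict[str, str] = field(default_factory=dict)  # sample -> BED path
    conditions: dict[str, str] = field(default_factory=dict)  # sample -> condition
    # tunables
    window_gbs: int = 588
    window_de: int = 1000
    min_bp_overlap: int = 1
    min_bp_marks: int = 10
    percentile: float = 5.0
    strict_gate: bool = True
    fc_threshold: float = 1.5
    alpha: float = 0.05
    min_count: int = 1
    min_mapq: int = 20
    min_frag: int = 50
    max_frag: int = 1000
    promoter_halfwidth: int = 1000
    tss_distance: int = 1000
    rip_anchor: str = "min"


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.dir = Path(config.outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.hash = _config_hash(config)

    def write_table(self, df: pd.DataFrame, name: str, stage: str, index: bool = True) -> Path:
        path = self.dir / name
        df.to_csv(path, sep="\t", index=index)
        write_sidecar(path, {"stage": stage, "version": __version__,
                             "config_hash": self.hash})
        return path

    def write_json(self, payload: dict, name: str, stage: str) -> Path:
        path = self.dir / name
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        write_sidecar(path, {"stage": stage, "version": __version__,
                             "config_hash": self.hash})
        return path


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    With ``simulate=True`` a full synthetic experiment is generated from
    ``sim_overrides`` (seeded by ``config.seed``) and analysed end to end.
    Otherwise annotation, peak and fragment files must be supplied and the
    cistrome -> quantify -> eGBS -> differential-expression chain runs on
    them; a missing input fails fast, naming the path.
    """
    run = _Run(config)
    with open(run.dir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    if config.simulate:
        return _run_simulated(run)
    return _run_from_files(run)


def _run_simulated(run: _Run) -> Path:
    cfg = run.config
    sim = SimConfig(**{"seed": cfg.seed, **cfg.sim_overrides})
    exp = simulate_experiment(sim)
    genes, chrom_sizes = exp.genes, exp.chrom_sizes
    truth = exp.truth

    write_gtf(genes, run.dir / "genome.gtf")
    for (tissue, rep), df in exp.peaks.items():
        write_bed(df, run.dir / f"peaks_{tissue}_rep{rep}.bed")
    truth.sites.to_csv(run.dir / "truth_sites.tsv", sep="\t", index=False)
    truth.genes.to_csv(run.dir / "truth_genes.tsv", sep="\t", index=False)

    # ---- cistrome (tissue A)
    cistrome = reproducible_peaks(exp.peaks[("A", 1)], exp.peaks[("A", 2)])
    ann = annotate_nearest_expressed_gene(
        cistrome, genes, cfg.tss_distance, cfg.promoter_halfwidth
    )
    ann.index = cistrome["name"].to_numpy()
    intergenic = ann["location_class"] == "intergenic"
    cistrome_out = cistrome.copy()
    cistrome_out["location_class"] = ann["location_class"].to_numpy()
    cistrome_out["nearest_gene"] = ann["nearest_gene"].to_numpy()
    cistrome_out["distance_to_tss"] = ann["distance_to_tss"].to_numpy()
    run.write_table(cistrome_out, "cistrome.tsv", "cistrome", index=False)

    # ---- nascent fragments realised from transcript + background counts
    tx = truth.transcripts
    source = pd.concat(
        [
            tx[["chrom", "start", "end"]].assign(name=tx["transcript_id"]),
            _bg_windows(truth),
        ],
        ignore_index=True,
    )
    source_counts = pd.concat(
        [exp.counts["transcript_total"], exp.counts["background_sites_A"]]
    )
    frag_by_sample = realize_fragments(sim, source, source_counts, chrom_sizes)
    fragdir = run.dir / "fragments"
    fragdir.mkdir(exist_ok=True)
    for sample, df in frag_by_sample.items():
        write_fragments(df, fragdir / f"{sample}.bed")
    conditions = {s: ("treated" if "treated" in s else "control") for s in frag_by_sample}

    result = _analyse_tissue_a(run, cistrome, ann, intergenic, genes, chrom_sizes,
                               frag_by_sample, conditions, exp)
    _analyse_chromatin(run, exp, result["de_erna"], chrom_sizes)
    _analyse_tissues(run, exp, cistrome, ann, genes, result)
    log.info("simulated run complete: %s", run.dir)
    return run.dir


def _bg_windows(truth) -> pd.DataFrame:
    sites = truth.sites
    bg = sites[sites["reproducible_A"] & sites["tissues"].str.contains("A")
               & sites["intergenic"] & ~sites["true_erna_A"]]
    return bg[["chrom", "start", "end"]].assign(name=bg["site_id"]).reset_index(drop=True)


def _analyse_tissue_a(run, cistrome, ann, intergenic, genes, chrom_sizes,
                      frag_by_sample, conditions, exp) -> dict:
    cfg = run.config
    sim = exp.config
    tx = exp.truth.transcripts

    # site-centric route: counts in 588 bp windows
    win_gbs = windows_around(cistrome, cfg.window_gbs, chrom_sizes)
    counts_gbs = count_fragments(
        frag_by_sample, win_gbs, cfg.min_mapq, cfg.min_frag, cfg.max_frag,
        nominal_length=cfg.window_gbs,
    )
    egbs_res = call_gbs_based(counts_gbs, intergenic, cfg.percentile)
    gbs_sites = cistrome.set_index("name").loc[
        egbs_res.calls.index[egbs_res.calls["erna_expressed"]]
    ].reset_index(names="name")

    # transcript route: counts over transcript spans
    tx_windows = tx[["chrom", "start", "end"]].assign(name=tx["transcript_id"])
    counts_tx = count_fragments(frag_by_sample, tx_windows, cfg.min_mapq,
                                cfg.min_frag, cfg.max_frag)
    expr_tx = tpm(counts_tx)
    expression_gate(expr_tx, cfg.percentile, cfg.strict_gate)
    tx_table = tx_windows.copy()
    tx_table["expressed"] = expr_tx.expressed.reindex(tx_table["name"]).to_numpy()
    igbs = cistrome.loc[intergenic.reindex(cistrome["name"]).to_numpy()]
    irnas, ernas, tx_sites = call_transcript_based(
        tx_table, genes, igbs, cfg.tss_distance, cfg.promoter_halfwidth
    )

    venn, downstream = combine_approaches(tx_sites, gbs_sites)
    run.write_json(
        {"transcript_only": venn.a_only, "gbs_only": venn.b_only,
         "shared_transcript": venn.shared_a, "shared_gbs": venn.shared_b,
         "n_irnas": len(irnas), "n_ernas": len(ernas),
         "n_erna_sites_transcript": len(tx_sites), "n_egbs": len(gbs_sites),
         "gate_threshold": egbs_res.threshold},
        "venn.json", "call-egbs",
    )

    # polyA designation from the polyA-enriched library
    pa_tx = tx[tx["polyA"]]
    pa_windows = pa_tx[["chrom", "start", "end"]].assign(name=pa_tx["transcript_id"])
    polya_frags = realize_fragments(
        sim, pa_windows, exp.counts["transcript_polyA"], chrom_sizes, stage=7
    )
    counts_pa = count_fragments(polya_frags, pa_windows, cfg.min_mapq,
                                cfg.min_frag, cfg.max_frag)
    expr_pa = tpm(counts_pa)
    expression_gate(expr_pa, cfg.percentile, cfg.strict_gate)
    pa_detected = pa_windows.loc[expr_pa.expressed.reindex(pa_windows["name"]).to_numpy()]
    tx_polya = designate_polyA(tx_table, pa_detected)
    tx_out = tx_table.copy()
    tx_out["polyA"] = tx_polya
    run.write_table(tx_out, "transcripts.tsv", "call-egbs", index=False)

    # chromatin state of the called eGBS
    marks = exp.mark_peaks
    chrom_class = classify_chromatin(
        gbs_sites, marks["ATAC"], marks["H3K27ac"], marks["H3K4me1"], cfg.min_bp_marks
    )
    egbs_table = gbs_sites.copy()
    egbs_table["chromatin_class"] = chrom_class.to_numpy()
    egbs_table["nearest_gene"] = ann["nearest_gene"].reindex(gbs_sites["name"]).to_numpy()
    run.write_table(egbs_table, "egbs.tsv", "call-egbs", index=False)

    # differential eRNA expression at 1 kb windows, transcriptome factors
    win_de = windows_around(cistrome, cfg.window_de, chrom_sizes)
    counts_de = count_fragments(frag_by_sample, win_de, cfg.min_mapq,
                                cfg.min_frag, cfg.max_frag,
                                nominal_length=cfg.window_de)
    sf_tx = median_of_ratios(counts_tx)
    sf_tx.provenance = "transcriptome_substituted"
    cond = pd.Series(conditions)
    keep = counts_de.counts.index.isin(gbs_sites["name"])
    de = nb_wald_test(counts_de.counts.loc[keep], cond[counts_de.counts.columns],
                      size_factors=sf_tx, levels=("control", "treated"))
    de = classify_regulation(de, cfg.fc_threshold, cfg.alpha, cfg.min_count,
                             max_counts=counts_de.counts.loc[keep].max(axis=1))
    run.write_table(de, "de_erna.tsv", "diff")
    write_sidecar(run.dir / "de_erna.tsv", {
        "stage": "diff", "version": __version__, "config_hash": run.hash,
        "size_factor_provenance": sf_tx.provenance,
        "size_factors": sf_tx.factors.round(6).to_dict(),
        "fc_threshold": cfg.fc_threshold, "alpha": cfg.alpha,
    })
    return {"de_erna": de, "egbs_table": egbs_table, "gbs_sites": gbs_sites,
            "counts_gbs": counts_gbs}


def _analyse_chromatin(run, exp, de_erna: pd.DataFrame, chrom_sizes) -> None:
    cfg = run.config
    sim = exp.config
    sites = exp.truth.sites
    rep_a = sites[sites["reproducible_A"] & sites["tissues"].str.contains("A")]
    site_windows = windows_around(
        rep_a[["chrom", "start", "end"]].assign(name=rep_a["site_id"]),
        cfg.window_de, chrom_sizes,
    )

    groups = de_erna["reg_class"].dropna()
    assay_counts, assay_factors, assay_cond = {}, {}, {}
    rip_rows = []
    for k, assay in enumerate(CHROMATIN_ASSAYS):
        counts = exp.counts[assay]
        union = site_windows[["chrom", "start", "end"]]
        truth_rip = exp.truth.rip.query("assay == @assay").set_index("sample_id")["true_rip"]
        frags = realize_rip_fragments(sim, union, truth_rip, chrom_sizes, stage=100 + k)
        rf = rip_factors(frags, union, peak_union_id=assay)
        assay_counts[assay] = counts
        assay_factors[assay] = rf.as_size_factors()
        assay_cond[assay] = ["treated" if "treated" in c else "control" for c in counts.columns]
        for s in counts.columns:
            rip_rows.append({"assay": assay, "sample_id": s, "rip": rf.rip[s],
                             "scaled_rip": rf.scaled_rip[s], "size_factor": rf.size_factor[s]})
    run.write_table(pd.DataFrame(rip_rows), "rip_factors.tsv", "chromatin", index=False)

    table = differential_features(assay_counts, assay_factors, assay_cond, groups)
    table["eRNA_log2fc"] = de_erna["log2fc"].reindex(table.index)
    run.write_table(table, "feature_changes.tsv", "chromatin")

    diff = table[table["erna_group"].isin(["induced", "repressed"])]
    corr = correlate_changes(diff, ["eRNA_log2fc"] + [f"{a}_log2fc" for a in CHROMATIN_ASSAYS])
    run.write_table(corr, "chromatin_correlation.tsv", "chromatin")
    strat = stratified_tests(table)
    run.write_table(strat, "stratified_tests.tsv", "chromatin", index=False)


def _analyse_tissues(run, exp, cistrome_a, ann_a, genes, result) -> None:
    from .tissue import compare_sites, compare_target_genes, de_specificity

    cfg = run.config
    # tissue B cistrome and eGBS from its own replicates/counts
    cistrome_b = reproducible_peaks(exp.peaks[("B", 1)], exp.peaks[("B", 2)])
    ann_b = annotate_nearest_expressed_gene(
        cistrome_b, genes, cfg.tss_distance, cfg.promoter_halfwidth
    )
    ann_b.index = cistrome_b["name"].to_numpy()
    counts_b = exp.counts["nascent_gbs_B"]
    cm_b = CountMatrix(
        counts_b, counts_b.sum(axis=0) * 20.0,
        pd.Series(cfg.window_gbs, index=counts_b.index), pd.DataFrame()
    )
    egbs_b = call_gbs_based(cm_b, ann_b["location_class"] == "intergenic", cfg.percentile)
    sites_b = cistrome_b.set_index("name").loc[
        egbs_b.calls.index[egbs_b.calls["erna_expressed"]]
    ].reset_index(names="name")

    sites_a = result["gbs_sites"]
    site_rep = compare_sites(sites_a, sites_b)
    ann_a_sub = ann_a.loc[[n for n in sites_a["name"]]]
    ann_b_sub = ann_b.loc[[n for n in sites_b["name"]]]
    gene_rep = compare_target_genes(ann_a_sub, ann_b_sub)

    de_a = classify_regulation(
        nb_wald_test(exp.counts["genes_A"],
                     ["treated" if "treated" in c else "control"
                      for c in exp.counts["genes_A"].columns],
                     levels=("control", "treated")),
        cfg.fc_threshold, cfg.alpha)
    de_b = classify_regulation(
        nb_wald_test(exp.counts["genes_B"],
                     ["treated" if "treated" in c else "control"
                      for c in exp.counts["genes_B"].columns],
                     levels=("control", "treated")),
        cfg.fc_threshold, cfg.alpha)
    run.write_table(de_a, "de_genes_A.tsv", "compare")
    run.write_table(de_b, "de_genes_B.tsv", "compare")
    spec_a, spec_b = de_specificity(de_a, de_b)

    run.write_json(
        {
            "sites": dataclasses.asdict(site_rep) | {"shared_ids": list(site_rep.shared_ids)},
            "genes": dataclasses.asdict(gene_rep),
            "de_specificity_pct": {"A": spec_a, "B": spec_b},
        },
        "tissue_comparison.json", "compare",
    )


def _run_from_files(run: _Run) -> Path:
    cfg = run.config
    required = {"gtf": cfg.gtf, "rep1": cfg.rep1, "rep2": cfg.rep2}
    for name, path in required.items():
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input '{name}' missing: {path}")
    if not cfg.fragments:
        raise FileNotFoundError("required input 'fragments' missing: no sample BEDs given")
    for sample, path in cfg.fragments.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"fragment BED for sample '{sample}' missing: {path}")

    genes = read_gtf(cfg.gtf, cfg.promoter_halfwidth)
    rep1, rep2 = read_bed(cfg.rep1), read_bed(cfg.rep2)
    cistrome = reproducible_peaks(rep1, rep2)
    if cfg.blacklist:
        cistrome = remove_blacklisted(cistrome, read_bed(cfg.blacklist))
    if cistrome["name"].nunique() != len(cistrome):
        cistrome = cistrome.assign(name=[f"peak{i:05d}" for i in range(len(cistrome))])
    ann = annotate_nearest_expressed_gene(cistrome, genes, cfg.tss_distance,
                                          cfg.promoter_halfwidth)
    ann.index = cistrome["name"].to_numpy()
    out = cistrome.copy()
    out["location_class"] = ann["location_class"].to_numpy()
    out["nearest_gene"] = ann["nearest_gene"].to_numpy()
    run.write_table(out, "cistrome.tsv", "cistrome", index=False)

    frag_by_sample = {s: read_fragments(p) for s, p in cfg.fragments.items()}
    win_gbs = windows_around(cistrome, cfg.window_gbs)
    counts_gbs = count_fragments(frag_by_sample, win_gbs, cfg.min_mapq,
                                 cfg.min_frag, cfg.max_frag,
                                 nominal_length=cfg.window_gbs)
    write_counts_tsv(counts_gbs.counts, run.dir / "counts_gbs.tsv")
    egbs_res = call_gbs_based(counts_gbs, ann["location_class"] == "intergenic",
                              cfg.percentile)
    run.write_table(egbs_res.calls, "egbs.tsv", "call-egbs")

    if cfg.conditions:
        win_de = windows_around(cistrome, cfg.window_de)
        counts_de = count_fragments(frag_by_sample, win_de, cfg.min_mapq,
                                    cfg.min_frag, cfg.max_frag,
                                    nominal_length=cfg.window_de)
        cond = pd.Series({s: cfg.conditions[s] for s in counts_de.counts.columns})
        de = nb_wald_test(counts_de.counts, cond, levels=tuple(sorted(set(cond))))
        de = classify_regulation(de, cfg.fc_threshold, cfg.alpha, cfg.min_count,
                                 max_counts=counts_de.counts.max(axis=1))
        run.write_table(de, "de_erna.tsv", "diff")
    return run.dir
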