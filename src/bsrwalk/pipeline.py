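"""End-to-end orchestration: simulate -> linkage scan -> Seq-walking -> report.

:func:`run_all` executes the whole forward-genetics workflow on a seeded
synthetic scenario: it generates the reference, map and F2 population,
computes per-SNP linkage posteriors from the bulk counts, calls the
mapping interval from the sliding-window scan, simulates and analyses the
two Seq-walking libraries, and nominates the candidate gene — the
annotated gene hit by the highest-count mutant-private insertion site
inside the interval.  Because the generator records its ground truth, the
report carries a recovery flag stating whether the nominated gene is the
gene that actually contains the planted causal insertion.

Per-stage seeds are derived from the single master seed with
``numpy.random.SeedSequence(master_seed)``, one 32-bit word per named
stage, so any stage can be re-run in isolation and reproduced exactly.
Each stage emits one structured log line with its input/output counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsa, scan as scan_mod, seqwalk as sw, synthetic as syn

log = logging.getLogger("bsrwalk")

_STAGES = [
    "reference", "map", "insertions", "population",
    "bulking", "counts", "mutant_lib", "control_lib",
]


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds: one SeedSequence word per stage."""
    words = np.random.SeedSequence(master_seed).generate_state(len(_STAGES))
    return {name: int(w) % 2**31 for name, w in zip(_STAGES, words)}


@dataclass
class ScanParams:
    window_size: int = 100
    step: int = 20
    tau: float | None = None


@dataclass
class SeqwalkParams:
    min_len: int = 90
    max_mismatch: int = 2
    bin_width: int = 100
    tolerance: int = 1
    seed_len: int = 31


@dataclass
class RunConfig:
    """Everything one pipeline run needs, round-trippable through YAML."""

    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    bsa: bsa.LinkageModelParams = field(default_factory=bsa.LinkageModelParams)
    scan: ScanParams = field(default_factory=ScanParams)
    seqwalk: SeqwalkParams = field(default_factory=SeqwalkParams)
    master_seed: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["centromere"] = list(d["sim"]["centromere"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = dict(d.get("sim", {}))
        if "centromere" in sim and sim["centromere"] is not None:
            sim["centromere"] = tuple(sim["centromere"])
        return cls(
            sim=syn.SimConfig(**sim),
            bsa=bsa.LinkageModelParams(**d.get("bsa", {})),
            scan=ScanParams(**d.get("scan", {})),
            seqwalk=SeqwalkParams(**d.get("seqwalk", {})),
            master_seed=int(d.get("master_seed", 1)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunReport:
    """Outcome of one pipeline run (recovery fields only when truth known)."""

    master_seed: int
    seeds: dict
    interval: dict | None  # MappingInterval fields, or None when no signal
    no_signal_reason: str | None
    candidate: dict | None  # rank-1 site row
    candidate_gene: str | None
    n_candidate_sites: int
    accounting: dict
    truth: dict | None = None
    recovered: bool | None = None
    interval_contains_causal: bool | None = None

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (np.bool_,)):
                return bool(o)
            raise TypeError(f"not JSON serialisable: {o!r}")

        text = json.dumps(dataclasses.asdict(self), indent=2, default=default)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def accounting(report: RunReport) -> None:
    """Re-check every integer read-conservation identity of a run.

    Raises :class:`bsrwalk.seqwalk.AccountingError` naming the violated
    stage; returns silently when all identities hold (an empty run — all
    zeros — passes).
    """
    acc = sw.RunAccounting(
        n_input=report.accounting["n_input"],
        n_unassigned=report.accounting["n_unassigned"],
        libraries={
            k: sw.LibraryAccounting(**v)
            for k, v in report.accounting["libraries"].items()
        },
    )
    acc.check()


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


def _pick_causal_gene(reference: syn.ReferenceGenome, cfg: syn.SimConfig) -> syn.Gene:
    """The gene nearest the centromere midpoint: the planted causal locus
    sits in the low-recombination region, as in the motivating study."""
    chrom = reference.chrom_names[0]
    target = (cfg.centromere[0] + cfg.centromere[1]) / 2 if cfg.centromere else reference.length(chrom) / 2
    genes = [g for g in reference.genes if g.chrom == chrom]
    if not genes:
        raise ValueError("reference has no genes on the mapping chromosome")
    return min(genes, key=lambda g: abs((g.start + g.end) / 2 - target))


def _plan_insertions(
    reference: syn.ReferenceGenome, cfg: syn.SimConfig, causal_gene: syn.Gene, seed: int
) -> tuple[pd.DataFrame, int]:
    """Plant the causal, shared and control-private insertions.

    Sites are kept at least ``min_insertion_spacing`` bp apart so each
    planted insertion is unambiguous at bin resolution.  Returns the truth
    table (chrom, pos, libraries, weight) and the causal position.
    """
    rng = np.random.default_rng(seed)
    chrom = reference.chrom_names[0]
    chrom_len = reference.length(chrom)
    causal_pos = int(rng.integers(causal_gene.start, causal_gene.end + 1))
    taken = [causal_pos]

    def draw(n: int) -> list[int]:
        out = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 10_000 * n:
                raise ValueError("cannot place insertions with the requested spacing")
            p = int(rng.integers(1, chrom_len + 1))
            if all(abs(p - q) >= cfg.min_insertion_spacing for q in taken):
                taken.append(p)
                out.append(p)
        return out

    shared = draw(cfg.n_shared_insertions)
    control_only = draw(cfg.n_control_private)
    rows = [(chrom, causal_pos, "mutant", cfg.causal_read_weight)]
    rows += [(chrom, p, "both", 1.0) for p in shared]
    rows += [(chrom, p, "control", 1.0) for p in control_only]
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "libraries", "weight"])
    return truth, causal_pos


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline on a synthetic scenario.

    When ``outdir`` is given, every intermediate artifact is written there
    in its standard format (FASTA/GFF3/TSV/FASTQ/BED/JSON); with
    ``outdir=None`` the run stays in memory.  Any stage failure aborts
    with the stage name attached.
    """
    cfg = config.sim
    seeds = stage_seeds(config.master_seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "simulate-reference"
    try:
        reference = syn.make_reference([cfg.chrom_length], cfg.n_genes, seeds["reference"])
        gmap = syn.make_genetic_map(
            reference, cfg.n_markers, cfg.centromere, cfg.suppression_factor,
            cfg.cm_per_mb, seeds["map"],
        )
        chrom = reference.chrom_names[0]
        log.info("stage=reference chroms=%d genes=%d markers=%d",
                 len(reference.chrom_names), len(reference.genes), len(gmap))

        stage = "plan-insertions"
        causal_gene = _pick_causal_gene(reference, cfg)
        truth_table, causal_pos = _plan_insertions(reference, cfg, causal_gene, seeds["insertions"])
        marker_bp, _ = gmap.chrom_markers(chrom)
        causal_marker = int(marker_bp[np.argmin(np.abs(marker_bp - causal_pos))])
        truth = syn.SimTruth(chrom, causal_pos, causal_gene.id, causal_marker,
                             truth_table, seeds)
        log.info("stage=insertions planted=%d causal=%s:%d gene=%s",
                 len(truth_table), chrom, causal_pos, causal_gene.id)

        stage = "simulate-population"
        population = syn.simulate_f2_population(
            gmap, (chrom, causal_marker), cfg.n_f2, seeds["population"]
        )
        bulks = syn.phenotype_and_bulk(population, cfg.n_mutant, cfg.n_wt, seeds["bulking"])
        counts = syn.simulate_bulk_allele_counts(
            bulks, gmap, cfg.mean_depth, cfg.seq_error, seeds["counts"]
        )
        log.info("stage=population n_f2=%d bulks=%d+%d snps=%d",
                 cfg.n_f2, bulks[0].n_individuals, bulks[1].n_individuals, len(counts))

        stage = "bsa"
        posteriors = bsa.compute_posteriors(counts, config.bsa)

        stage = "scan"
        chrom_post = posteriors[posteriors["chrom"] == chrom].reset_index(drop=True)
        scan_df = scan_mod.sliding_window_scan(
            chrom_post, config.scan.window_size, config.scan.step
        )
        interval = scan_mod.call_interval(scan_df, gmap, chrom, config.scan.tau)
        has_interval = isinstance(interval, scan_mod.MappingInterval)
        log.info("stage=scan windows=%d interval=%s", len(scan_df),
                 f"{interval.start_bp}-{interval.end_bp}" if has_interval else "none")

        stage = "simulate-seqwalk"
        def lib_insertions(label):
            sel = truth_table[truth_table["libraries"].isin([label, "both"])]
            return [syn.Insertion(r.chrom, r.pos, r.weight) for r in sel.itertuples(index=False)]

        reads_m, _ = syn.simulate_seqwalk_library(
            reference, lib_insertions("mutant"), cfg.n_reads, cfg.barcodes["mutant"],
            cfg.tir_tag, cfg.read_len_params, cfg.seq_error, seeds["mutant_lib"], "mutant",
        )
        reads_c, _ = syn.simulate_seqwalk_library(
            reference, lib_insertions("control"), cfg.n_reads, cfg.barcodes["control"],
            cfg.tir_tag, cfg.read_len_params, cfg.seq_error, seeds["control_lib"], "control",
        )
        pooled = reads_m + reads_c
        log.info("stage=seqwalk-sim reads=%d+%d", len(reads_m), len(reads_c))

        stage = "seqwalk"
        swp = config.seqwalk
        result = sw.run_seqwalk(
            pooled, cfg.barcodes, cfg.tir_tag, reference,
            min_len=swp.min_len, max_mismatch=swp.max_mismatch,
            bin_width=swp.bin_width, tolerance=swp.tolerance, seed_len=swp.seed_len,
            interval=interval if has_interval else None, genes=reference.genes,
        )
        log.info("stage=seqwalk sites_mutant=%d sites_control=%d private=%d",
                 len(result.sample_sites), len(result.control_sites),
                 len(result.candidate_sites))

        stage = "report"
        candidate = gene_id = None
        if isinstance(result.report, sw.CandidateReport):
            candidate = {k: (v if not isinstance(v, np.generic) else v.item())
                         for k, v in result.report.candidate.items()}
            gene_id = candidate.get("gene_id")
        recovered = None
        contains = None
        if has_interval:
            contains = bool(interval.start_bp <= causal_pos <= interval.end_bp)
        if result.report is not None:
            recovered = bool(gene_id is not None and gene_id == causal_gene.id)
        report = RunReport(
            master_seed=config.master_seed,
            seeds=seeds,
            interval=dataclasses.asdict(interval) if has_interval else None,
            no_signal_reason=None if has_interval else interval.reason,
            candidate=candidate,
            candidate_gene=gene_id,
            n_candidate_sites=len(result.candidate_sites),
            accounting=result.accounting.to_dict(),
            truth=truth.to_dict(),
            recovered=recovered,
            interval_contains_causal=contains,
        )
        accounting(report)

        if out is not None:
            stage = "write-artifacts"
            reference.to_fasta(out / "reference.fasta")
            reference.to_gff3(out / "genes.gff3")
            gmap.to_tsv(out / "genetic_map.tsv")
            bsa.write_bulk_counts_tsv(counts, out / "bulk_counts.tsv")
            bsa.write_posteriors_tsv(posteriors, out / "posteriors.tsv")
            scan_mod.write_scan_tsv(scan_df, out / "scan.tsv")
            if has_interval:
                interval.to_bed(out / "interval.bed")
                interval.to_json(out / "interval.json")
            sw.write_fastq(reads_m, out / "mutant.fastq")
            sw.write_fastq(reads_c, out / "control.fastq")
            result.sample_sites.to_tsv(out / "sites_mutant.tsv")
            result.control_sites.to_tsv(out / "sites_control.tsv")
            result.candidate_sites.to_tsv(out / "sites_private.tsv")
            result.candidate_sites.to_bed(out / "sites_private.bed")
            if isinstance(result.report, sw.CandidateReport):
                result.report.to_tsv(out / "candidate_report.tsv")
            (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
            report.to_json(out / "report.json")
            config.to_yaml(out / "config.yaml")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Seeded experiments
# ---------------------------------------------------------------------------


def recovery_experiment(
    n_runs: int = 20, base_seed: int = 1, config: RunConfig | None = None
) -> pd.DataFrame:
    """Run the full pipeline for ``n_runs`` derived master seeds.

    Per run the row records whether an interval was called, whether it
    contains the true causal position, its cM width, whether the rank-1
    candidate site/gene match the planted causal insertion, and whether
    every read-conservation identity held.
    """
    config = config or RunConfig()
    masters = np.random.SeedSequence(base_seed).generate_state(n_runs) % 2**31
    rows = []
    for master in masters:
        report = run_all(replace(config, master_seed=int(master)))
        interval_called = report.interval is not None
        bin_width = config.seqwalk.bin_width
        causal_bin = (report.truth["causal_pos"] - 1) // bin_width * bin_width + 1
        rank1_site = (
            report.candidate is not None
            and report.candidate["chrom"] == report.truth["causal_chrom"]
            and report.candidate["bin_start"] == causal_bin
        )
        rows.append(
            {
                "master_seed": int(master),
                "interval_called": interval_called,
                "contains_causal": bool(report.interval_contains_causal)
                if interval_called else False,
                "width_cm": report.interval["width_cm"] if interval_called else np.nan,
                "rank1_site_correct": bool(rank1_site),
                "gene_recovered": bool(report.recovered),
                "conservation_ok": True,  # run_all raises otherwise
            }
        )
    return pd.DataFrame(rows)


def allele_freq_experiment(
    n_reps: int = 40,
    depth: float = 50.0,
    n_mutant: int = 123,
    n_wt: int = 123,
    r_values=(0.0, 0.1, 0.5),
    seed: int = 0,
    n_f2: int = 800,
) -> pd.DataFrame:
    """Monte-Carlo check of the bulk allele-frequency laws at zero error.

    For each requested recombination fraction a marker is placed at the
    Haldane-inverse cM distance from the causal locus (r = 0.5 markers go
    on a second, unlinked chromosome); ``n_reps`` independent populations
    of bulks are simulated at sequencing error 0 and the observed P1
    frequency in each bulk is compared with f_m(r) = 1 - r and
    f_w(r) = 1/3 + r/3.  Returns one row per (r, bulk) with the mean
    observed frequency, its standard error over replicates, and the
    expectation.
    """
    linked = [r for r in r_values if r < 0.5]
    unlinked = [r for r in r_values if r >= 0.5]
    rows = []
    cm = [0.0] + [float(syn.haldane_cm(r)) for r in linked if r > 0]
    bp = [1_000 * (i + 1) for i in range(len(cm))]
    frames = [pd.DataFrame({"chrom": "chr1", "pos_bp": bp, "pos_cm": cm})]
    if unlinked:
        frames.append(pd.DataFrame({"chrom": "chr2", "pos_bp": [1_000], "pos_cm": [0.0]}))
    gmap = syn.GeneticMap(pd.concat(frames, ignore_index=True))
    marker_for_r = {}
    for r in r_values:
        if r >= 0.5:
            marker_for_r[r] = gmap.marker_index("chr2", 1_000)
        elif r == 0:
            marker_for_r[r] = gmap.marker_index("chr1", 1_000)
        else:
            marker_for_r[r] = gmap.marker_index("chr1", bp[cm.index(float(syn.haldane_cm(r)))])

    rep_seeds = np.random.SeedSequence(seed).generate_state(3 * n_reps) % 2**31
    freqs = {(r, b): [] for r in r_values for b in (bsa.MUTANT, bsa.WILDTYPE)}
    for i in range(n_reps):
        pop = syn.simulate_f2_population(gmap, ("chr1", 1_000), n_f2, int(rep_seeds[3 * i]))
        bulks = syn.phenotype_and_bulk(pop, n_mutant, n_wt, int(rep_seeds[3 * i + 1]))
        counts = syn.simulate_bulk_allele_counts(
            bulks, gmap, depth, 0.0, int(rep_seeds[3 * i + 2])
        )
        for r, idx in marker_for_r.items():
            row = counts.iloc[idx]
            if row["mut_ref"] + row["mut_alt"] > 0:
                freqs[(r, bsa.MUTANT)].append(row["mut_ref"] / (row["mut_ref"] + row["mut_alt"]))
            if row["wt_ref"] + row["wt_alt"] > 0:
                freqs[(r, bsa.WILDTYPE)].append(row["wt_ref"] / (row["wt_ref"] + row["wt_alt"]))
    for r in r_values:
        for kind in (bsa.MUTANT, bsa.WILDTYPE):
            vals = np.asarray(freqs[(r, kind)], dtype=float)
            rows.append(
                {
                    "r": r,
                    "bulk": kind,
                    "mean_freq": vals.mean(),
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)),
                    "expected": bsa.expected_allele_freq(min(r, 0.5), kind),
                    "n_reps": len(vals),
                }
            )
    return pd.DataFrame(rows)
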