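"""Synthetic BSR-Seq / Seq-walking scenarios with known ground truth.

This module produces every input the mapping pipeline consumes:

* a reference genome with non-overlapping gene models (FASTA + GFF3),
* a monotone genetic map, optionally with suppressed recombination across
  a centromeric span (TSV of physical vs genetic marker positions),
* an F2 population from a cross of two inbreds segregating one recessive
  locus, with gametes drawn under Haldane's no-interference model,
* phenotype bulks and pooled RNA-seq allele counts at biallelic SNPs, and
* barcoded transposon flanking-sequence reads (FASTQ) with insertions
  planted at known positions.

Conventions
-----------
Coordinates are 1-based and inclusive on the forward strand.  ``P1`` is
the mutant-donor parent (its chromosomes carry the recessive allele *m*
and, by convention, the reference allele at every SNP); ``P2`` is the
mapping parent.  In origin arrays, 0 codes a P1 chromosome segment and 1 a
P2 segment.  An insertion position is the first genomic base of its
recovered flank.

All operations are deterministic given their seed: the same seed yields
byte-identical FASTA/GFF/FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqwalk import RawRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"

#: Default library barcodes: itp-Mu8 for the mutant-derived library,
#: itp-Mu31 for the control (wild-type inbred) library.
DEFAULT_BARCODES = {"mutant": "GTCGAT", "control": "CTGCTA"}

#: Synthetic stand-in for the conserved Mu terminal-inverted-repeat tag that
#: remains on a Seq-walking read after adapter removal (25 nt).
DEFAULT_TIR_TAG = "AGAGAAGCCAACGCCATCGCCTCTA"


# ---------------------------------------------------------------------------
# Map-function helpers
# ---------------------------------------------------------------------------


def haldane_r(d_cm):
    """Recombination fraction for a genetic distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_cm(r):
    """Inverse Haldane map function: distance in cM for r < 0.5."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log1p(-2.0 * r)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str


@dataclass
class ReferenceGenome:
    chrom_names: list[str]
    sequences: list[str]
    genes: list[Gene]

    def __post_init__(self):
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        lengths = dict(zip(self.chrom_names, map(len, self.sequences)))
        for g in self.genes:
            if not (1 <= g.start <= g.end <= lengths[g.chrom]):
                raise ValueError(f"gene {g.id} outside chromosome bounds")

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def sequence(self, chrom: str) -> str:
        return self.sequences[self.chrom_names.index(chrom)]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence, 1-based inclusive, clipped at the chromosome end."""
        seq = self.sequence(chrom)
        return seq[start - 1 : min(end, len(seq))]

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in zip(self.chrom_names, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in zip(self.chrom_names, self.sequences):
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\tbsrwalk\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
                )

    @classmethod
    def from_files(cls, fasta_path, gff3_path=None) -> "ReferenceGenome":
        names, seqs = [], []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        genes: list[Gene] = []
        if gff3_path is not None:
            with open(gff3_path) as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) < 9 or parts[2] != "gene":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    genes.append(
                        Gene(attrs.get("ID", f"gene{len(genes)+1:04d}"),
                             parts[0], int(parts[3]), int(parts[4]), parts[6])
                    )
        return cls(names, seqs, genes)


def make_reference(
    chrom_lengths,
    n_genes: int,
    seed: int,
    min_gene_len: int = 500,
    max_gene_len: int = 3000,
    chrom_names=None,
) -> ReferenceGenome:
    """Random reference with uniformly scattered, non-overlapping genes.

    Gene counts are split across chromosomes in proportion to length; gene
    lengths are uniform on ``[min_gene_len, max_gene_len]`` and the free
    space between genes is partitioned uniformly at random, which scatters
    genes without overlap.  Chromosomes of at least 10 kb are recommended
    so that default-length genes pack loosely.  An infeasible packing (the
    genes do not fit on a chromosome) raises ``ValueError``.
    """
    lengths = [int(x) for x in chrom_lengths]
    if not lengths or any(x <= 0 for x in lengths):
        raise ValueError("chromosome lengths must be positive")
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if not (0 < min_gene_len <= max_gene_len):
        raise ValueError("need 0 < min_gene_len <= max_gene_len")
    rng = np.random.default_rng(seed)
    names = list(chrom_names) if chrom_names else [f"chr{i+1}" for i in range(len(lengths))]
    p = np.asarray(lengths, dtype=float)
    counts = rng.multinomial(n_genes, p / p.sum())

    sequences, genes = [], []
    gid = 1
    for name, chrom_len, g in zip(names, lengths, counts):
        gene_lens = rng.integers(min_gene_len, max_gene_len + 1, size=g)
        free = chrom_len - int(gene_lens.sum())
        if free < 0:
            raise ValueError(
                f"cannot place {g} genes totalling {int(gene_lens.sum())} bp on "
                f"{name} ({chrom_len} bp) without overlap"
            )
        gaps = rng.multinomial(free, np.full(g + 1, 1.0 / (g + 1))) if g else []
        strands = rng.integers(0, 2, size=g)
        cursor = 0
        for j in range(g):
            cursor += int(gaps[j])
            start = cursor + 1
            end = cursor + int(gene_lens[j])
            genes.append(Gene(f"gene{gid:04d}", name, start, end, "+-"[strands[j]]))
            gid += 1
            cursor = end
        seq = _BASES[rng.integers(0, 4, size=chrom_len)].tobytes().decode("ascii")
        sequences.append(seq)
    return ReferenceGenome(names, sequences, genes)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Markers with physical (bp) and genetic (cM) positions.

    ``df`` columns: ``chrom``, ``pos_bp``, ``pos_cm``.  Within each
    chromosome physical positions are strictly increasing and genetic
    positions non-decreasing (a monotone map).
    """

    df: pd.DataFrame

    def __post_init__(self):
        for chrom, grp in self.df.groupby("chrom", sort=False):
            bp = grp["pos_bp"].to_numpy()
            cm = grp["pos_cm"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"{chrom}: physical positions must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: genetic positions must be non-decreasing")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def markers(self) -> list[tuple[str, int, float]]:
        return list(self.df.itertuples(index=False, name=None))

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_markers(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        grp = self.df[self.df["chrom"] == chrom]
        return grp["pos_bp"].to_numpy(), grp["pos_cm"].to_numpy()

    def interpolate_cm(self, chrom: str, pos_bp) -> np.ndarray:
        """cM at arbitrary bp: linear between markers, constant beyond ends."""
        bp, cm = self.chrom_markers(chrom)
        if len(bp) == 0:
            raise ValueError(f"no markers on {chrom}")
        return np.interp(np.asarray(pos_bp, dtype=float), bp, cm)

    def marker_index(self, chrom: str, pos_bp: int) -> int:
        hit = self.df.index[(self.df["chrom"] == chrom) & (self.df["pos_bp"] == pos_bp)]
        if len(hit) != 1:
            raise ValueError(f"no unique marker at {chrom}:{pos_bp}")
        return int(hit[0])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))


def make_genetic_map(
    reference: ReferenceGenome,
    n_markers: int,
    centromere_span=None,
    suppression_factor: float = 1.0,
    cm_per_mb: float = 5.0,
    seed: int = 0,
) -> GeneticMap:
    """Random marker map with an optionally suppressed centromeric span.

    Outside the span the map accumulates ``cm_per_mb`` centimorgans per
    megabase; inside it the local rate is ``suppression_factor`` times
    that, emulating the low per-Mb recombination of centromeric regions.
    ``centromere_span`` is ``(start, end)`` (applied to the first
    chromosome) or a ``{chrom: (start, end)}`` mapping.

    suppression_factor must lie in (0, 1]; a value outside that range
    would request a non-monotone map and raises ``ValueError``.
    """
    if not (0.0 < suppression_factor <= 1.0):
        raise ValueError("suppression_factor must be in (0, 1] (monotone map)")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    spans: dict[str, tuple[int, int]] = {}
    if centromere_span is not None:
        if isinstance(centromere_span, dict):
            spans = {k: (int(v[0]), int(v[1])) for k, v in centromere_span.items()}
        else:
            spans = {reference.chrom_names[0]: (int(centromere_span[0]), int(centromere_span[1]))}
        for chrom, (s, e) in spans.items():
            if not (1 <= s < e <= reference.length(chrom)):
                raise ValueError(f"centromere span {s}-{e} outside {chrom}")

    rng = np.random.default_rng(seed)
    lengths = np.array([len(s) for s in reference.sequences], dtype=float)
    counts = rng.multinomial(n_markers, lengths / lengths.sum())
    frames = []
    for name, chrom_len, m in zip(reference.chrom_names, lengths.astype(int), counts):
        if m == 0:
            continue
        pos = np.sort(rng.choice(chrom_len, size=m, replace=False)) + 1
        if name in spans:
            s, e = spans[name]
            inside = np.clip(np.minimum(pos, e) - (s - 1), 0, e - s + 1)
        else:
            inside = np.zeros(m)
        outside = pos - inside
        cm = (outside + suppression_factor * inside) * cm_per_mb / 1e6
        frames.append(pd.DataFrame({"chrom": name, "pos_bp": pos, "pos_cm": cm}))
    df = pd.concat(frames, ignore_index=True)
    return GeneticMap(df)


# ---------------------------------------------------------------------------
# F2 population, bulking, allele counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class F2Individual:
    """One F2 plant: two gametes (per-marker parental origin) plus its
    genotype at the causal locus."""

    gametes: tuple[np.ndarray, np.ndarray]  # int8 arrays, 0 = P1, 1 = P2
    causal_genotype: str  # 'mm', 'm+' or '++'


@dataclass
class F2Population:
    """A vectorised F2 population.

    ``origins`` has shape ``(n, 2, M)`` over individuals x gametes x
    markers, holding parental origin (0 = P1 mutant donor, 1 = P2).
    """

    origins: np.ndarray
    causal_index: int
    gmap: GeneticMap

    def __len__(self) -> int:
        return self.origins.shape[0]

    def n_p1_at_causal(self) -> np.ndarray:
        """Number of P1 (mutant) alleles per individual at the causal locus."""
        return (self.origins[:, :, self.causal_index] == 0).sum(axis=1)

    def causal_genotypes(self) -> np.ndarray:
        return np.array(["++", "m+", "mm"])[self.n_p1_at_causal()]

    def is_mutant(self) -> np.ndarray:
        """Recessive phenotype: mutant iff homozygous mm."""
        return self.n_p1_at_causal() == 2

    def __getitem__(self, i: int) -> F2Individual:
        return F2Individual(
            (self.origins[i, 0].copy(), self.origins[i, 1].copy()),
            str(self.causal_genotypes()[i]),
        )


def simulate_f2_population(gmap: GeneticMap, causal_locus, n: int, seed: int = 0) -> F2Population:
    """Simulate ``n`` F2 individuals by Haldane's crossover model.

    Each gamete is an independent Markov chain along each chromosome: the
    origin of the first marker is Bernoulli(1/2) and switches between
    adjacent markers with probability given by the Haldane map function of
    their cM distance (crossovers as a Poisson process on the genetic
    scale, no interference).  ``causal_locus`` is ``(chrom, pos_bp)`` and
    must coincide with a map marker.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    causal_index = gmap.marker_index(*causal_locus)
    rng = np.random.default_rng(seed)
    total = len(gmap)
    gametes = np.empty((2 * n, total), dtype=np.int8)
    col = 0
    for chrom in gmap.chroms:
        _, cm = gmap.chrom_markers(chrom)
        m = len(cm)
        first = rng.integers(0, 2, size=2 * n).astype(np.int8)
        if m > 1:
            r = haldane_r(np.diff(cm))
            switches = (rng.random((2 * n, m - 1)) < r).astype(np.int8)
            cum = np.concatenate(
                [np.zeros((2 * n, 1), dtype=np.int8), np.cumsum(switches, axis=1) % 2], axis=1
            )
        else:
            cum = np.zeros((2 * n, 1), dtype=np.int8)
        gametes[:, col : col + m] = (first[:, None] + cum) % 2
        col += m
    origins = gametes.reshape(n, 2, total)
    return F2Population(origins, causal_index, gmap)


@dataclass
class Bulk:
    """A phenotype pool: the 2N chromosomes of its member individuals."""

    kind: str  # 'mutant' or 'wildtype'
    member_indices: np.ndarray
    chromosomes: np.ndarray  # (2N, M) parental origins

    @property
    def n_individuals(self) -> int:
        return len(self.member_indices)


def phenotype_and_bulk(
    population: F2Population, n_mutant: int = 123, n_wt: int = 123, seed: int = 0
) -> tuple[Bulk, Bulk]:
    """Select phenotype bulks from an F2 population.

    The mutant bulk is drawn without replacement from the homozygous mm
    individuals (the recessive phenotype), the wild-type bulk from the
    remaining m+/++ individuals.  Raises ``ValueError`` naming the deficit
    when a class is too small.
    """
    n_p1 = population.n_p1_at_causal()
    mm = np.flatnonzero(n_p1 == 2)
    wt = np.flatnonzero(n_p1 < 2)
    if len(mm) < n_mutant:
        raise ValueError(
            f"mutant bulk needs {n_mutant} mm individuals but the population has {len(mm)}"
        )
    if len(wt) < n_wt:
        raise ValueError(
            f"wild-type bulk needs {n_wt} non-mm individuals but the population has {len(wt)}"
        )
    rng = np.random.default_rng(seed)
    pick_m = np.sort(rng.choice(mm, size=n_mutant, replace=False))
    pick_w = np.sort(rng.choice(wt, size=n_wt, replace=False))
    total = population.origins.shape[2]
    return (
        Bulk("mutant", pick_m, population.origins[pick_m].reshape(2 * n_mutant, total)),
        Bulk("wildtype", pick_w, population.origins[pick_w].reshape(2 * n_wt, total)),
    )


def simulate_bulk_allele_counts(
    bulks: tuple[Bulk, Bulk],
    gmap: GeneticMap,
    mean_depth: float = 20.0,
    seq_error: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled RNA-seq allele counts at every map marker (= SNP).

    Per SNP and bulk the read depth is Poisson(``mean_depth``); each read
    samples a uniformly random chromosome of the bulk and reports its
    allele, miscalled with probability ``seq_error``.  The P1 (mutant
    donor) allele is written as the reference allele.  Columns: chrom,
    pos, ref_allele, alt_allele, mut_ref, mut_alt, wt_ref, wt_alt; rows
    sorted by (chrom, pos).
    """
    mutant, wildtype = bulks
    for b in (mutant, wildtype):
        if b.chromosomes.shape[0] == 0:
            raise ValueError(f"{b.kind} bulk is empty")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0.0 <= seq_error < 0.5):
        raise ValueError("seq_error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    m = len(gmap)

    def bulk_counts(bulk: Bulk) -> tuple[np.ndarray, np.ndarray]:
        f_p1 = (bulk.chromosomes == 0).mean(axis=0)
        depth = rng.poisson(mean_depth, size=m)
        p_read = f_p1 * (1.0 - seq_error) + (1.0 - f_p1) * seq_error
        k_ref = rng.binomial(depth, p_read)
        return k_ref, depth

    mut_ref, mut_n = bulk_counts(mutant)
    wt_ref, wt_n = bulk_counts(wildtype)
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    df = pd.DataFrame(
        {
            "chrom": gmap.df["chrom"].to_numpy(),
            "pos": gmap.df["pos_bp"].to_numpy(),
            "ref_allele": np.array(list(_BASE_STR))[ref_idx],
            "alt_allele": np.array(list(_BASE_STR))[alt_idx],
            "mut_ref": mut_ref,
            "mut_alt": mut_n - mut_ref,
            "wt_ref": wt_ref,
            "wt_alt": wt_n - wt_ref,
        }
    )
    return df.sort_values(["chrom", "pos"], ignore_index=True)


# ---------------------------------------------------------------------------
# Seq-walking read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Insertion:
    chrom: str
    pos: int  # first flank base, 1-based
    weight: float = 1.0


@dataclass
class LibraryTruth:
    """Realised per-insertion read counts for one simulated library."""

    library: str
    seed: int
    insertions: pd.DataFrame  # chrom, pos, weight, n_reads


def simulate_seqwalk_library(
    reference: ReferenceGenome,
    insertions,
    n_reads: int,
    barcode: str,
    tir_tag: str = DEFAULT_TIR_TAG,
    read_len_params: tuple[float, float, int, int] = (150.0, 40.0, 30, 300),
    seq_error: float = 0.01,
    seed: int = 0,
    library: str = "lib",
) -> tuple[list[RawRead], LibraryTruth]:
    """Simulate barcoded flanking-sequence reads for one library.

    Each read is ``barcode + tir_tag + flank`` where the flank is copied
    from the forward strand of the reference starting at the insertion
    position; its length is Normal(mean, sd) truncated to [min, max]
    (``read_len_params``).  Reads are assigned to insertions by a
    multinomial draw over the given weights, every base is miscalled
    independently with probability ``seq_error``, and the output order is
    shuffled.  Qualities are constant (Q40): they carry no information
    downstream.
    """
    if not barcode or not tir_tag:
        raise ValueError("barcode and tir_tag must be non-empty")
    if not (0.0 <= seq_error < 0.5):
        raise ValueError("seq_error must be in [0, 0.5)")
    ins = [i if isinstance(i, Insertion) else Insertion(*i) for i in insertions]
    if not ins:
        raise ValueError("at least one insertion is required")
    for i in ins:
        if i.chrom not in reference.chrom_names:
            raise ValueError(f"insertion chromosome {i.chrom!r} not in reference")
        if not (1 <= i.pos <= reference.length(i.chrom)):
            raise ValueError(f"insertion {i.chrom}:{i.pos} outside reference bounds")
        if i.weight <= 0:
            raise ValueError("insertion weights must be positive")

    rng = np.random.default_rng(seed)
    weights = np.array([i.weight for i in ins], dtype=float)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    mean, sd, lo, hi = read_len_params
    prefix = barcode + tir_tag

    reads: list[RawRead] = []
    serial = 0
    for insertion, c in zip(ins, counts):
        if c == 0:
            continue
        lens = np.clip(np.rint(rng.normal(mean, sd, size=c)), lo, hi).astype(int)
        for flank_len in lens:
            flank = reference.fetch(insertion.chrom, insertion.pos, insertion.pos + int(flank_len) - 1)
            seq = prefix + flank
            errs = np.flatnonzero(rng.random(len(seq)) < seq_error)
            if len(errs):
                arr = bytearray(seq, "ascii")
                shifts = rng.integers(1, 4, size=len(errs))
                for e, s in zip(errs, shifts):
                    base = _BASE_STR.find(chr(arr[e]))
                    arr[e] = ord(_BASE_STR[(base + int(s)) % 4])
                seq = arr.decode("ascii")
            serial += 1
            reads.append(
                RawRead(
                    f"{library}:{serial:07d}:{insertion.chrom}:{insertion.pos}",
                    seq,
                    "I" * len(seq),
                )
            )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = LibraryTruth(
        library,
        seed,
        pd.DataFrame(
            {
                "chrom": [i.chrom for i in ins],
                "pos": [i.pos for i in ins],
                "weight": weights,
                "n_reads": counts,
            }
        ),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Scenario configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the default synthetic study.

    The defaults describe a desk-scale stand-in for the real experiment: a
    single 10 Mb chromosome carrying a centromere with 10x suppressed
    recombination, 2,000 expressed SNPs, phenotype bulks of 123 mutant and
    123 wild-type F2 individuals, 20x mean RNA-seq depth per SNP and bulk,
    and two Seq-walking libraries of 50,000 reads each with the published
    library barcodes.
    """

    chrom_length: int = 10_000_000
    n_genes: int = 80
    n_markers: int = 2_000
    centromere: tuple[int, int] = (4_000_000, 6_000_000)
    suppression_factor: float = 0.1
    cm_per_mb: float = 5.0
    n_f2: int = 800
    n_mutant: int = 123
    n_wt: int = 123
    mean_depth: float = 20.0
    seq_error: float = 0.01
    n_reads: int = 50_000
    flank_len_mean: float = 150.0
    flank_len_sd: float = 40.0
    flank_len_min: int = 30
    flank_len_max: int = 300
    barcodes: dict = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    tir_tag: str = DEFAULT_TIR_TAG
    n_shared_insertions: int = 20
    n_control_private: int = 9
    causal_read_weight: float = 10.0
    min_insertion_spacing: int = 1_000
    master_seed: int = 1

    def __post_init__(self):
        for name in ("chrom_length", "n_genes", "n_markers", "n_f2", "n_mutant",
                     "n_wt", "n_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")
        codes = list(self.barcodes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("barcodes must be distinct")
        if len({len(c) for c in codes}) != 1:
            raise ValueError("barcodes must have equal length")

    @property
    def read_len_params(self) -> tuple[float, float, int, int]:
        return (self.flank_len_mean, self.flank_len_sd, self.flank_len_min, self.flank_len_max)


@dataclass
class SimTruth:
    """Ground truth of one synthetic scenario, for recovery testing."""

    causal_chrom: str
    causal_pos: int  # position of the planted causal insertion
    causal_gene: str
    causal_marker_pos: int  # map marker acting as the causal locus in the F2
    planted_insertions: pd.DataFrame  # chrom, pos, libraries, weight
    seeds: dict

    def __post_init__(self):
        mut_only = self.planted_insertions[
            self.planted_insertions["libraries"] == "mutant"
        ]
        causal = mut_only[
            (mut_only["chrom"] == self.causal_chrom) & (mut_only["pos"] == self.causal_pos)
        ]
        if len(causal) != 1:
            raise ValueError("the causal insertion must be present exactly once, mutant-private")

    def to_dict(self) -> dict:
        return {
            "causal_chrom": self.causal_chrom,
            "causal_pos": int(self.causal_pos),
            "causal_gene": self.causal_gene,
            "causal_marker_pos": int(self.causal_marker_pos),
            "planted_insertions": self.planted_insertions.to_dict(orient="records"),
            "seeds": {k: int(v) for k, v in self.seeds.items()},
        }
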