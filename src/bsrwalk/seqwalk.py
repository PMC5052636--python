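"""Transposon insertion-site calling from barcoded flanking-sequence reads.

Seq-walking sequences outward from the terminal inverted repeat (TIR) of a
transposon into the neighbouring genomic DNA, so every informative read has
the layout ``barcode + TIR tag + genomic flank``.  This module takes such
reads for a mutant-derived library and a control library and produces a
ranked candidate table:

1. :func:`demultiplex` sorts reads by exact barcode prefix,
2. :func:`trim_mu_flank` strips the TIR tag (tolerating a few mismatches),
3. :func:`filter_length` discards flanks too short to place uniquely,
4. :func:`map_flanks` aligns flanks with a unique-exact-seed, ungapped
   extension strategy against a k-mer index of the reference,
5. :func:`call_sites` clusters alignment start points into fixed-width bins,
6. :func:`subtract_control` removes sites also recovered from the control
   library (heritable insertions present before mutagenesis cannot be
   causal), and
7. :func:`restrict_and_rank` keeps sites inside the linkage mapping
   interval and ranks them by supporting read count.

Every stage reports integer read accounting; the identities
``input = assigned + unassigned``, ``assigned = trimmed + rejected``,
``trimmed = kept + length_filtered`` and
``kept = mapped + unmapped + multimapped`` are checked exactly.

Insertion coordinates are 1-based and refer to the first genomic base of
the flank on the forward strand of the reference, matching the convention
of the synthetic read generator.  The built-in mapper is deliberately
minimal (unique 31-mer seed, ungapped extension, no splicing or gaps): it
is meant for desk-scale references; site tables produced by an external
aligner can be imported from TSV instead via :meth:`SiteTable.from_tsv`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Read records and FASTQ round-trip
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte-level base encoding: A,C,G,T -> 0..3, anything else -> 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENC[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """A single sequencing read as it comes off the instrument."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass(frozen=True)
class FlankRead:
    """A genomic flank remaining after barcode and TIR-tag removal."""

    id: str
    library: str
    sequence: str


@dataclass(frozen=True)
class TrimRejected:
    """A read that failed TIR-tag trimming, with the reason."""

    id: str
    reason: str


def read_fastq(path) -> list[RawRead]:
    return [
        RawRead(rec.id, str(rec.seq), "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[RawRead], path) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
            yield rec

    SeqIO.write(records(), str(path), "fastq")


# ---------------------------------------------------------------------------
# Demultiplexing and trimming
# ---------------------------------------------------------------------------


def demultiplex(reads: Sequence[RawRead], barcode_map: dict[str, str]) -> tuple[dict[str, list[RawRead]], int]:
    """Sort reads into libraries by exact barcode prefix match.

    The barcode is removed from assigned reads.  Returns the per-library
    read lists and the number of unassigned reads; by construction
    ``sum(len(v) for v in assigned.values()) + unassigned == len(reads)``.
    """
    if not barcode_map:
        raise ValueError("barcode_map must contain at least one barcode")
    codes = list(barcode_map.values())
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate barcode sequences in {barcode_map!r}")
    lengths = {len(c) for c in codes}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have equal length")
    (blen,) = lengths
    by_code = {code: label for label, code in barcode_map.items()}

    assigned: dict[str, list[RawRead]] = {label: [] for label in barcode_map}
    unassigned = 0
    for read in reads:
        label = by_code.get(read.sequence[:blen])
        if label is None:
            unassigned += 1
        else:
            assigned[label].append(
                RawRead(read.id, read.sequence[blen:], read.quality[blen:])
            )
    return assigned, unassigned


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_mu_flank(read: RawRead, tir_tag: str, max_mismatch: int = 2, library: str = "") -> FlankRead | TrimRejected:
    """Strip the transposon TIR tag from a demultiplexed read.

    The tag must appear at the very start of the (already barcode-stripped)
    read with at most ``max_mismatch`` substitutions; the remainder is the
    genomic flank.
    """
    if not tir_tag:
        raise ValueError("tir_tag must be non-empty")
    if len(read.sequence) <= len(tir_tag):
        return TrimRejected(read.id, "read shorter than TIR tag")
    mism = _hamming(read.sequence[: len(tir_tag)], tir_tag)
    if mism > max_mismatch:
        return TrimRejected(read.id, f"{mism} mismatches to TIR tag (max {max_mismatch})")
    return FlankRead(read.id, library, read.sequence[len(tir_tag):])


def filter_length(flanks: Sequence[FlankRead], min_exclusive: int = 90) -> list[FlankRead]:
    """Keep flanks strictly longer than ``min_exclusive`` bases.

    A 90 bp flank is removed at the default threshold; a 91 bp flank is
    kept.  Short flanks cannot be placed confidently and inflate spurious
    site calls.
    """
    return [f for f in flanks if len(f.sequence) > min_exclusive]


# ---------------------------------------------------------------------------
# Minimal seed-and-extend mapper
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of an encoded sequence plus a validity mask."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    enc64 = enc.astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes <<= np.uint64(2)
        codes |= enc64[j : j + n]
    # windows containing a non-ACGT base are invalid seeds
    if not (enc >= 4).any():
        return codes, np.ones(n, dtype=bool)
    bad = (enc >= 4).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    return codes, valid


class KmerIndex:
    """Exact k-mer index over a reference, queried via binary search."""

    def __init__(self, sequences: dict[str, str], seed_len: int = 31):
        if seed_len < 4 or seed_len > 31:
            raise ValueError("seed_len must be between 4 and 31")
        self.seed_len = seed_len
        self.chrom_names = list(sequences)
        self.enc = {name: _encode(seq) for name, seq in sequences.items()}
        self._offsets = {}
        all_codes, all_pos = [], []
        offset = 0
        for name in self.chrom_names:
            codes, valid = _kmer_codes(self.enc[name], seed_len)
            if valid.all():
                all_codes.append(codes)
                all_pos.append(np.arange(len(codes), dtype=np.int64) + offset)
            else:
                idx = np.flatnonzero(valid)
                all_codes.append(codes[idx])
                all_pos.append(idx + offset)
            self._offsets[name] = offset
            offset += len(self.enc[name])
        codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.uint64)
        pos = np.concatenate(all_pos) if all_pos else np.empty(0, np.int64)
        order = np.argsort(codes)
        self._sorted_codes = codes[order]
        self._global_pos = pos[order]
        bounds = np.array([self._offsets[n] for n in self.chrom_names] + [offset], dtype=np.int64)
        self._bounds = bounds

    @classmethod
    def from_reference(cls, reference, seed_len: int = 31) -> "KmerIndex":
        return cls(dict(zip(reference.chrom_names, reference.sequences)), seed_len)

    def _locate(self, global_pos: int) -> tuple[str, int]:
        """Global 0-based offset -> (chrom, 0-based position)."""
        i = int(np.searchsorted(self._bounds, global_pos, side="right") - 1)
        name = self.chrom_names[i]
        return name, int(global_pos - self._offsets[name])

    def lookup(self, code) -> np.ndarray:
        # the needle must stay uint64: a Python int would trigger a float64
        # cast of the whole index (slow and lossy for 62-bit codes)
        code = np.uint64(code)
        lo = np.searchsorted(self._sorted_codes, code, side="left")
        hi = np.searchsorted(self._sorted_codes, code, side="right")
        return self._global_pos[lo:hi]

    def lookup_many(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._sorted_codes, codes.astype(np.uint64), side="left")
        hi = np.searchsorted(self._sorted_codes, codes.astype(np.uint64), side="right")
        return lo, hi


@dataclass(frozen=True)
class Alignment:
    read_id: str
    chrom: str
    pos: int  # 1-based position of the first flank base on the forward strand
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class Unmapped:
    read_id: str
    reason: str


@dataclass(frozen=True)
class Multimapped:
    read_id: str
    n_hits: int


def _query_code(seq: str, k: int):
    """uint64 code of the first k-mer, or None if short or non-ACGT."""
    enc = _encode(seq[:k])
    if len(enc) < k or (enc >= 4).any():
        return None
    code = 0
    for b in enc:
        code = (code << 2) | int(b)
    return np.uint64(code)


def _extend(enc_q: np.ndarray, chrom_enc: np.ndarray, start0: int) -> tuple[int, int]:
    """Ungapped comparison of a query against the reference at start0.

    Returns (mismatches over the overlap, overlap length); bases running
    off the chromosome end are clipped.
    """
    m = min(len(enc_q), len(chrom_enc) - start0)
    mism = int(np.count_nonzero(enc_q[:m] != chrom_enc[start0 : start0 + m]))
    return mism, m


def map_flanks(
    flanks: Sequence[FlankRead],
    index: KmerIndex,
    max_mismatch_frac: float = 0.05,
) -> list[Alignment | Unmapped | Multimapped]:
    """Place flanks on the reference by unique exact seed + ungapped extension.

    The first ``seed_len``-mer of each flank is looked up exactly, on both
    the forward strand and (via the flank's reverse complement) the reverse
    strand.  Each seed hit is extended without gaps; hits with a mismatch
    fraction above ``max_mismatch_frac`` are discarded.  A single best
    surviving placement yields an :class:`Alignment`; several equally good
    placements yield :class:`Multimapped` (excluded from site calling);
    none yields :class:`Unmapped`.

    The reported coordinate is always that of the flank base adjacent to
    the transposon (the first base of the flank as sequenced), so forward
    and reverse placements of the same insertion agree.
    """
    k = index.seed_len
    results: list[Alignment | Unmapped | Multimapped | None] = [None] * len(flanks)
    todo = []
    for i, flank in enumerate(flanks):
        if len(flank.sequence) < k:
            results[i] = Unmapped(
                flank.id, f"flank shorter than seed ({len(flank.sequence)} < {k})"
            )
        else:
            todo.append(i)
    if not todo:
        return results

    # batch-encode the seed k-mers of every query: the flank's first k bases
    # (forward strand) and the reverse complement of its last k bases (the
    # first k-mer of the reverse-complemented flank)
    first = np.array([flanks[i].sequence[:k] for i in todo], dtype=f"S{k}")
    last = np.array([flanks[i].sequence[-k:] for i in todo], dtype=f"S{k}")
    fwd_e = _ENC[first.view(np.uint8).reshape(len(todo), k)]
    last_e = _ENC[last.view(np.uint8).reshape(len(todo), k)]
    fwd_valid = (fwd_e < 4).all(axis=1)
    rc_valid = (last_e < 4).all(axis=1)
    rc_e = (3 - last_e.astype(np.int16))[:, ::-1].astype(np.uint8)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd_codes = (fwd_e.astype(np.uint64) * powers).sum(axis=1)
    rc_codes = (np.where(rc_e < 4, rc_e, 0).astype(np.uint64) * powers).sum(axis=1)
    flo, fhi = index.lookup_many(fwd_codes)
    rlo, rhi = index.lookup_many(rc_codes)

    for qi, i in enumerate(todo):
        flank = flanks[i]
        seq = flank.sequence
        L = len(seq)
        allowed = int(max_mismatch_frac * L)
        candidates: list[tuple[int, str, int, str]] = []  # (mism, chrom, pos1, strand)

        if fwd_valid[qi] and fhi[qi] > flo[qi]:
            enc_q = _encode(seq)
            for gp in index._global_pos[flo[qi] : fhi[qi]]:
                chrom, start0 = index._locate(int(gp))
                mism, m = _extend(enc_q, index.enc[chrom], start0)
                if mism <= allowed and m >= k:
                    candidates.append((mism, chrom, start0 + 1, "+"))

        if rc_valid[qi] and rhi[qi] > rlo[qi]:
            enc_rc = _encode(revcomp(seq))
            for gp in index._global_pos[rlo[qi] : rhi[qi]]:
                chrom, start0 = index._locate(int(gp))
                mism, m = _extend(enc_rc, index.enc[chrom], start0)
                if mism <= allowed and m >= k:
                    # rc spans start0 .. start0+m-1; the flank's first base is
                    # the last base of that span
                    candidates.append((mism, chrom, start0 + m, "-"))

        if not candidates:
            results[i] = Unmapped(flank.id, "no acceptable seed hit")
            continue
        best = min(c[0] for c in candidates)
        top = sorted(set(c for c in candidates if c[0] == best))
        if len(top) > 1:
            results[i] = Multimapped(flank.id, len(top))
        else:
            mism, chrom, pos, strand = top[0]
            results[i] = Alignment(flank.id, chrom, pos, strand, mism)
    return results


def map_flank(flank: FlankRead, index: KmerIndex, max_mismatch_frac: float = 0.05):
    """Single-read convenience wrapper around :func:`map_flanks`."""
    return map_flanks([flank], index, max_mismatch_frac)[0]


# ---------------------------------------------------------------------------
# Site calling, subtraction, ranking
# ---------------------------------------------------------------------------


@dataclass
class SiteTable:
    """Clustered insertion sites with supporting read counts.

    ``df`` has columns ``chrom``, ``bin_start`` (1-based, a multiple of the
    bin width offset by 1), ``read_count`` and ``library``.
    """

    df: pd.DataFrame
    bin_width: int

    COLUMNS = ["chrom", "bin_start", "read_count", "library"]

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, bin_width: int) -> "SiteTable":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        return cls(df[cls.COLUMNS], bin_width)

    def to_bed(self, path) -> None:
        """Export sites as BED (0-based half-open bins)."""
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.bin_start - 1}\t{row.bin_start - 1 + self.bin_width}"
                    f"\t{row.library}\t{row.read_count}\n"
                )


def call_sites(alignments: Sequence, bin_width: int = 100, library: str = "") -> SiteTable:
    """Cluster alignment start points into fixed-width bins.

    Only :class:`Alignment` entries contribute; unmapped and multimapped
    results are excluded.  Bin coordinates are 1-based: position ``p``
    falls in the bin starting at ``(p - 1) // bin * bin + 1``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    rows = [
        (a.chrom, (a.pos - 1) // bin_width * bin_width + 1)
        for a in alignments
        if isinstance(a, Alignment)
    ]
    if not rows:
        df = pd.DataFrame(columns=SiteTable.COLUMNS)
        df["bin_start"] = df["bin_start"].astype(int)
        df["read_count"] = df["read_count"].astype(int)
        return SiteTable(df, bin_width)
    df = (
        pd.DataFrame(rows, columns=["chrom", "bin_start"])
        .groupby(["chrom", "bin_start"], as_index=False)
        .size()
        .rename(columns={"size": "read_count"})
        .sort_values(["chrom", "bin_start"], ignore_index=True)
    )
    df["library"] = library
    return SiteTable(df[SiteTable.COLUMNS], bin_width)


def subtract_control(sample: SiteTable, control: SiteTable, tolerance: int = 1) -> SiteTable:
    """Remove sample sites present in the control library.

    A sample site is dropped when a control site on the same chromosome
    lies within ``tolerance`` bins of it (the tolerance absorbs small
    coordinate jitter such as the transposon's target-site duplication).
    """
    if sample.bin_width != control.bin_width:
        raise ValueError(
            f"bin widths differ: sample {sample.bin_width}, control {control.bin_width}"
        )
    if len(control) == 0 or len(sample) == 0:
        return SiteTable(sample.df.copy(), sample.bin_width)
    max_dist = tolerance * sample.bin_width
    keep = np.ones(len(sample.df), dtype=bool)
    for chrom, grp in control.df.groupby("chrom"):
        cbins = np.sort(grp["bin_start"].to_numpy())
        mask = sample.df["chrom"].to_numpy() == chrom
        sbins = sample.df.loc[mask, "bin_start"].to_numpy()
        i = np.searchsorted(cbins, sbins)
        near = np.zeros(len(sbins), dtype=bool)
        left_ok = i > 0
        near[left_ok] |= (sbins[left_ok] - cbins[i[left_ok] - 1]) <= max_dist
        right_ok = i < len(cbins)
        near[right_ok] |= (cbins[i[right_ok]] - sbins[right_ok]) <= max_dist
        keep[mask] &= ~near
    return SiteTable(sample.df[keep].reset_index(drop=True), sample.bin_width)


@dataclass
class CandidateReport:
    """Sites inside the mapping interval, ranked by supporting reads.

    ``df`` columns: rank, chrom, bin_start, read_count, library, gene_id,
    inside_interval (always True for retained rows).  Ties on read count
    are broken by ascending coordinate, so rank 1 is unique.
    """

    df: pd.DataFrame
    n_outside: int

    @property
    def candidate(self) -> pd.Series:
        return self.df.iloc[0]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class NoCandidate:
    reason: str


def restrict_and_rank(sites: SiteTable, interval, genes: Sequence) -> CandidateReport | NoCandidate:
    """Keep sites whose bin overlaps the mapping interval and rank them.

    ``interval`` needs ``chrom``, ``start_bp`` and ``end_bp`` attributes
    (a :class:`bsrwalk.scan.MappingInterval`); ``genes`` is a sequence of
    gene records with ``id``, ``chrom``, ``start``, ``end``.  The rank-1
    site — the one with the most supporting reads — is the candidate.
    """
    if len(sites) == 0:
        return NoCandidate("no insertion sites to rank")
    df = sites.df.copy()
    bin_end = df["bin_start"] + sites.bin_width - 1
    inside = (
        (df["chrom"] == interval.chrom)
        & (bin_end >= interval.start_bp)
        & (df["bin_start"] <= interval.end_bp)
    )
    n_outside = int((~inside).sum())
    df = df[inside].copy()
    if df.empty:
        return NoCandidate("no insertion site inside the mapping interval")
    df = df.sort_values(
        ["read_count", "chrom", "bin_start"], ascending=[False, True, True], ignore_index=True
    )
    gene_ids = []
    for row in df.itertuples(index=False):
        end = row.bin_start + sites.bin_width - 1
        hit = None
        for g in genes:
            if g.chrom == row.chrom and g.start <= end and g.end >= row.bin_start:
                hit = g.id
                break
        gene_ids.append(hit)
    df["gene_id"] = gene_ids
    df["inside_interval"] = True
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return CandidateReport(df, n_outside)


# ---------------------------------------------------------------------------
# Per-library processing with exact read accounting
# ---------------------------------------------------------------------------


class AccountingError(AssertionError):
    """An integer read-conservation identity was violated."""


@dataclass
class LibraryAccounting:
    library: str
    n_assigned: int = 0
    n_trimmed: int = 0
    n_rejected: int = 0
    n_kept: int = 0
    n_length_filtered: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_multimapped: int = 0

    def check(self) -> None:
        if self.n_assigned != self.n_trimmed + self.n_rejected:
            raise AccountingError(
                f"{self.library}: trimming lost reads "
                f"({self.n_assigned} != {self.n_trimmed} + {self.n_rejected})"
            )
        if self.n_trimmed != self.n_kept + self.n_length_filtered:
            raise AccountingError(
                f"{self.library}: length filter lost reads "
                f"({self.n_trimmed} != {self.n_kept} + {self.n_length_filtered})"
            )
        if self.n_kept != self.n_mapped + self.n_unmapped + self.n_multimapped:
            raise AccountingError(
                f"{self.library}: mapping lost reads "
                f"({self.n_kept} != {self.n_mapped} + {self.n_unmapped} + {self.n_multimapped})"
            )


@dataclass
class RunAccounting:
    n_input: int
    n_unassigned: int
    libraries: dict[str, LibraryAccounting] = field(default_factory=dict)

    def check(self) -> None:
        assigned = sum(acc.n_assigned for acc in self.libraries.values())
        if self.n_input != assigned + self.n_unassigned:
            raise AccountingError(
                f"demultiplex: lost reads ({self.n_input} != {assigned} + {self.n_unassigned})"
            )
        for acc in self.libraries.values():
            acc.check()

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_unassigned": self.n_unassigned,
            "libraries": {k: dataclasses.asdict(v) for k, v in self.libraries.items()},
        }


def process_library(
    reads: Sequence[RawRead],
    library: str,
    tir_tag: str,
    index: KmerIndex,
    min_len: int = 90,
    max_mismatch: int = 2,
    bin_width: int = 100,
    max_mismatch_frac: float = 0.05,
) -> tuple[SiteTable, LibraryAccounting]:
    """Trim, filter, map and call sites for one demultiplexed library."""
    acc = LibraryAccounting(library=library, n_assigned=len(reads))
    flanks: list[FlankRead] = []
    for read in reads:
        out = trim_mu_flank(read, tir_tag, max_mismatch=max_mismatch, library=library)
        if isinstance(out, FlankRead):
            flanks.append(out)
    acc.n_trimmed = len(flanks)
    acc.n_rejected = acc.n_assigned - acc.n_trimmed

    kept = filter_length(flanks, min_exclusive=min_len)
    acc.n_kept = len(kept)
    acc.n_length_filtered = acc.n_trimmed - acc.n_kept

    results = map_flanks(kept, index, max_mismatch_frac=max_mismatch_frac)
    acc.n_mapped = sum(isinstance(r, Alignment) for r in results)
    acc.n_unmapped = sum(isinstance(r, Unmapped) for r in results)
    acc.n_multimapped = sum(isinstance(r, Multimapped) for r in results)
    acc.check()
    return call_sites(results, bin_width=bin_width, library=library), acc


@dataclass
class SeqwalkResult:
    sample_sites: SiteTable
    control_sites: SiteTable
    candidate_sites: SiteTable  # after control subtraction
    report: CandidateReport | NoCandidate | None
    accounting: RunAccounting


def run_seqwalk(
    reads: Sequence[RawRead],
    barcode_map: dict[str, str],
    tir_tag: str,
    reference,
    mutant_label: str = "mutant",
    control_label: str = "control",
    min_len: int = 90,
    max_mismatch: int = 2,
    bin_width: int = 100,
    tolerance: int = 1,
    seed_len: int = 31,
    interval=None,
    genes: Sequence | None = None,
) -> SeqwalkResult:
    """Full Seq-walking analysis: demultiplex, per-library site calling,
    control subtraction and (when an interval is given) candidate ranking.
    """
    for label in (mutant_label, control_label):
        if label not in barcode_map:
            raise ValueError(f"barcode_map lacks library {label!r}")
    assigned, unassigned = demultiplex(reads, barcode_map)
    accounting = RunAccounting(n_input=len(reads), n_unassigned=unassigned)

    index = KmerIndex.from_reference(reference, seed_len=seed_len)
    sample_sites, acc_m = process_library(
        assigned[mutant_label], mutant_label, tir_tag, index,
        min_len=min_len, max_mismatch=max_mismatch, bin_width=bin_width,
    )
    control_sites, acc_c = process_library(
        assigned[control_label], control_label, tir_tag, index,
        min_len=min_len, max_mismatch=max_mismatch, bin_width=bin_width,
    )
    accounting.libraries[mutant_label] = acc_m
    accounting.libraries[control_label] = acc_c
    accounting.check()

    candidate_sites = subtract_control(sample_sites, control_sites, tolerance=tolerance)
    report = None
    if interval is not None:
        report = restrict_and_rank(candidate_sites, interval, genes or [])
    return SeqwalkResult(sample_sites, control_sites, candidate_sites, report, accounting)
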