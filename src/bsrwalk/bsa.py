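"""Bayesian linkage posterior from pooled allele counts (BSR-Seq).

In an F2 mapping population bulked by a recessive phenotype, the mutant
bulk contains only homozygous *mm* individuals, so at a SNP with
recombination fraction *r* to the causal locus the mutant-donor (P1)
allele occupies a fraction

    f_m(r) = 1 - r

of the mutant-bulk chromosomes, while among phenotypically wild-type
siblings (1/3 ``++`` : 2/3 ``m+``) it occupies

    f_w(r) = 1/3 + r/3.

At complete linkage (r = 0) the mutant pool therefore shows only one
allele; an unlinked SNP (r = 1/2) shows both alleles at equal frequency in
both pools.  Each bulk's reads are modelled as binomial draws with a
symmetric per-read miscall probability ``epsilon``.  The posterior that a
SNP is linked combines a point-mass prior ``pi`` on linkage (with r
uniform on a quadrature grid inside (0, 1/2)) against the unlinked
alternative r = 1/2:

    P(linked | k) = pi * mean_r L(k | r) / (pi * mean_r L(k | r) + (1 - pi) * L(k | 1/2))

Two likelihood modes are available.  The default treats allele
frequencies at their expectations f_b(r).  The exact mode additionally
marginalises over the finite bulk: the number of P1 chromosomes among the
2N sampled chromosomes of a bulk is Binomial(2N, f_b(r)), and reads are
binomial in the realised chromosome fraction.  The exact mode is slower
and captures the overdispersion that finite bulks add on top of read
sampling; it also serves as the reference for validating the fast mode.

All likelihood work is done on the log scale with log-sum-exp, so
degenerate inputs (zero depth, impossible observations at epsilon = 0)
yield well-defined posteriors, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

MUTANT = "mutant"
WILDTYPE = "wildtype"

_COUNT_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele",
                  "mut_ref", "mut_alt", "wt_ref", "wt_alt"]


def expected_allele_freq(r, bulk_kind: str):
    """Expected mutant-parent (P1) allele frequency among bulk chromosomes.

    ``f_m(r) = 1 - r`` for the mutant bulk, ``f_w(r) = 1/3 + r/3`` for the
    wild-type bulk.  Accepts scalars or arrays; r must lie in [0, 0.5].
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if bulk_kind == MUTANT:
        out = 1.0 - r
    elif bulk_kind == WILDTYPE:
        out = (1.0 + r) / 3.0
    else:
        raise ValueError(f"bulk_kind must be {MUTANT!r} or {WILDTYPE!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SNPCounts:
    """Per-SNP read evidence: P1-allele and total counts per bulk."""

    chrom: str
    pos: int
    k_m: int  # mutant-bulk reads carrying the P1 allele
    n_m: int
    k_w: int
    n_w: int

    def __post_init__(self):
        for k, n, which in ((self.k_m, self.n_m, "mutant"), (self.k_w, self.n_w, "wild-type")):
            if n < 0 or not (0 <= k <= n):
                raise ValueError(f"invalid {which}-bulk counts k={k}, n={n}")


@dataclass
class LinkageModelParams:
    """Model parameters: linkage prior, read-error rate, r quadrature grid
    and bulk sizes (individuals)."""

    pi: float = 0.05
    epsilon: float = 0.01
    grid_size: int = 64
    r_lo: float = 0.0005
    r_hi: float = 0.4995
    n_mutant: int = 123
    n_wt: int = 123
    exact: bool = False

    def __post_init__(self):
        if not (0.0 < self.pi < 1.0):
            raise ValueError("pi must be in (0, 1)")
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5)")
        if not (0.0 < self.r_lo < self.r_hi < 0.5):
            raise ValueError("r grid must lie strictly inside (0, 0.5)")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.n_mutant < 1 or self.n_wt < 1:
            raise ValueError("bulk sizes must be positive")

    @property
    def r_grid(self) -> np.ndarray:
        return np.linspace(self.r_lo, self.r_hi, self.grid_size)


@dataclass(frozen=True)
class LinkagePosterior:
    chrom: str
    pos: int
    posterior: float


def _read_prob(f, epsilon):
    """Probability a read reports the P1 allele given its true frequency."""
    return f * (1.0 - epsilon) + (1.0 - f) * epsilon


def _bulk_loglik_default(k, n, r, bulk_kind, params) -> np.ndarray:
    """log L(k | r) with the bulk allele frequency at its expectation.

    Broadcasts counts of shape (S, 1) against r of shape (R,)."""
    f = expected_allele_freq(r, bulk_kind)
    p = _read_prob(np.asarray(f, dtype=float), params.epsilon)
    return binom.logpmf(k, n, p)


def _bulk_loglik_exact(k, n, r, bulk_kind, params) -> np.ndarray:
    """log L(k | r) marginalised over the finite bulk.

    J ~ Binomial(2N, f_b(r)) chromosomes carry the P1 allele; reads are
    then Binomial(n, J/2N corrected for epsilon).  Returns shape
    (S, R) for counts (S, 1) against r (R,)."""
    n_ind = params.n_mutant if bulk_kind == MUTANT else params.n_wt
    two_n = 2 * n_ind
    j = np.arange(two_n + 1)
    f = np.atleast_1d(np.asarray(expected_allele_freq(r, bulk_kind), dtype=float))
    log_w = binom.logpmf(j[None, :], two_n, f[:, None])  # (R, J)
    p_j = _read_prob(j / two_n, params.epsilon)  # (J,)
    k = np.atleast_2d(k)
    n = np.atleast_2d(n)
    out = np.empty((k.shape[0], len(f)))
    # chunk over SNPs to bound the (S, R, J) intermediate
    chunk = max(1, int(2_000_000 / (len(f) * (two_n + 1))))
    for lo in range(0, k.shape[0], chunk):
        hi = min(lo + chunk, k.shape[0])
        log_k = binom.logpmf(k[lo:hi], n[lo:hi], p_j[None, :])  # (s, J)
        out[lo:hi] = logsumexp(log_w[None, :, :] + log_k[:, None, :], axis=2)
    return out


def snp_log_likelihood(counts: SNPCounts, r, params: LinkageModelParams, exact: bool | None = None):
    """Joint log-likelihood of both bulks' counts at recombination fraction r.

    With zero depth in both bulks the log-likelihood is 0 for every r; at
    ``epsilon = 0`` an observation that is impossible under complete
    linkage (k_m < n_m at r = 0) has log-likelihood -inf.
    """
    exact = params.exact if exact is None else exact
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    fn = _bulk_loglik_exact if exact else _bulk_loglik_default
    ll = (
        fn(np.array([[counts.k_m]]), np.array([[counts.n_m]]), r_arr, MUTANT, params)
        + fn(np.array([[counts.k_w]]), np.array([[counts.n_w]]), r_arr, WILDTYPE, params)
    )[0]
    return ll if np.ndim(r) else float(ll[0])


def _posterior_from_loglik(ll_grid: np.ndarray, ll_null: np.ndarray, pi: float) -> np.ndarray:
    """Posterior linkage probability from (S, R) grid and (S,) null log-liks."""
    log_linked = logsumexp(ll_grid, axis=1) - np.log(ll_grid.shape[1]) + np.log(pi)
    log_null = ll_null + np.log1p(-pi)
    with np.errstate(invalid="ignore"):
        post = np.exp(log_linked - np.logaddexp(log_linked, log_null))
    # both hypotheses numerically impossible: the data are uninformative
    post = np.where(np.isfinite(log_linked) | np.isfinite(log_null), post, pi)
    return np.clip(post, 0.0, 1.0)


def linkage_posterior(counts: SNPCounts, params: LinkageModelParams) -> LinkagePosterior:
    """Posterior probability that one SNP is linked to the causal locus."""
    ll_grid = snp_log_likelihood(counts, params.r_grid, params)
    ll_null = snp_log_likelihood(counts, 0.5, params)
    post = _posterior_from_loglik(ll_grid[None, :], np.array([ll_null]), params.pi)
    return LinkagePosterior(counts.chrom, counts.pos, float(post[0]))


def _require_sorted(df: pd.DataFrame) -> None:
    key = df[["chrom", "pos"]]
    if not key.equals(key.sort_values(["chrom", "pos"], ignore_index=True)):
        raise ValueError("counts table must be sorted by (chrom, pos)")


def compute_posteriors(counts: pd.DataFrame, params: LinkageModelParams) -> pd.DataFrame:
    """Posterior linkage probability for every SNP of a bulk-counts table.

    ``counts`` uses the bulk-counts TSV columns (mut_ref/mut_alt etc.,
    with the mutant-parent allele as reference) and must be sorted by
    (chrom, pos).  Returns a DataFrame with chrom, pos and posterior in the
    input order; each SNP is scored independently of its neighbours.
    """
    out_cols = ["chrom", "pos", "posterior"]
    if counts.empty:
        return pd.DataFrame(columns=out_cols)
    _require_sorted(counts.reset_index(drop=True))
    k_m = counts["mut_ref"].to_numpy()[:, None]
    n_m = (counts["mut_ref"] + counts["mut_alt"]).to_numpy()[:, None]
    k_w = counts["wt_ref"].to_numpy()[:, None]
    n_w = (counts["wt_ref"] + counts["wt_alt"]).to_numpy()[:, None]
    fn = _bulk_loglik_exact if params.exact else _bulk_loglik_default
    grid = params.r_grid
    ll_grid = fn(k_m, n_m, grid, MUTANT, params) + fn(k_w, n_w, grid, WILDTYPE, params)
    null = np.array([0.5])
    ll_null = (fn(k_m, n_m, null, MUTANT, params) + fn(k_w, n_w, null, WILDTYPE, params))[:, 0]
    post = _posterior_from_loglik(ll_grid, ll_null, params.pi)
    return pd.DataFrame(
        {"chrom": counts["chrom"].to_numpy(), "pos": counts["pos"].to_numpy(), "posterior": post}
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_bulk_counts_tsv(df: pd.DataFrame, path) -> None:
    df[_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bulk_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bulk counts table missing columns: {missing}")
    return df


def read_bulk_counts_vcf(path, mutant_sample: str, wt_sample: str) -> pd.DataFrame:
    """Bulk counts from a VCF with per-sample allele depths (FORMAT/AD).

    Expects one sample per bulk; only biallelic SNPs with AD present in
    both samples are used.  The VCF REF allele is taken as the
    mutant-parent allele, matching the TSV convention.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for name in (mutant_sample, wt_sample):
            if name not in vcf.header.samples:
                raise ValueError(f"sample {name!r} not in VCF header")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            try:
                ad_m = rec.samples[mutant_sample]["AD"]
                ad_w = rec.samples[wt_sample]["AD"]
            except KeyError:
                continue
            if ad_m is None or ad_w is None:
                continue
            rows.append(
                (rec.chrom, rec.pos, rec.ref, rec.alts[0],
                 int(ad_m[0]), int(ad_m[1]), int(ad_w[0]), int(ad_w[1]))
            )
    return pd.DataFrame(rows, columns=_COUNT_COLUMNS)


def write_posteriors_tsv(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "posterior"]].to_csv(path, sep="\t", index=False)


def read_posteriors_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "pos", "posterior") if c not in df.columns]
    if missing:
        raise ValueError(f"posterior table missing columns: {missing}")
    return df
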