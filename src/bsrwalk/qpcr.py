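"""qPCR standard-curve efficiency and efficiency-corrected expression.

A dilution-series standard curve regresses threshold cycle Ct on
log10(dilution); its slope gives the per-primer amplification efficiency

    E = 10^(-1/slope) - 1,

where E = 1 is perfect per-cycle doubling (slope = -1/log10(2) = -3.32).
Acceptable assays have E between 85% and 105% (bounds inclusive).
Relative expression uses the efficiency-corrected single-calibrator ratio

    ratio = (1 + E_target)^(-Ct_target) / (1 + E_ref)^(-Ct_ref),

i.e. each gene's signal is back-extrapolated with its own efficiency
before forming the target/reference ratio (Pfaffl-style correction; with
E_target = E_ref = 1 this reduces to the familiar 2^-dCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def amplification_efficiency(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope (must be < 0)."""
    if not slope < 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def validate_efficiency(efficiency: float, lo: float = 0.85, hi: float = 1.05) -> bool:
    """Whether an efficiency lies in the accepted window (inclusive bounds)."""
    return lo <= efficiency <= hi


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    efficiency: float
    r_squared: float

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


def fit_standard_curve(log10_dilution, ct) -> StandardCurve:
    """Least-squares Ct ~ log10(dilution) fit of a dilution series."""
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    fit = stats.linregress(x, y)
    return StandardCurve(float(fit.slope), amplification_efficiency(float(fit.slope)),
                         float(fit.rvalue) ** 2)


def relative_expression(ct_target: float, ct_ref: float,
                        e_target: float = 1.0, e_ref: float = 1.0) -> float:
    """Efficiency-corrected expression of a target relative to a reference gene."""
    if e_target <= 0 or e_ref <= 0:
        raise ValueError("efficiencies must be positive")
    return (1.0 + e_target) ** (-ct_target) / (1.0 + e_ref) ** (-ct_ref)


def relative_expression_table(
    ct_table: pd.DataFrame,
    reference_gene: str,
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample relative expression, averaged over replicates.

    ``ct_table`` has columns sample, gene, replicate, ct.  For every
    (sample, gene, replicate) triple the ratio is formed against the
    reference gene's Ct of the same sample and replicate; output reports
    the mean and SD over replicates per (sample, gene).  Genes missing
    from ``efficiencies`` default to E = 1.
    """
    required = {"sample", "gene", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if reference_gene not in set(ct_table["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    eff = efficiencies or {}
    ref = ct_table[ct_table["gene"] == reference_gene].set_index(["sample", "replicate"])["ct"]
    rows = []
    targets = ct_table[ct_table["gene"] != reference_gene]
    for row in targets.itertuples(index=False):
        key = (row.sample, row.replicate)
        if key not in ref.index:
            raise ValueError(f"no reference Ct for sample={row.sample}, replicate={row.replicate}")
        ratio = relative_expression(
            row.ct, float(ref.loc[key]),
            eff.get(row.gene, 1.0), eff.get(reference_gene, 1.0),
        )
        rows.append((row.sample, row.gene, ratio))
    out = (
        pd.DataFrame(rows, columns=["sample", "gene", "relative_expression"])
        .groupby(["sample", "gene"], as_index=False)
        .agg(relative_expression=("relative_expression", "mean"),
             sd=("relative_expression", "std"))
    )
    return out


def read_ct_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
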