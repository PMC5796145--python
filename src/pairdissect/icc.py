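"""Agreement intraclass correlation from two-way ANOVA variance components.

For each gene, the two samples of every tumor pair form an n x 2 table
(patients x pair members).  A two-way crossed ANOVA decomposes its
variability into between-patient, member (within-patient) and residual
mean squares; method-of-moments variance estimates give the agreement
ICC

    ICC = sigma2_patients / (sigma2_patients + sigma2_members + sigma2_residual)

Components are deliberately NOT truncated at zero, so the ICC can be
negative — the convention of the single-rater absolute-agreement ICC,
ICC(A,1).  Genes with zero total variance within a group have an
undefined ICC and are flagged rather than assigned a value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, PairDesign

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Mean squares and method-of-moments variance estimates for one gene.

    ``sigma2_*`` estimates may be negative; ``k_members`` is fixed at 2
    (tumor pairs).
    """

    ms_patients: float
    ms_members: float
    ms_residual: float
    sigma2_patients: float
    sigma2_members: float
    sigma2_residual: float
    n_pairs: int
    k_members: int = 2


def anova_decompose(pairs_matrix: np.ndarray) -> VarianceComponents:
    """Two-way crossed ANOVA decomposition of an n x 2 pairs table.

    With grand mean g, patient (row) means r_i and member (column) means
    c_j over n patients and k = 2 members:

    * ``MS_patients = k * sum_i (r_i - g)^2 / (n - 1)``
    * ``MS_members  = n * sum_j (c_j - g)^2 / (k - 1)``
    * ``MS_residual = sum_ij (x_ij - r_i - c_j + g)^2 / ((n-1)(k-1))``

    and the variance estimates are ``(MS_patients - MS_residual)/k``,
    ``(MS_members - MS_residual)/n`` and ``MS_residual``.

    Raises
    ------
    ValueError
        If fewer than 2 pairs, a non n x 2 shape, or any NaN.
    """
    x = np.asarray(pairs_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError(f"expected an n x 2 array, got shape {x.shape}")
    if x.shape[0] < 2:
        raise ValueError("ICC requires at least 2 pairs")
    if np.isnan(x).any():
        raise ValueError("pairs matrix contains NaN")
    ms_p, ms_m, ms_r, s2_p, s2_m, s2_r = (
        float(a[0]) for a in _decompose_batch(x[None, :, :])
    )
    return VarianceComponents(
        ms_patients=ms_p,
        ms_members=ms_m,
        ms_residual=ms_r,
        sigma2_patients=s2_p,
        sigma2_members=s2_m,
        sigma2_residual=s2_r,
        n_pairs=x.shape[0],
    )


def _decompose_batch(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized decomposition over a (genes, n, 2) stack.

    Returns arrays (ms_p, ms_m, ms_r, s2_p, s2_m, s2_r), each length genes.
    """
    n = x.shape[1]
    k = x.shape[2]
    grand = x.mean(axis=(1, 2))
    row_means = x.mean(axis=2)  # (genes, n)
    col_means = x.mean(axis=1)  # (genes, k)
    ms_p = k * ((row_means - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
    ms_m = n * ((col_means - grand[:, None]) ** 2).sum(axis=1) / (k - 1)
    resid = (
        x
        - row_means[:, :, None]
        - col_means[:, None, :]
        + grand[:, None, None]
    )
    ms_r = (resid**2).sum(axis=(1, 2)) / ((n - 1) * (k - 1))
    s2_p = (ms_p - ms_r) / k
    s2_m = (ms_m - ms_r) / n
    return ms_p, ms_m, ms_r, s2_p, s2_m, ms_r


def icc_agreement(components: VarianceComponents) -> float:
    """Agreement ICC from variance components.

    ``sigma2_patients / (sigma2_patients + sigma2_members +
    sigma2_residual)``.  May be negative; equals 1 only when the member
    and residual components vanish with positive between-patient spread.

    Raises
    ------
    ZeroDivisionError
        If the denominator is (numerically) zero — a constant gene.
    """
    denom = (
        components.sigma2_patients
        + components.sigma2_members
        + components.sigma2_residual
    )
    scale = (
        components.ms_patients + components.ms_members + components.ms_residual
    )
    if denom == 0 or (scale > 0 and abs(denom) < 1e-12 * scale):
        raise ZeroDivisionError(
            "ICC undefined: total variance estimate is zero"
        )
    return components.sigma2_patients / denom


def icc_per_gene(
    matrix: ExpressionMatrix,
    design: PairDesign,
    group: str,
) -> pd.DataFrame:
    """Per-probe agreement ICC for one group's pairs.

    Returns a DataFrame with columns ``probe_id, symbol, group, icc,
    ms_patients, ms_members, ms_residual, sigma2_patients,
    sigma2_members, sigma2_residual``; probes whose ICC is undefined
    (zero total variance within the group) carry ``icc = NaN`` and are
    counted in the log.

    The batched computation is exactly the per-probe decomposition above,
    evaluated for all probes at once.
    """
    pairs = design.pairs_for_group(group)
    if len(pairs) < 2:
        raise ValueError(f"group {group!r} has < 2 pairs; ICC undefined")
    design.validate_against(matrix)

    m1 = matrix.values[pairs["member1_sample"].tolist()].to_numpy(dtype=float)
    m2 = matrix.values[pairs["member2_sample"].tolist()].to_numpy(dtype=float)
    x = np.stack([m1, m2], axis=2)  # (probes, n_pairs, 2)

    ms_p, ms_m, ms_r, s2_p, s2_m, s2_r = _decompose_batch(x)
    denom = s2_p + s2_m + s2_r
    scale = ms_p + ms_m + ms_r
    undefined = (denom == 0) | (np.abs(denom) < 1e-12 * np.maximum(scale, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(undefined, np.nan, s2_p / np.where(undefined, 1.0, denom))

    n_undef = int(undefined.sum())
    if n_undef:
        logger.info(
            "%d/%d probes with undefined ICC (zero total variance) in group %s",
            n_undef,
            len(icc),
            group,
        )

    symbols = (
        matrix.symbols.reindex(matrix.probe_ids)
        if matrix.symbols is not None
        else pd.Series("", index=matrix.probe_ids)
    )
    return pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "symbol": symbols.fillna("").to_numpy(),
            "group": group,
            "icc": icc,
            "ms_patients": ms_p,
            "ms_members": ms_m,
            "ms_residual": ms_r,
            "sigma2_patients": s2_p,
            "sigma2_members": s2_m,
            "sigma2_residual": s2_r,
        }
    ).reset_index(drop=True)


def write_icc_table(table: pd.DataFrame, path) -> None:
    """Write an ICC table as TSV (probe_id, symbol, group, icc, mean squares)."""
    cols = [
        "probe_id",
        "symbol",
        "group",
        "icc",
        "ms_patients",
        "ms_members",
        "ms_residual",
    ]
    table[cols].to_csv(path, sep="\t", index=False)
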