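"""Expression matrix I/O and the preprocessing stages.

Reading supports two dialects: a plain TSV (row 1 sample ids, column 1
probe ids) and the GEO series-matrix text format, whose data block sits
between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``
markers with metadata bang-lines around it.

Preprocessing stages mirror a bead-array workflow: a detection filter
(drop probes undetected in every sample), quantile normalization as the
between-sample normalization step, and an IQR filter retaining only the
most variable probes.  Per-pair variant-probe counting and bimodal
receptor-status calling round out the sample-level summaries.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, PairDesign, ReceptorCall


# -- reading / writing -------------------------------------------------------

def read_expression(
    path,
    dialect: str = "tsv",
    log2_transform: bool = False,
    missing: str = "reject",
) -> ExpressionMatrix:
    """Read a probes x samples expression matrix.

    Parameters
    ----------
    dialect
        ``"tsv"`` (plain tab-separated, header = sample ids, first column
        = probe ids) or ``"geo_series_matrix"`` (table between the
        ``!series_matrix_table_begin/end`` markers; bang-lines ignored).
    log2_transform
        Apply log2 to the values after reading (for matrices deposited on
        the linear scale).  Values are otherwise assumed log2 already.
    missing
        ``"reject"`` (default) errors on any missing cell; ``"drop"``
        removes probes with missing values.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "geo_series_matrix":
        df = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate probe ids in {path}: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample ids in {path}: {dups}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at probe {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        if missing == "reject":
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at probe {numeric.index[r]!r}, "
                f"sample {numeric.columns[c]!r} (policy: reject)"
            )
        elif missing == "drop":
            numeric = numeric.dropna(axis=0)
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    if log2_transform:
        if (numeric.to_numpy() <= 0).any():
            raise ValueError("log2 transform requires strictly positive values")
        numeric = np.log2(numeric)
    return ExpressionMatrix(values=numeric)


def _read_series_matrix(path) -> pd.DataFrame:
    """Parse the data block of a GEO series-matrix text file."""
    lines = Path(path).read_text().splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines)
            if l.strip().strip('"') == "!series_matrix_table_begin"
        )
        end = next(
            i for i, l in enumerate(lines)
            if l.strip().strip('"') == "!series_matrix_table_end"
        )
    except StopIteration:
        raise ValueError(
            f"{path}: no !series_matrix_table_begin/end markers found"
        ) from None
    block = [l for l in lines[start + 1 : end] if l.strip()]
    if len(block) < 2:
        raise ValueError(f"{path}: empty series-matrix table")

    def split(line: str) -> list[str]:
        return [f.strip().strip('"') for f in line.split("\t")]

    header = split(block[0])[1:]
    rows = [split(l) for l in block[1:]]
    index = [r[0] for r in rows]
    data = [r[1:] for r in rows]
    return pd.DataFrame(data, index=index, columns=header).replace(
        {"null": None, "NULL": None, "": None}
    )


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write values as the plain TSV dialect (round-trips with reading)."""
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")


def read_detection_p(matrix: ExpressionMatrix, path) -> ExpressionMatrix:
    """Attach a companion detection-p TSV (same shape as the values)."""
    p = pd.read_csv(path, sep="\t", index_col=0)
    p.index = p.index.astype(str)
    p.columns = p.columns.astype(str)
    if p.shape != matrix.values.shape:
        raise ValueError(
            f"detection-p shape {p.shape} != values shape {matrix.values.shape}"
        )
    p = p.loc[matrix.probe_ids, matrix.sample_ids]
    return ExpressionMatrix(
        values=matrix.values, symbols=matrix.symbols, detection_p=p
    )


def read_annotation(path, symbol_column: str = "symbol") -> pd.Series:
    """Read a probe -> gene-symbol table (first column probe ids)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if symbol_column not in table.columns:
        raise ValueError(
            f"annotation file lacks a {symbol_column!r} column; "
            f"has {list(table.columns)}"
        )
    sym = table[symbol_column].astype(str)
    sym.index = sym.index.astype(str)
    return sym


def read_design(path) -> PairDesign:
    """Read a pair-design TSV: patient_id, group, member1_sample, member2_sample."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return PairDesign(table=table)


def write_design(design: PairDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# -- preprocessing stages ----------------------------------------------------

def detection_filter(
    matrix: ExpressionMatrix, alpha: float = 0.01
) -> ExpressionMatrix:
    """Drop probes undetected in every sample.

    A probe is retained iff its detection p-value is <= ``alpha`` in at
    least one sample; probe order is preserved.  Requires detection
    p-values.
    """
    if matrix.detection_p is None:
        raise ValueError(
            "matrix has no detection p-values; skip the detection filter "
            "explicitly if the deposited data are already filtered"
        )
    detected = (matrix.detection_p.to_numpy() <= alpha).any(axis=1)
    return matrix.subset_probes(matrix.probe_ids[detected])


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean sorted profile (ties averaged).

    Stand-in for platform-specific spline normalization: after the
    transform each sample's sorted values equal the across-sample mean of
    sorted values; a sample's ranks are untouched, so any within-sample
    monotone distortion is removed.
    """
    x = matrix.values.to_numpy(dtype=float)
    n_probes, n_samples = x.shape
    if n_samples < 2:
        warnings.warn("quantile normalization with a single sample is a no-op")
        return matrix
    mean_profile = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n_probes + 1, dtype=float)
    for j in range(n_samples):
        ranks = rankdata(x[:, j], method="average")
        # fractional (tied) ranks interpolate between adjacent profile values
        out[:, j] = np.interp(ranks, positions, mean_profile)
    return ExpressionMatrix(
        values=pd.DataFrame(
            out, index=matrix.probe_ids, columns=matrix.sample_ids
        ),
        symbols=matrix.symbols,
        detection_p=matrix.detection_p,
    )


def iqr_filter(matrix: ExpressionMatrix, threshold: float = 0.5) -> ExpressionMatrix:
    """Keep the most variable probes: IQR across samples > ``threshold``.

    Quartiles use linear interpolation between order statistics (the R
    ``quantile`` type-7 default).  Probe order is preserved; an empty
    result is a valid (empty) matrix.
    """
    if matrix.n_samples < 4:
        warnings.warn(
            f"IQR over {matrix.n_samples} samples is unstable; "
            "4 or more samples recommended"
        )
    x = matrix.values.to_numpy(dtype=float)
    q75, q25 = np.percentile(x, [75, 25], axis=1)  # linear interpolation
    keep = (q75 - q25) > threshold
    return matrix.subset_probes(matrix.probe_ids[keep])


def count_variant_probes(
    matrix: ExpressionMatrix,
    pair: Sequence[str],
    fc_threshold: float = 2.0,
) -> int:
    """Count probes differing more than ``fc_threshold``-fold within a pair.

    Values are log2, so a fold change > fc or < 1/fc corresponds to
    ``|x_member1 - x_member2| > log2(fc_threshold)``; the count is
    symmetric in member order and invariant to shifting both members.
    """
    member1, member2 = pair
    for s in (member1, member2):
        if s not in matrix.values.columns:
            raise KeyError(f"sample {s!r} not in matrix")
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    diff = matrix.values[member1].to_numpy() - matrix.values[member2].to_numpy()
    return int((np.abs(diff) > np.log2(fc_threshold)).sum())


# -- receptor-status calling -------------------------------------------------

def call_receptor_status(
    matrix: ExpressionMatrix,
    probe_id: str,
    marker: str = "ER",
    min_separation: float = 1.0,
    min_weight: float = 0.1,
    seed: int = 0,
) -> list[ReceptorCall]:
    """Call positive/negative status from a bimodal expression split.

    Fits a two-component univariate Gaussian mixture to the probe's
    values across samples; the threshold is the point between the two
    component means where posterior membership is 0.5.  Samples above the
    threshold are positive.  If the fit is not convincingly bimodal
    (component means closer than ``min_separation`` log2 units, or either
    weight below ``min_weight``), every call is "indeterminate".
    """
    from sklearn.mixture import GaussianMixture

    if probe_id not in matrix.values.index:
        raise KeyError(f"probe {probe_id!r} not in matrix")
    values = matrix.values.loc[probe_id].to_numpy(dtype=float)
    samples = list(matrix.sample_ids)
    if len(values) < 6:
        raise ValueError("receptor calling needs at least 6 samples")

    gm = GaussianMixture(n_components=2, n_init=5, random_state=seed)
    gm.fit(values[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)

    bimodal = (
        abs(means[hi] - means[lo]) >= min_separation
        and weights.min() >= min_weight
    )
    if not bimodal:
        return [
            ReceptorCall(sample_id=s, marker=marker, status="indeterminate")
            for s in samples
        ]

    threshold = _posterior_crossing(
        means[lo], sds[lo], weights[lo], means[hi], sds[hi], weights[hi]
    )
    return [
        ReceptorCall(
            sample_id=s,
            marker=marker,
            status="positive" if v > threshold else "negative",
            threshold=float(threshold),
            confidence=float(abs(v - threshold)),
        )
        for s, v in zip(samples, values)
    ]


def _posterior_crossing(
    m1: float, s1: float, w1: float, m2: float, s2: float, w2: float
) -> float:
    """Value between the two component means with equal posterior density.

    Solves ``w1 N(x|m1,s1) = w2 N(x|m2,s2)`` — a quadratic in x — and
    returns the root inside (m1, m2); falls back to the midpoint if the
    fitted variances make both roots fall outside.
    """
    # quadratic a x^2 + b x + c = 0 from equating log component densities
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        m2**2 / (2 * s2**2)
        - m1**2 / (2 * s1**2)
        + np.log(w1 * s2)
        - np.log(w2 * s1)
    )
    if abs(a) < 1e-12:  # equal variances: linear crossing
        if abs(b) < 1e-12:
            return 0.5 * (m1 + m2)
        return -c / b
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > min(m1, m2)) & (roots < max(m1, m2))]
    if inside.size:
        return float(inside[0])
    return 0.5 * (m1 + m2)


def write_receptor_calls(calls: list[ReceptorCall], path) -> None:
    """Write calls as TSV: sample_id, marker, status, threshold."""
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "marker": c.marker,
                "status": c.status,
                "threshold": c.threshold,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
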