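"""Core in-memory containers: expression matrices and pair designs.

An :class:`ExpressionMatrix` holds log2-scale expression values as a
probes x samples :class:`pandas.DataFrame`, with optional probe -> gene
symbol annotation and an optional detection p-value matrix of identical
shape.  A :class:`PairDesign` maps each patient to the two samples of a
tumor pair plus a group label (SBC, MBC or LRC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

GROUPS = ("SBC", "MBC", "LRC")
"""Canonical group labels: synchronous bilateral, metachronous bilateral,
and locally recurrent tumor pairs."""


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 expression with optional annotation.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns sample ids, log2 scale.
    symbols
        Optional Series mapping probe id -> gene symbol.  Probes without
        a symbol may be absent or hold an empty string / NaN.
    detection_p
        Optional DataFrame of per-probe per-sample detection p-values,
        same index/columns as ``values``.
    """

    values: pd.DataFrame
    symbols: Optional[pd.Series] = None
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate probe ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate sample ids: {dups}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite after ingest")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError(
                    "detection_p shape does not match values: "
                    f"{self.detection_p.shape} vs {self.values.shape}"
                )
            self.detection_p = self.detection_p.reindex(
                index=idx, columns=cols
            )
        if self.symbols is not None:
            self.symbols = self.symbols.reindex(idx)

    # -- basic accessors -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids: Iterable) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``probe_ids`` (order kept)."""
        ids = pd.Index(probe_ids)
        return ExpressionMatrix(
            values=self.values.loc[ids],
            symbols=None if self.symbols is None else self.symbols.loc[ids],
            detection_p=(
                None if self.detection_p is None else self.detection_p.loc[ids]
            ),
        )

    def subset_samples(self, sample_ids: Iterable) -> "ExpressionMatrix":
        ids = pd.Index(sample_ids)
        return ExpressionMatrix(
            values=self.values[ids],
            symbols=self.symbols,
            detection_p=(
                None if self.detection_p is None else self.detection_p[ids]
            ),
        )

    def with_symbols(self, symbols: pd.Series) -> "ExpressionMatrix":
        """Attach a probe -> symbol annotation (reindexed to the probes)."""
        return replace(self, symbols=symbols.reindex(self.values.index))


@dataclass
class PairDesign:
    """Patient -> (member1, member2, group) map over tumor pairs.

    Member-order convention (recorded in ``member_convention``): for SBC
    member1/member2 follow the recorded right/left order; for MBC and LRC
    member1 is the earlier lesion (primary).  The agreement ICC keeps a
    member effect in the model, so the convention is fixed but the
    estimate itself is symmetric in expectation.
    """

    table: pd.DataFrame
    member_convention: str = (
        "SBC: member1=right, member2=left; MBC/LRC: member1=earlier lesion"
    )

    REQUIRED = ("patient_id", "group", "member1_sample", "member2_sample")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        samples = pd.concat(
            [self.table["member1_sample"], self.table["member2_sample"]]
        )
        if samples.duplicated().any():
            dups = samples[samples.duplicated()].unique().tolist()[:5]
            raise ValueError(f"sample appears in more than one pair: {dups}")
        if self.table["patient_id"].duplicated().any():
            raise ValueError("duplicate patient ids in design")

    @property
    def groups(self) -> list[str]:
        present = set(self.table["group"])
        return [g for g in GROUPS if g in present]

    def n_pairs(self, group: str) -> int:
        return int((self.table["group"] == group).sum())

    def pairs_for_group(self, group: str) -> pd.DataFrame:
        """Rows of the design table for one group, in table order."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise ValueError(f"group {group!r} has no pairs in the design")
        return sub.reset_index(drop=True)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Raise if any design sample is absent from the matrix."""
        have = set(matrix.sample_ids)
        want = set(self.table["member1_sample"]) | set(
            self.table["member2_sample"]
        )
        missing = sorted(want - have)
        if missing:
            raise ValueError(f"design samples absent from matrix: {missing[:5]}")


@dataclass
class ReceptorCall:
    """Marker status for one sample, from a bimodal expression split."""

    sample_id: str
    marker: str
    status: str  # "positive" | "negative" | "indeterminate"
    threshold: float = field(default=np.nan)
    confidence: float = field(default=np.nan)  # |value - threshold|
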