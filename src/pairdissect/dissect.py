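"""End-to-end dissection of intra-pair expression variability.

The pipeline computes per-gene agreement ICC separately for each pair
group (SBC, MBC, LRC) on several probe panels and compares the resulting
ICC distributions:

* ``unselected_IQR`` — all detected probes passing the IQR variability
  filter (biologically unselected, most variable genes);
* one panel per gene signature (intrinsic/PAM50-style, stromal-style) —
  mapped by symbol, not IQR-filtered.

Group-level comparison uses a one-way ANOVA across the three groups'
per-gene ICC values plus pairwise Welch t-tests, together with median
ICC, the count of probes above an ICC cutoff, and per-pair variant-probe
counts.  ICC values of different genes are correlated, so these p-values
order the panels rather than calibrate error rates; that caveat is
inherent to treating genes as observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as eio
from .icc import icc_per_gene, write_icc_table
from .matrix import ExpressionMatrix, PairDesign
from .signatures import GeneSignature, map_symbols_to_probes

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """Summary of one probe panel's per-group ICC distributions."""

    panel: str
    n_probes: int
    median_icc: dict[str, float]
    n_above_cutoff: dict[str, int]
    icc_cutoff: float
    anova_f: float
    anova_p: float
    pairwise_p: dict[str, float]
    variant_counts: dict[str, list[int]] = field(default_factory=dict)
    median_variant_count: dict[str, float] = field(default_factory=dict)
    n_undefined: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "n_probes": self.n_probes,
            "median_icc": self.median_icc,
            "n_above_cutoff": self.n_above_cutoff,
            "icc_cutoff": self.icc_cutoff,
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
            "pairwise_p": self.pairwise_p,
            "median_variant_count": self.median_variant_count,
            "n_undefined": self.n_undefined,
        }


@dataclass
class DissectionConfig:
    """Thresholds and switches for the full pipeline."""

    detection_alpha: Optional[float] = 0.01  # None skips the stage
    normalize: str = "none"  # "none" | "quantile"
    iqr_threshold: float = 0.5
    icc_cutoff: float = 0.5
    fc_threshold: float = 2.0
    variant_on_full: bool = False  # count variants on all detected probes
    iqr_filter_signatures: bool = False
    collapse_genes: str = "none"  # "none" | "max-iqr"
    t_test: str = "welch"  # "welch" | "student"


@dataclass
class DissectionReport:
    """All panel comparisons plus per-panel ICC tables and run metadata."""

    panels: dict[str, GroupComparison]
    icc_tables: dict[str, pd.DataFrame]
    metadata: dict

    def summary_dict(self) -> dict:
        return {
            "panels": {k: v.to_dict() for k, v in self.panels.items()},
            "metadata": self.metadata,
        }

    def write(self, out_dir) -> dict[str, str]:
        """Emit JSON summary + per-panel ICC TSVs; return written paths."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"summary": str(out / "summary.json")}
        with open(paths["summary"], "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, default=float)
        for panel, table in self.icc_tables.items():
            p = str(out / f"icc_{panel}.tsv")
            write_icc_table(table, p)
            paths[f"icc_{panel}"] = p
        return paths


def compare_groups(
    icc_tables: Mapping[str, pd.DataFrame],
    cutoff: float = 0.5,
    panel: str = "",
    t_test: str = "welch",
) -> GroupComparison:
    """Compare per-gene ICC distributions across groups.

    ``icc_tables`` maps group label -> per-gene ICC table (as produced by
    :func:`pairdissect.icc.icc_per_gene`).  Undefined (NaN) ICCs are
    excluded from medians, counts and tests; a group with no defined ICC
    at all is an error.
    """
    if len(icc_tables) < 2:
        raise ValueError("need at least 2 groups to compare")
    values: dict[str, np.ndarray] = {}
    n_undefined: dict[str, int] = {}
    for group, table in icc_tables.items():
        icc = table["icc"].to_numpy(dtype=float)
        defined = icc[~np.isnan(icc)]
        n_undefined[group] = int(np.isnan(icc).sum())
        if defined.size < 2:
            raise ValueError(
                f"group {group!r} has fewer than 2 defined ICC values"
            )
        values[group] = defined

    f_stat, anova_p = stats.f_oneway(*values.values())
    if f_stat < 0 and f_stat > -1e-12:  # cancellation noise on equal groups
        f_stat, anova_p = 0.0, 1.0
    equal_var = t_test == "student"
    pairwise = {
        f"{a}_vs_{b}": float(
            stats.ttest_ind(values[a], values[b], equal_var=equal_var).pvalue
        )
        for a, b in combinations(values, 2)
    }
    return GroupComparison(
        panel=panel,
        n_probes=max(len(t) for t in icc_tables.values()),
        median_icc={g: float(np.median(v)) for g, v in values.items()},
        n_above_cutoff={g: int((v > cutoff).sum()) for g, v in values.items()},
        icc_cutoff=cutoff,
        anova_f=float(f_stat),
        anova_p=float(anova_p),
        pairwise_p=pairwise,
        n_undefined=n_undefined,
    )


def _collapse_max_iqr(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep, per gene symbol, the probe with the largest IQR."""
    if matrix.symbols is None:
        raise ValueError("gene collapsing requires symbol annotations")
    x = matrix.values.to_numpy(dtype=float)
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    iqr = pd.Series(q75 - q25, index=matrix.probe_ids)
    sym = matrix.symbols.fillna("")
    keep = []
    for _symbol, probes in iqr.groupby(sym.to_numpy(), sort=False):
        keep.append(probes.idxmax())
    return matrix.subset_probes(keep)


def run_dissection(
    matrix: ExpressionMatrix,
    design: PairDesign,
    signatures: Sequence[GeneSignature] = (),
    config: Optional[DissectionConfig] = None,
) -> DissectionReport:
    """Full pipeline: preprocessing, per-panel per-group ICC, comparisons.

    Stages: detection filter (if p-values present and enabled) ->
    optional quantile normalization -> IQR filter for the unselected
    panel.  Signature panels are mapped on the detected (pre-IQR) matrix
    and bypass the IQR filter unless ``iqr_filter_signatures`` is set.
    Deterministic given inputs and thresholds.
    """
    cfg = config or DissectionConfig()
    design.validate_against(matrix)
    stage_log: dict[str, int] = {"input_probes": matrix.n_probes}

    work = matrix
    if cfg.detection_alpha is not None and work.detection_p is not None:
        work = eio.detection_filter(work, alpha=cfg.detection_alpha)
    stage_log["detected_probes"] = work.n_probes
    if cfg.normalize == "quantile":
        work = eio.quantile_normalize(work)
    elif cfg.normalize != "none":
        raise ValueError(f"unknown normalization {cfg.normalize!r}")
    if cfg.collapse_genes == "max-iqr":
        work = _collapse_max_iqr(work)
        stage_log["collapsed_probes"] = work.n_probes
    elif cfg.collapse_genes != "none":
        raise ValueError(f"unknown collapse mode {cfg.collapse_genes!r}")

    unselected = eio.iqr_filter(work, threshold=cfg.iqr_threshold)
    stage_log["unselected_IQR_probes"] = unselected.n_probes

    panel_matrices: dict[str, ExpressionMatrix] = {"unselected_IQR": unselected}
    signature_counts: dict[str, dict] = {}
    for sig in signatures:
        mapping = map_symbols_to_probes(sig, work)
        panel = work.subset_probes(mapping.probe_ids)
        if cfg.iqr_filter_signatures:
            panel = eio.iqr_filter(panel, threshold=cfg.iqr_threshold)
        panel_matrices[sig.name] = panel
        signature_counts[sig.name] = {
            "n_symbols_input": mapping.n_symbols_input,
            "n_symbols_matched": mapping.n_symbols_matched,
            "n_probes": mapping.n_probes,
        }
        stage_log[f"{sig.name}_probes"] = panel.n_probes

    groups = design.groups
    panels: dict[str, GroupComparison] = {}
    icc_tables: dict[str, pd.DataFrame] = {}
    for panel_name, panel_matrix in panel_matrices.items():
        if panel_matrix.n_probes == 0:
            logger.warning("panel %s is empty; skipped", panel_name)
            continue
        tables = {
            g: icc_per_gene(panel_matrix, design, g) for g in groups
        }
        comparison = compare_groups(
            tables, cutoff=cfg.icc_cutoff, panel=panel_name, t_test=cfg.t_test
        )
        variant_matrix = work if cfg.variant_on_full else panel_matrix
        counts: dict[str, list[int]] = {}
        for g in groups:
            pairs = design.pairs_for_group(g)
            counts[g] = [
                eio.count_variant_probes(
                    variant_matrix,
                    (row.member1_sample, row.member2_sample),
                    fc_threshold=cfg.fc_threshold,
                )
                for row in pairs.itertuples()
            ]
        comparison.variant_counts = counts
        comparison.median_variant_count = {
            g: float(np.median(c)) for g, c in counts.items()
        }
        panels[panel_name] = comparison
        icc_tables[panel_name] = pd.concat(tables.values(), ignore_index=True)

    from . import __version__

    metadata = {
        "version": __version__,
        "groups": groups,
        "n_pairs": {g: design.n_pairs(g) for g in groups},
        "thresholds": {
            "detection_alpha": cfg.detection_alpha,
            "iqr_threshold": cfg.iqr_threshold,
            "icc_cutoff": cfg.icc_cutoff,
            "fc_threshold": cfg.fc_threshold,
        },
        "normalize": cfg.normalize,
        "collapse_genes": cfg.collapse_genes,
        "t_test": cfg.t_test,
        "stage_probe_counts": stage_log,
        "signature_counts": signature_counts,
    }
    return DissectionReport(panels=panels, icc_tables=icc_tables, metadata=metadata)
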