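"""Synthetic paired-tumor cohorts under a variance-component model.

Each gene's log2 expression in pair i, member j of group gamma is

    x_gij = mu_g + h_gi + g_gi[j] + t_gi[j] + eps_gij

with four independent normal sources:

* ``h`` — host/patient effect, variance ``var_host``; always shared by
  the two members of a pair (same woman).
* ``g`` — tumor genetic background, variance ``var_genetic``; shared
  within a pair only for local recurrences (LRC, same clonal origin),
  independent per member in bilateral pairs (SBC, MBC — distinct
  primaries).
* ``t`` — time / microenvironment effect, variance ``var_time``; shared
  within a pair only for synchronous bilateral tumors (SBC, diagnosed
  together), independent per member when a time interval separates the
  two lesions (MBC, LRC).
* ``eps`` — technical noise, variance ``var_noise``, iid.

The population agreement ICC of such a gene is the shared variance over
the total:

    ICC = (var_host + var_genetic*[genetic shared] + var_time*[time shared])
          / (var_host + var_genetic + var_time + var_noise)

Gene classes model biologically distinct sets: "intrinsic-like" genes
(tumor-genotype driven, var_time = 0) and "stromal-like" genes
(host/microenvironment driven, var_genetic = 0) alongside a generic
background class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .matrix import GROUPS, ExpressionMatrix, PairDesign

#: Which variance sources are shared within a pair, per group:
#: (genetic_shared, time_shared).
SHARING: dict[str, tuple[bool, bool]] = {
    "LRC": (True, False),
    "SBC": (False, True),
    "MBC": (False, False),
}

#: Cohort sizes of the bilateral/recurrence case series this model emulates.
DEFAULT_N_PAIRS: dict[str, int] = {"SBC": 18, "MBC": 11, "LRC": 10}


@dataclass
class GeneClassParams:
    """Variance components for one gene class.

    Variances are in squared log2 units.  ``mean_range`` is the uniform
    range baseline expression mu_g is drawn from (log2 units); the wide
    default gives a realistic array dynamic range so that IQR filtering
    is exercisable, while ICC itself is location-invariant.
    ``undetected`` marks the class's genes as below detection: their
    detection p-value is set to 0.5 in every sample (detected genes get
    0), a deliberately simple rule sufficient to exercise the detection
    filter.
    """

    name: str
    var_host: float = 0.1
    var_genetic: float = 0.5
    var_time: float = 0.3
    var_noise: float = 0.2
    n_genes: int = 2000
    mean_range: tuple[float, float] = (6.0, 12.0)
    undetected: bool = False
    noise_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None
    """Optional hook drawing ``size`` unit-variance noise deviates from a
    heavier-tailed law (robustness checks only); scaled by sqrt(var_noise)."""

    def __post_init__(self) -> None:
        for attr in ("var_host", "var_genetic", "var_time", "var_noise"):
            v = getattr(self, attr)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{attr} must be finite and >= 0, got {v}")
        if self.var_noise <= 0:
            raise ValueError("var_noise must be strictly positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.mean_range[1] < self.mean_range[0]:
            raise ValueError("mean_range must be (low, high) with low <= high")

    @property
    def total_variance(self) -> float:
        return self.var_host + self.var_genetic + self.var_time + self.var_noise


@dataclass
class SimulationConfig:
    """Cohort configuration: gene classes, pair counts per group, seed."""

    gene_classes: list[GeneClassParams]
    n_pairs: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PAIRS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gene_classes:
            raise ValueError("at least one gene class is required")
        names = [c.name for c in self.gene_classes]
        if len(set(names)) != len(names):
            raise ValueError("gene class names must be unique")
        for group in self.n_pairs:
            if group not in SHARING:
                raise ValueError(
                    f"unknown group {group!r}; expected one of {sorted(SHARING)}"
                )
        for group, n in self.n_pairs.items():
            if n < 2:
                raise ValueError(
                    f"group {group!r} has n_pairs={n}; ICC needs >= 2 pairs"
                )

    @property
    def groups(self) -> list[str]:
        return [g for g in GROUPS if g in self.n_pairs]


@dataclass
class SimulatedCohort:
    """A simulated cohort: expression matrix, pair design, per-gene truth.

    ``truth`` has one row per gene: probe_id, symbol, gene_class and the
    population ICC for each group.
    """

    matrix: ExpressionMatrix
    design: PairDesign
    truth: pd.DataFrame
    config: SimulationConfig


def population_icc(
    params: GeneClassParams, genetic_shared: bool, time_shared: bool
) -> float:
    """Closed-form population agreement ICC under the generative model.

    Shared variance over total variance:
    ``(var_host + var_genetic*genetic_shared + var_time*time_shared) /
    (var_host + var_genetic + var_time + var_noise)``.
    """
    total = params.total_variance
    if total <= 0:
        raise ValueError("total variance must be positive")
    shared = params.var_host
    if genetic_shared:
        shared += params.var_genetic
    if time_shared:
        shared += params.var_time
    return shared / total


def population_icc_group(params: GeneClassParams, group: str) -> float:
    """Population ICC for a named group's sharing structure."""
    if group not in SHARING:
        raise ValueError(f"unknown group {group!r}")
    return population_icc(params, *SHARING[group])


def default_config(seed: int = 0) -> SimulationConfig:
    """The default three-class cohort.

    A generic background class carries all four variance sources; the
    intrinsic-like class has no time variance (genotype-driven genes);
    the stromal-like class has no genetic variance (host-driven genes).
    Variance sizes are illustrative — the relative weight of genetic vs.
    time variability in real tumors is not quantified — but ordered so
    that genetic variability exceeds time variability for unselected
    genes, matching the observed group ranking.
    """
    return SimulationConfig(
        gene_classes=[
            GeneClassParams(
                name="background",
                var_host=0.1,
                var_genetic=0.5,
                var_time=0.3,
                var_noise=0.2,
                n_genes=2000,
            ),
            GeneClassParams(
                name="intrinsic-like",
                var_host=0.1,
                var_genetic=0.5,
                var_time=0.0,
                var_noise=0.2,
                n_genes=2000,
            ),
            GeneClassParams(
                name="stromal-like",
                var_host=0.1,
                var_genetic=0.0,
                var_time=0.3,
                var_noise=0.2,
                n_genes=2000,
            ),
        ],
        seed=seed,
    )


def _sample_ids(group: str, n_pairs: int) -> tuple[list[str], list[str], list[str]]:
    patients = [f"{group}_p{i + 1:03d}" for i in range(n_pairs)]
    member1 = [f"{p}_a" for p in patients]
    member2 = [f"{p}_b" for p in patients]
    return patients, member1, member2


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a cohort from the variance-component model.

    Reproducibility: each gene uses its own random substream, derived as
    ``SeedSequence(config.seed, spawn_key=(gene_index,))`` with genes
    indexed in class order — so gene 17 gets the same values whether the
    cohort has 100 or 10,000 genes, and identical configs give bitwise
    identical cohorts.  Within a gene's stream the draw order is fixed:
    mu_g, then for each group (SBC, MBC, LRC order) host, genetic, time,
    noise terms.
    """
    groups = config.groups
    columns: list[str] = []
    design_rows: list[dict] = []
    for group in groups:
        patients, m1, m2 = _sample_ids(group, config.n_pairs[group])
        for p, a, b in zip(patients, m1, m2):
            design_rows.append(
                {
                    "patient_id": p,
                    "group": group,
                    "member1_sample": a,
                    "member2_sample": b,
                }
            )
            columns.extend([a, b])

    n_genes_total = sum(c.n_genes for c in config.gene_classes)
    values = np.empty((n_genes_total, len(columns)))
    detection = np.zeros_like(values)

    probe_ids: list[str] = []
    gene_classes: list[str] = []
    gene_index = 0
    for cls in config.gene_classes:
        for _ in range(cls.n_genes):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(gene_index,))
            )
            mu = rng.uniform(*cls.mean_range)
            row = np.empty(len(columns))
            offset = 0
            for group in groups:
                n = config.n_pairs[group]
                genetic_shared, time_shared = SHARING[group]
                host = rng.normal(0.0, np.sqrt(cls.var_host), size=n)
                genetic = _pair_term(
                    rng, cls.var_genetic, n, shared=genetic_shared
                )
                time_term = _pair_term(rng, cls.var_time, n, shared=time_shared)
                if cls.noise_sampler is not None:
                    eps = cls.noise_sampler(rng, 2 * n).reshape(n, 2) * np.sqrt(
                        cls.var_noise
                    )
                else:
                    eps = rng.normal(0.0, np.sqrt(cls.var_noise), size=(n, 2))
                block = mu + host[:, None] + genetic + time_term + eps
                row[offset : offset + 2 * n] = block.reshape(-1)
                offset += 2 * n
            values[gene_index] = row
            if cls.undetected:
                detection[gene_index] = 0.5
            probe_ids.append(f"probe_{gene_index + 1:05d}")
            gene_classes.append(cls.name)
            gene_index += 1

    symbols = pd.Series(
        [f"SIM{i + 1:05d}" for i in range(n_genes_total)],
        index=pd.Index(probe_ids, name="probe_id"),
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=columns),
        symbols=symbols,
        detection_p=pd.DataFrame(detection, index=probe_ids, columns=columns),
    )
    design = PairDesign(table=pd.DataFrame(design_rows))

    by_name = {c.name: c for c in config.gene_classes}
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "symbol": symbols.to_numpy(),
            "gene_class": gene_classes,
        }
    )
    for group in groups:
        truth[f"pop_icc_{group}"] = [
            population_icc_group(by_name[c], group) for c in gene_classes
        ]
    return SimulatedCohort(matrix=matrix, design=design, truth=truth, config=config)


def _pair_term(
    rng: np.random.Generator, variance: float, n_pairs: int, shared: bool
) -> np.ndarray:
    """Draw a (n_pairs, 2) component, shared or independent within pairs.

    A draw is consumed even when variance = 0, keeping the stream layout
    identical across gene classes.
    """
    sd = np.sqrt(variance)
    if shared:
        per_pair = rng.normal(0.0, sd, size=n_pairs)
        return np.repeat(per_pair[:, None], 2, axis=1)
    return rng.normal(0.0, sd, size=(n_pairs, 2))


def class_signature(cohort: SimulatedCohort, class_name: str):
    """Gene signature of all symbols in one simulated gene class."""
    from .signatures import GeneSignature

    symbols = cohort.truth.loc[
        cohort.truth["gene_class"] == class_name, "symbol"
    ]
    if symbols.empty:
        raise ValueError(f"no genes of class {class_name!r} in cohort")
    return GeneSignature(
        name=class_name,
        symbols=frozenset(s.casefold() for s in symbols),
        source="simulated gene class",
    )


# -- config (de)serialization ------------------------------------------------

def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML (or JSON) key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    classes = [
        GeneClassParams(
            name=c["name"],
            var_host=float(c.get("var_host", 0.1)),
            var_genetic=float(c.get("var_genetic", 0.5)),
            var_time=float(c.get("var_time", 0.3)),
            var_noise=float(c.get("var_noise", 0.2)),
            n_genes=int(c.get("n_genes", 2000)),
            mean_range=tuple(c.get("mean_range", (6.0, 12.0))),
            undetected=bool(c.get("undetected", False)),
        )
        for c in raw["gene_classes"]
    ]
    return SimulationConfig(
        gene_classes=classes,
        n_pairs={str(k): int(v) for k, v in raw.get(
            "n_pairs", DEFAULT_N_PAIRS
        ).items()},
        seed=int(raw.get("seed", 0)),
    )


def save_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write matrix, design and truth tables as TSV; return the paths."""
    from pathlib import Path

    from .io import write_design, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "detection_p": str(out / "detection_p.tsv"),
        "design": str(out / "design.tsv"),
        "truth": str(out / "truth.tsv"),
        "annotation": str(out / "annotation.tsv"),
    }
    write_expression(cohort.matrix, paths["expression"])
    if cohort.matrix.detection_p is not None:
        cohort.matrix.detection_p.to_csv(paths["detection_p"], sep="\t")
    write_design(cohort.design, paths["design"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    cohort.matrix.symbols.rename("symbol").to_csv(paths["annotation"], sep="\t")
    return paths
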