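"""Seeded generators for the two data shapes the curation pipeline consumes.

``simulate_timecourse`` emulates a partially synchronized fibroblast-style
time course after serum refeeding: modules of genes with G0- (decay from
quiescence), G1- (early bump), S- (late logistic rise that falls off as
cells pass into G2-M) and G2-M-shaped (later rise) profiles, plus flat
housekeeping genes, measured in two batches with additive offsets and
Gaussian log2 noise.

``simulate_atlas`` emulates a promoter-level expression atlas across many
primary cell types: cell-cycle promoters track each cell type's
proliferation index, while lineage promoters are high only in their own
lineage.  A configurable fraction of cell-cycle genes additionally carries a
lineage-driven alternative promoter, the pattern the refinement stage is
designed to detect.

Both generators carry their ground truth (module / promoter-class labels)
so recovery can be scored exactly, and are bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from cyclecurate.preprocess import ExpressionMatrix

__all__ = [
    "TimecourseConfig",
    "SyntheticTimecourse",
    "AtlasConfig",
    "CellType",
    "SyntheticAtlas",
    "simulate_timecourse",
    "simulate_atlas",
    "simulate_study",
    "MODULE_LABELS",
    "DEFAULT_MARKERS",
]

MODULE_LABELS = ("G0", "G1", "S", "G2M", "flat")

#: Phase-diagnostic genes planted into the S and G2M modules so that the
#: default marker panel resolves on synthetic data.
DEFAULT_MARKERS = {"S": ("CDC25A", "BRCA1"), "G2M": ("CDK1", "CCNB1")}


def _default_peak_params() -> dict[str, dict[str, float]]:
    return {
        "G0": {"tau": 4.0, "amplitude": 2.5},
        "G1": {"peak": 6.0, "width": 2.5, "amplitude": 2.5},
        "S": {"peak": 18.0, "width": 1.5, "decay": 1 / 6, "amplitude": 2.5},
        "G2M": {"peak": 21.0, "width": 1.5, "decay": 1 / 24, "amplitude": 2.5},
    }


@dataclass
class TimecourseConfig:
    """Parameters of the synchronized time-course generator.

    Defaults encode a 0-24 h course sampled every 2 h in two batches:
    G0 genes decay from quiescence (time constant 4 h), G1 genes peak near
    6 h post-refeeding, S genes rise sigmoidally centred at 18 h and decline
    afterwards, G2-M genes rise centred at 21 h, and flat genes stay at
    baseline.  Amplitudes are in log2 units around a lognormal mean of 2.5;
    measurement noise is additive Gaussian on the log2 scale.
    """

    genes_per_module: dict[str, int] = field(
        default_factory=lambda: {"G0": 60, "G1": 60, "S": 50, "G2M": 50, "flat": 40}
    )
    time_grid: Sequence[float] = field(
        default_factory=lambda: tuple(float(t) for t in range(0, 25, 2))
    )
    peak_params: dict[str, dict[str, float]] = field(default_factory=_default_peak_params)
    noise_sd: float = 0.25
    batch_offsets: dict[str, float] = field(
        default_factory=lambda: {"b1": 0.0, "b2": 0.6}
    )
    baseline: float = 7.0
    amplitude_sigma: float = 0.2
    #: SD of the gene-specific component of each batch offset (batch effects
    #: on arrays are gene-specific, which is what location adjustment
    #: removes).  None tracks ``noise_sd``, so noise-free runs stay exact.
    batch_gene_sd: float | None = None
    #: Optional loss-of-synchrony half-life (h); profiles are damped toward
    #: baseline as 0.5**(t/half-life).  None disables damping.
    desync_halflife: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for module, n in self.genes_per_module.items():
            if module not in MODULE_LABELS:
                raise ValueError(f"unknown module label {module!r}")
            if n < 0:
                raise ValueError(f"negative gene count for module {module!r}")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("time grid is empty")
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise ValueError("time grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.batch_offsets:
            raise ValueError("at least one batch is required")
        if self.desync_halflife is not None and self.desync_halflife <= 0:
            raise ValueError("desync_halflife must be positive")
        if self.batch_gene_sd is not None and self.batch_gene_sd < 0:
            raise ValueError("batch_gene_sd must be >= 0")


@dataclass
class SyntheticTimecourse:
    """A generated time course with its ground-truth module labels."""

    matrix: ExpressionMatrix
    truth: pd.Series  # feature id -> module label
    batch: pd.Series  # sample id -> batch label
    config: TimecourseConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.to_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
        self.truth.rename("module").to_csv(
            outdir / "truth.tsv", sep="\t", index_label="feature_id"
        )
        _dump_config(self.config, outdir / "config.yaml")


def _module_shape(module: str, t: np.ndarray, params: dict[str, float]) -> np.ndarray:
    """Unit-amplitude temporal shape of one module over the time grid."""
    if module == "G0":
        return np.exp(-t / params["tau"])
    if module == "G1":
        return np.exp(-0.5 * ((t - params["peak"]) / params["width"]) ** 2)
    if module in ("S", "G2M"):
        rise = 1.0 / (1.0 + np.exp(-(t - params["peak"]) / params["width"]))
        fall = np.exp(-np.maximum(t - params["peak"], 0.0) * params.get("decay", 0.0))
        return rise * fall
    if module == "flat":
        return np.zeros_like(t)
    raise ValueError(f"unknown module label {module!r}")


def _gene_names(module: str, n: int) -> list[str]:
    names = list(DEFAULT_MARKERS.get(module, ()))[:n]
    names += [f"{module}_{i:03d}" for i in range(1, n - len(names) + 1)]
    return names


def simulate_timecourse(config: TimecourseConfig) -> SyntheticTimecourse:
    """Generate a synchronized time-course matrix with planted modules.

    With ``noise_sd=0`` every gene in a module is an affine transform of the
    module shape (amplitude and baseline vary per gene), so within-module
    Pearson correlations are exactly 1.  The first S genes are named after
    the S-phase markers CDC25A and BRCA1, the first G2-M genes after CDK1
    and CCNB1, so the default marker panel applies directly.
    """
    t = np.asarray(config.time_grid, dtype=float)
    rng = np.random.default_rng(config.seed)

    batches = list(config.batch_offsets)
    sample_ids, times, batch_of = [], [], []
    for b in batches:
        for ti in t:
            sample_ids.append(f"{b}_{ti:g}h")
            times.append(ti)
            batch_of.append(b)

    damp = (
        0.5 ** (t / config.desync_halflife)
        if config.desync_halflife is not None
        else np.ones_like(t)
    )

    rows, feature_ids, labels = [], [], []
    for module in MODULE_LABELS:  # fixed order for reproducibility
        n = config.genes_per_module.get(module, 0)
        if n == 0:
            continue
        params = config.peak_params.get(module, {})
        shape = _module_shape(module, t, params) * damp
        amplitude = params.get("amplitude", 0.0)
        jitter_sd = (
            config.noise_sd if config.batch_gene_sd is None else config.batch_gene_sd
        )
        for name in _gene_names(module, n):
            amp = amplitude * np.exp(rng.normal(0.0, config.amplitude_sigma))
            gene_offsets = {
                b: config.batch_offsets[b]
                + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
                for b in batches
            }
            profile = np.concatenate(
                [config.baseline + gene_offsets[b] + amp * shape for b in batches]
            )
            if config.noise_sd > 0:
                profile = profile + rng.normal(0.0, config.noise_sd, profile.size)
            rows.append(profile)
            feature_ids.append(name)
            labels.append(module)

    values = pd.DataFrame(np.asarray(rows), index=feature_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"time_h": times, "batch": batch_of}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = pd.Series(labels, index=pd.Index(feature_ids, name="feature_id"))
    batch = meta["batch"].copy()
    return SyntheticTimecourse(ExpressionMatrix(values, meta), truth, batch, config)


@dataclass(frozen=True)
class CellType:
    name: str
    proliferation: float  # fraction of the population cycling, in [0, 1]
    lineage: str


def _default_cell_types() -> list[CellType]:
    return [
        CellType("embryonic_stem", 0.95, "embryonic"),
        CellType("cd34_hsc", 0.85, "immune"),
        CellType("epithelial", 0.80, "epithelial"),
        CellType("fibroblast", 0.70, "mesenchymal"),
        CellType("keratinocyte", 0.60, "skin"),
        CellType("endothelial", 0.50, "vascular"),
        CellType("t_cell", 0.40, "immune"),
        CellType("melanocyte", 0.30, "skin"),
        CellType("hepatocyte", 0.15, "liver"),
        CellType("adipocyte", 0.10, "adipose"),
        CellType("monocyte", 0.05, "immune"),
        CellType("neuron", 0.02, "neural"),
    ]


@dataclass
class AtlasConfig:
    """Parameters of the promoter-atlas generator.

    Cell-cycle promoters follow ``log2 TPM = base + gene offset +
    beta * proliferation + noise``; lineage promoters sit ``lineage_high``
    log2 units above base within their lineage and ``lineage_low`` below it
    elsewhere.  ``alt_promoter_fraction`` of the cycle genes receive a
    second, lineage-driven promoter.
    """

    cell_types: list[CellType] = field(default_factory=_default_cell_types)
    replicates: int = 3
    cycle_genes: int | Sequence[str] = 100
    other_genes: int | Sequence[str] = 150
    #: number-of-promoters distribution for non-cycle genes
    promoters_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.3}
    )
    alt_promoter_fraction: float = 0.25
    beta: float = 3.0  # proliferation effect on log2 TPM
    base_log2_tpm: float = 3.0
    lineage_high: float = 4.0
    lineage_low: float = 2.0
    gene_offset_sd: float = 0.3
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            raise ValueError("at least one cell type is required")
        for ct in self.cell_types:
            if not 0.0 <= ct.proliferation <= 1.0:
                raise ValueError(
                    f"proliferation index of {ct.name!r} outside [0, 1]"
                )
        if not 0.0 <= self.alt_promoter_fraction <= 1.0:
            raise ValueError("alt_promoter_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        total = sum(self.promoters_per_gene.values())
        if total <= 0 or any(v < 0 for v in self.promoters_per_gene.values()):
            raise ValueError("promoters_per_gene must be a non-negative distribution")


@dataclass
class SyntheticAtlas:
    """A generated promoter atlas with promoter-class ground truth."""

    tpm: ExpressionMatrix  # promoters x samples, linear TPM
    promoter_to_gene: pd.Series  # promoter id -> gene id
    truth: pd.Series  # promoter id -> "cycle" | "lineage:<label>"
    alt_genes: list[str]  # cycle genes carrying a lineage alternative promoter
    config: AtlasConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tpm.to_tsv(outdir / "atlas_tpm.tsv", outdir / "atlas_samples.tsv")
        pd.DataFrame(
            {"gene_id": self.promoter_to_gene, "truth": self.truth}
        ).to_csv(outdir / "atlas_truth.tsv", sep="\t", index_label="promoter_id")
        _dump_config(self.config, outdir / "atlas_config.yaml")


def _as_gene_list(genes: int | Sequence[str], prefix: str) -> list[str]:
    if isinstance(genes, int):
        return [f"{prefix}{i:04d}" for i in range(1, genes + 1)]
    return list(genes)


def simulate_atlas(config: AtlasConfig) -> SyntheticAtlas:
    """Generate a promoter x sample TPM atlas with planted promoter classes."""
    rng = np.random.default_rng(config.seed)
    cycle_genes = _as_gene_list(config.cycle_genes, "CYC")
    other_genes = _as_gene_list(config.other_genes, "OTH")
    # Lineage promoters are only planted for lineages spanning >= 2 cell
    # types: a single-type "lineage" is indistinguishable from a cell-type
    # idiosyncrasy (and, for extreme proliferation indices, from the cycle
    # signal itself).
    counts_by_lineage: dict[str, int] = {}
    for ct in config.cell_types:
        counts_by_lineage[ct.lineage] = counts_by_lineage.get(ct.lineage, 0) + 1
    lineages = sorted(l for l, c in counts_by_lineage.items() if c >= 2)
    if not lineages:
        lineages = sorted(counts_by_lineage)

    sample_ids, meta_rows = [], []
    for ct in config.cell_types:
        for r in range(1, config.replicates + 1):
            sample_ids.append(f"{ct.name}_r{r}")
            meta_rows.append((ct.name, ct.proliferation, ct.lineage, r))
    meta = pd.DataFrame(
        meta_rows,
        columns=["cell_type", "proliferation", "lineage", "replicate"],
        index=pd.Index(sample_ids, name="sample_id"),
    )
    prolif = meta["proliferation"].to_numpy()
    sample_lineage = meta["lineage"].to_numpy()

    n_alt = int(round(config.alt_promoter_fraction * len(cycle_genes)))
    alt_genes = sorted(
        rng.choice(np.asarray(cycle_genes, dtype=object), size=n_alt, replace=False)
    ) if n_alt else []
    alt_set = set(alt_genes)

    prom_ids: list[str] = []
    gene_of: list[str] = []
    truth: list[str] = []
    rows: list[np.ndarray] = []

    def lineage_profile(lineage: str, offset: float) -> np.ndarray:
        high = sample_lineage == lineage
        log2 = np.where(
            high,
            config.base_log2_tpm + config.lineage_high,
            config.base_log2_tpm - config.lineage_low,
        ) + offset
        return log2

    def add_promoter(gene: str, k: int, log2: np.ndarray, label: str) -> None:
        if config.noise_sd > 0:
            log2 = log2 + rng.normal(0.0, config.noise_sd, log2.size)
        prom_ids.append(f"p{k}@{gene}")
        gene_of.append(gene)
        truth.append(label)
        rows.append(2.0 ** log2)

    for gene in cycle_genes:
        offset = rng.normal(0.0, config.gene_offset_sd)
        log2 = config.base_log2_tpm + offset + config.beta * prolif
        add_promoter(gene, 1, log2, "cycle")
        if gene in alt_set:
            lineage = str(rng.choice(lineages))
            add_promoter(
                gene, 2,
                lineage_profile(lineage, rng.normal(0.0, config.gene_offset_sd)),
                f"lineage:{lineage}",
            )

    counts = sorted(config.promoters_per_gene)
    probs = np.asarray([config.promoters_per_gene[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    for gene in other_genes:
        n_prom = int(rng.choice(counts, p=probs))
        for k in range(1, n_prom + 1):
            lineage = str(rng.choice(lineages))
            add_promoter(
                gene, k,
                lineage_profile(lineage, rng.normal(0.0, config.gene_offset_sd)),
                f"lineage:{lineage}",
            )

    tpm = pd.DataFrame(np.asarray(rows), index=prom_ids, columns=sample_ids)
    index = pd.Index(prom_ids, name="promoter_id")
    return SyntheticAtlas(
        ExpressionMatrix(tpm, meta),
        pd.Series(gene_of, index=index),
        pd.Series(truth, index=index),
        list(alt_genes),
        config,
    )


def simulate_study(
    seed: int = 0, noise_sd: float = 0.25
) -> tuple[SyntheticTimecourse, SyntheticAtlas]:
    """Generate a matched time course + promoter atlas over one gene universe.

    The atlas's cycle genes are exactly the time course's S and G2M module
    genes; all other time-course genes appear in the atlas with lineage
    promoters only.  This is the default end-to-end study configuration.
    """
    tc_config = TimecourseConfig(seed=seed, noise_sd=noise_sd)
    tc = simulate_timecourse(tc_config)
    cycle = sorted(tc.truth.index[tc.truth.isin(["S", "G2M"])])
    other = sorted(tc.truth.index[~tc.truth.isin(["S", "G2M"])])
    atlas = simulate_atlas(
        AtlasConfig(
            cycle_genes=cycle, other_genes=other, noise_sd=noise_sd, seed=seed + 1
        )
    )
    return tc, atlas


def _dump_config(config, path: Path) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(asdict(config)), fh, sort_keys=False)
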