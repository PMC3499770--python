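"""Synthetic multi-condition time-course expression data with ground truth.

The generator emulates the structure of a factorial light x temperature
perturbation experiment on a single organism: K conditions sharing one gene
list and one time grid (dense 20-min sampling to 360 min plus 5, 10, 640 and
1280 min), log2-scale intensities, a common reference time point, and three
kinds of latent temporal signal confined to disjoint gene modules:

* ``diurnal``  — sin(2 pi tau / T) scaled by the condition's light level,
* ``light``    — a fast saturating response (1 - exp(-tau/tau0)) with
  photoadaptation decay exp(-tau/tau_adapt), scaled by the condition's
  light contrast to the control,
* ``temperature`` — the analogous saturating response for the temperature
  contrast, with a much slower time constant and no adaptation
  (acclimation to temperature is slow and sustained).

The three temporal shapes are deliberately only weakly correlated on the
sampling grid (|r| < 0.4), as expected of distinct regulatory programs;
without the adaptation/time-constant separation, any two monotone response
curves are collinear (r > 0.75) on a front-loaded grid and no decomposition
could attribute them to distinct components.

Gene g in condition c at time tau is

    x(g, tau, c) = mu_g + beta * L(g) * s_kind(g)(tau, c) + eps,
    eps ~ Normal(0, (sigma * d_g)^2),

with L(g) = 1 for module members and 0 for background genes, mu_g a
per-gene log2 baseline drawn once (deliberately tight, sd 0.25: a wide
static baseline spread survives column-centering identically in every
table and becomes a stable between-table structure that swamps the
response components; keeping it small makes the compromise reflect
dynamics, which is what this benchmark is about), and d_g a mild per-gene
lognormal noise dispersion (microarray genes differ in variability). A fraction of the
background genes is additionally *erratic*: wildly variable in one single,
randomly assigned condition (condition-specific dysregulation or array
artifacts, the realistic hazard of single-replicate designs). Erratic
genes survive a fold-change/CV filter through their one noisy condition
but carry no reproducible cross-condition covariance — exactly the
population the bootstrap significance step is meant to screen out — and
they give the enrichment universe its unselected majority. Optionally one
condition is an *outlier*: its
signal matrix is replaced by an independent per-gene white-noise draw of
comparable magnitude, which destroys the within-module covariance blocks
and gives that table a deviant covariance structure the table-weighting
step should down-rank.

Levels in the default design are dimensionless perturbation scores:
light_level = 3.0 * sqrt(uE / 150) (square-root photometric scaling, so the
darkness contrast and the high-light contrast are comparable) and an
effective leaf-temperature score combining the air-temperature
perturbation (+-5.4) with radiative heating/cooling by the light contrast
(coefficient 0.3: irradiated leaves run warmer than the air, darkened
leaves cooler). With beta = 2 and sigma = 0.5 this puts module amplitudes
at 3-9 log2 units in their most responsive conditions, so module genes
clear the default fold-change/CV filter, while background genes pass it
only through the erratic-condition mechanism above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionTable, GeneSet, GeneSetCollection, TableCollection

#: factorial light x temperature design mirroring an 8-condition grid.
#: light_level is a dimensionless photosensory score (3.0*sqrt(uE/150):
#: square-root photometric scaling keeps the darkness and high-light
#: contrasts comparable). temperature_level is an effective LEAF temperature
#: score: the air-temperature perturbation (-5.4 cold / 0 / +5.4 heat)
#: plus a radiative term 0.3*(light contrast) -- irradiated leaves run
#: warmer than the air, darkened leaves cooler, so every light shift also
#: perturbs the temperature experienced by the leaf.
DEFAULT_DESIGN: dict[str, dict[str, float]] = {
    "21-L": {"light_level": 3.0, "temperature_level": 0.0},  # control
    "4-D": {"light_level": 0.0, "temperature_level": -6.3},
    "21-D": {"light_level": 0.0, "temperature_level": -0.9},
    "32-D": {"light_level": 0.0, "temperature_level": 4.5},
    "4-L": {"light_level": 2.28, "temperature_level": -5.62},
    "21-LL": {"light_level": 2.1, "temperature_level": -0.27},
    "21-HL": {"light_level": 4.08, "temperature_level": 0.32},
    "32-L": {"light_level": 3.0, "temperature_level": 5.4},
}

DEFAULT_CONTROL = "21-L"

#: default time grid (minutes): dense 20-min sampling plus 5, 10, 640, 1280
DEFAULT_TIME_GRID = np.array([0.0, 5.0, 10.0] + list(range(20, 361, 20)) + [640.0, 1280.0])

#: module sizes follow the variance hierarchy of diurnal experiments: the
#: diurnal program involves the most genes, stress-response regulons fewer
DEFAULT_MODULES = {"diurnal": 80, "light": 40, "temperature": 45}

FACTORS = ("diurnal", "light", "temperature")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of the generating process."""

    design: dict[str, dict[str, float]]
    control_id: str
    modules: dict[str, list[str]]  # module id -> gene ids (disjoint)
    factor_of_module: dict[str, str]  # module id -> latent factor kind
    beta: float
    noise_sd: float
    outlier_condition: str | None
    seed: int
    diurnal_period_min: float = 1440.0
    response_tau0_min: float = 40.0
    baselines: dict[str, float] = field(default_factory=dict)
    erratic_condition: dict[str, str] = field(default_factory=dict)

    @property
    def module_genes(self) -> set[str]:
        return {g for genes in self.modules.values() for g in genes}


def _time_grid(n_timepoints: int) -> np.ndarray:
    if n_timepoints == len(DEFAULT_TIME_GRID):
        return DEFAULT_TIME_GRID.copy()
    return np.arange(n_timepoints, dtype=float) * 20.0


def _signals(
    design: dict[str, dict[str, float]],
    control_id: str,
    tau: np.ndarray,
    period: float,
    tau0: float,
    light_adapt: float,
    temp_tau0: float,
) -> dict[str, dict[str, np.ndarray]]:
    """Latent signal s(tau, c) per factor kind and condition."""
    ctrl = design[control_id]
    step = (1.0 - np.exp(-tau / tau0)) * np.exp(-tau / light_adapt)
    slow_step = 1.0 - np.exp(-tau / temp_tau0)
    out: dict[str, dict[str, np.ndarray]] = {}
    for cid, levels in design.items():
        out[cid] = {
            "diurnal": levels["light_level"] * np.sin(2 * np.pi * tau / period),
            "light": (levels["light_level"] - ctrl["light_level"]) * step,
            "temperature": (levels["temperature_level"] - ctrl["temperature_level"]) * slow_step,
        }
    return out


def generate_collection(
    n_genes: int = 500,
    n_timepoints: int = 23,
    design: dict[str, dict[str, float]] | None = None,
    modules: dict[str, int] | dict[str, list[str]] | None = None,
    beta: float = 2.0,
    sigma: float = 0.5,
    noise_dispersion: float = 0.3,
    noise_cap: float = 3.0,
    erratic_fraction: float = 0.25,
    erratic_sd: float = 2.0,
    baseline_sd: float = 0.25,
    seed: int = 0,
    outlier: str | None = None,
    control_id: str = DEFAULT_CONTROL,
    diurnal_period_min: float = 1440.0,
    response_tau0_min: float = 40.0,
    light_adaptation_min: float = 300.0,
    temperature_tau0_min: float = 720.0,
) -> tuple[TableCollection, SyntheticGroundTruth]:
    """Generate a log2-scale table collection plus its ground truth.

    ``modules`` maps a module id (which must be, or name, one of the factor
    kinds ``diurnal``/``light``/``temperature``) either to a gene count (the
    members are then sampled from the gene pool) or to an explicit gene
    list. Modules must be disjoint. With ``outlier`` set, that condition's
    signal matrix is replaced by an independent per-gene white-noise draw of
    comparable magnitude (deviant covariance).
    """
    if design is None:
        design = {k: dict(v) for k, v in DEFAULT_DESIGN.items()}
    if control_id not in design:
        raise ValueError(f"control_id {control_id!r} not in design")
    if outlier is not None and outlier not in design:
        raise ValueError(f"outlier condition {outlier!r} not in design")
    if modules is None:
        modules = dict(DEFAULT_MODULES)
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]

    # resolve module membership (counts -> sampled disjoint gene lists)
    factor_of_module: dict[str, str] = {}
    resolved: dict[str, list[str]] = {}
    requested_counts: dict[str, int] = {}
    for mid, spec in modules.items():
        kind = next((f for f in FACTORS if f in mid), None)
        if kind is None:
            raise ValueError(
                f"module id {mid!r} must reference one of {FACTORS}"
            )
        factor_of_module[mid] = kind
        if isinstance(spec, int):
            requested_counts[mid] = spec
        else:
            resolved[mid] = list(spec)
    explicit = [g for genes in resolved.values() for g in genes]
    if len(set(explicit)) != len(explicit):
        raise ValueError("modules overlap: a gene appears in more than one module")
    unknown = set(explicit) - set(gene_ids)
    if unknown:
        raise ValueError(f"module genes outside the gene pool: {sorted(unknown)[:5]}")
    pool = [g for g in gene_ids if g not in set(explicit)]
    total_requested = sum(requested_counts.values())
    if total_requested > len(pool):
        raise ValueError("n_genes too small for the requested module sizes")
    drawn = rng.choice(len(pool), size=total_requested, replace=False)
    cursor = 0
    for mid, cnt in requested_counts.items():
        resolved[mid] = sorted(pool[i] for i in drawn[cursor : cursor + cnt])
        cursor += cnt

    tau = _time_grid(n_timepoints)
    if len(tau) < 4:
        raise ValueError("need at least 4 time points")
    signals = _signals(design, control_id, tau, diurnal_period_min,
                       response_tau0_min, light_adaptation_min,
                       temperature_tau0_min)

    mu = rng.normal(8.0, baseline_sd, size=n_genes)
    noise_sd = sigma * np.minimum(
        np.exp(rng.normal(0.0, noise_dispersion, size=n_genes)), noise_cap
    )
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # per-gene factor kind (None = background)
    kind_of_gene: dict[str, str] = {}
    for mid, genes in resolved.items():
        for g in genes:
            kind_of_gene[g] = factor_of_module[mid]

    # erratic background genes: one randomly assigned condition in which a
    # gene is wildly variable (condition-specific dysregulation); they pass
    # variability filters but have no reproducible cross-table structure
    condition_ids = list(design)
    background = [g for g in gene_ids if g not in kind_of_gene]
    n_erratic = int(round(erratic_fraction * len(background)))
    erratic_pick = rng.choice(len(background), size=n_erratic, replace=False)
    erratic_condition = {
        background[i]: condition_ids[rng.integers(0, len(condition_ids))]
        for i in sorted(erratic_pick)
    }

    tables = []
    for cid in design:
        signal = np.zeros((n_genes, len(tau)))
        if cid == outlier:
            # independent per-gene draw: destroys the within-module
            # covariance blocks, giving this table deviant structure
            for g in kind_of_gene:
                signal[gene_index[g]] = beta * rng.normal(0.0, 2.0, size=len(tau))
        else:
            per_kind = signals[cid]
            for g, kind in kind_of_gene.items():
                signal[gene_index[g]] = beta * per_kind[kind]
        sd_here = noise_sd.copy()
        for g, ec in erratic_condition.items():
            if ec == cid:
                sd_here[gene_index[g]] = erratic_sd
        values = (
            mu[:, None]
            + signal
            + sd_here[:, None] * rng.standard_normal((n_genes, len(tau)))
        )
        tables.append(
            ExpressionTable(cid, gene_ids, tau, values, scale="log2")
        )
    truth = SyntheticGroundTruth(
        design=design,
        control_id=control_id,
        modules=resolved,
        factor_of_module=factor_of_module,
        beta=beta,
        noise_sd=sigma,
        outlier_condition=outlier,
        seed=seed,
        diurnal_period_min=diurnal_period_min,
        response_tau0_min=response_tau0_min,
        baselines={g: float(mu[i]) for i, g in enumerate(gene_ids)},
        erratic_condition=erratic_condition,
    )
    return TableCollection(tables=tables, control_id=control_id), truth


def ground_truth_gene_sets(
    truth: SyntheticGroundTruth,
    n_decoys: int = 5,
    seed: int = 0,
    gene_pool: list[str] | None = None,
    exclude_modules: bool = True,
) -> GeneSetCollection:
    """One gene set per true module plus random same-size decoy sets.

    Decoy members are drawn without replacement from ``gene_pool`` (default:
    all generated genes, excluding module members when ``exclude_modules``).
    """
    rng = np.random.default_rng(seed)
    if gene_pool is None:
        gene_pool = sorted(truth.baselines)
    module_genes = truth.module_genes
    pool = [g for g in gene_pool if not (exclude_modules and g in module_genes)]
    sizes = [len(g) for g in truth.modules.values()]
    decoy_size = int(round(np.mean(sizes))) if sizes else 10

    sets: dict[str, GeneSet] = {}
    for mid, genes in truth.modules.items():
        sets[f"module:{mid}"] = GeneSet(f"true {truth.factor_of_module[mid]} module", list(genes))
    for d in range(1, n_decoys + 1):
        take = min(decoy_size, len(pool))
        members = sorted(rng.choice(pool, size=take, replace=False))
        sets[f"decoy:{d:02d}"] = GeneSet("random decoy set", list(members))
    return GeneSetCollection(sets)
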