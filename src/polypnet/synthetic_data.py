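"""Truth-labelled synthetic data for the polyp feeding analysis pipeline.

Expression matrices follow a single-factor-per-module model: every gene in
module *m* is

    x_g(s) = a_g * e_m(s) + sqrt(1 - a_g^2) * eps_g(s)

where ``e_m`` is the module's latent eigengene trajectory (standard normal
per sample), ``a_g`` is the gene's loading and ``eps_g`` is residual noise.
One "driven" module has its latent shifted by a configurable number of
standard deviations in the feeding group, which plants the module--trait
association the downstream network stage must recover.  Background genes
are pure noise.

Because the model is fully parametric, population values of every
downstream quantity are known in closed form: within-module gene--gene
correlations converge to ``a_g * a_h``, the gene--eigengene correlation
(kME) to ``a_g``, and the eigengene's variance-explained fraction to the
mean squared loading.  Oracle tests lean on those identities.

Physiological tables are drawn from per-trait, per-group normal
distributions whose default means/SDs are the study's reported summaries
(polyp diameter, polyp counts, skeleton weight, symbiont density,
chlorophyll per cell, host/symbiont Ea).  Assay plates are simulated as a
known line (absorbance = slope * concentration + intercept) plus noise so
standard-curve fitting can be checked by round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MODULE_SIZES_NETWORK",
    "GLUCOSE_STANDARDS_MG_ML",
    "DEFAULT_TRAIT_PARAMS",
    "SimConfig",
    "SimTruth",
    "AssayPlate",
    "scaled_module_sizes",
    "simulate_expression",
    "simulate_physiology",
    "simulate_assay_plate",
]

#: Default 13-module size profile of the 5000-gene co-expression network.
#: The three largest (1255/1226/1130 = 25.1/24.52/22.6 %) and the smallest
#: (48 = 0.96 %) are the reported module sizes; the intermediate nine are
#: package defaults chosen to decrease monotonically and sum to 5000.
MODULE_SIZES_NETWORK: tuple[int, ...] = (
    1255, 1226, 1130, 380, 250, 180, 140, 110, 90, 75, 60, 56, 48,
)

#: Glucose standard series of the carbohydrate assay (mg mL^-1).
GLUCOSE_STANDARDS_MG_ML: tuple[float, ...] = (0.0, 0.08, 0.16, 0.24, 0.32)

#: Per-trait, per-group normal parameters used by :func:`simulate_physiology`.
#: Means/SDs for growth, symbiont, chlorophyll and Ea rows are the study's
#: reported group summaries; caspase A405, T-AOC and MDA scales are
#: synthetic defaults (the source reports those only graphically) chosen so
#: that caspase activation is clearly suppressed by feeding while T-AOC and
#: MDA overlap between groups.
DEFAULT_TRAIT_PARAMS = pd.DataFrame(
    [
        ("diameter_day30_um", "control", 2419.40, 137.26),
        ("diameter_day30_um", "feeding", 2650.70, 163.42),
        ("diameter_day60_um", "control", 2797.90, 89.98),
        ("diameter_day60_um", "feeding", 3308.50, 331.11),
        ("polyp_count_day15", "control", 3.20, 0.60),
        ("polyp_count_day15", "feeding", 4.00, 0.63),
        ("polyp_count_day60", "control", 6.10, 0.53),
        ("polyp_count_day60", "feeding", 9.80, 1.93),
        ("skeleton_weight_g", "control", 0.00267, 0.0002),
        ("skeleton_weight_g", "feeding", 0.0054, 0.00036),
        ("symbiont_density_1e5_cells_cm2", "control", 2.15, 0.10),
        ("symbiont_density_1e5_cells_cm2", "feeding", 2.57, 0.12),
        ("chlorophyll_pg_cell", "control", 17.11, 1.49),
        ("chlorophyll_pg_cell", "feeding", 19.05, 1.07),
        ("ea_host_J_cm2", "control", 26.92, 2.67),
        ("ea_host_J_cm2", "feeding", 30.51, 1.52),
        ("ea_symbiont_J_cm2", "control", 9.31, 0.65),
        ("ea_symbiont_J_cm2", "feeding", 10.60, 0.76),
        ("caspase_a405", "control", 1.00, 0.08),
        ("caspase_a405", "feeding", 0.62, 0.07),
        ("taoc_U_mg", "control", 1.50, 0.25),
        ("taoc_U_mg", "feeding", 1.68, 0.28),
        ("mda_nmol_mg", "control", 1.05, 0.30),
        ("mda_nmol_mg", "feeding", 1.12, 0.32),
    ],
    columns=["trait", "group", "mean", "sd"],
)

GROUPS = ("control", "feeding")


def scaled_module_sizes(total: int, profile: tuple[int, ...] = MODULE_SIZES_NETWORK) -> list[int]:
    """Scale a module-size profile to a smaller network, preserving the sum.

    Sizes are scaled proportionally, floored, and the remainder distributed
    by largest fractional part (ties to the larger module).  Used to run the
    full 13-module structure at reduced gene counts.
    """
    profile_arr = np.asarray(profile, dtype=float)
    raw = profile_arr / profile_arr.sum() * total
    sizes = np.floor(raw).astype(int)
    remainder = total - int(sizes.sum())
    if remainder > 0:
        frac_order = np.argsort(-(raw - sizes), kind="stable")
        sizes[frac_order[:remainder]] += 1
    return sizes.tolist()


@dataclass
class SimConfig:
    """Configuration of the planted-module expression simulator.

    Defaults mirror the study scale: 19,397 detected genes of which the
    5,000-gene network carries 13 modules, with 5 replicates per group.
    """

    n_genes: int = 19397
    module_sizes: tuple[int, ...] = MODULE_SIZES_NETWORK
    n_per_group: int = 5
    loading_range: tuple[float, float] = (0.6, 0.95)
    trait_effect: float = 2.0
    #: index of the trait-driven module; None picks the 4th-largest module
    #: ("yellow" by size rank) or the last one when fewer modules exist
    driven_module_index: int | None = None
    noise_sd: float = 1.0
    emit_counts: bool = False
    n_independent_de: int = 0
    independent_de_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} "
                f"but only {self.n_genes} genes are available"
            )
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        low, high = self.loading_range
        if not (0.0 < low <= high <= 1.0):
            raise ValueError("loading_range must satisfy 0 < low <= high <= 1")
        if self.driven_module_index is None:
            self.driven_module_index = min(3, len(self.module_sizes) - 1)
        if not (0 <= self.driven_module_index < len(self.module_sizes)):
            raise ValueError("driven_module_index out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_independent_de < 0:
            raise ValueError("n_independent_de must be non-negative")
        n_background = self.n_genes - sum(self.module_sizes)
        if self.n_independent_de > n_background:
            raise ValueError("n_independent_de exceeds background gene count")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated expression matrix."""

    gene_module: np.ndarray  # per-gene module label, 0 = background
    gene_loading: np.ndarray  # a_g per gene (0 for background)
    eigengene_trajectories: pd.DataFrame  # module x sample latent values
    de_genes: frozenset  # genes with a planted group effect
    driven_module: int  # 1-based label of the trait-driven module
    module_sizes: tuple[int, ...] = field(default_factory=tuple)


@dataclass
class AssayPlate:
    """Simulated spectrophotometric plate with recorded true concentrations."""

    wells: pd.DataFrame  # columns: well, role, true_concentration, absorbance
    slope: float
    intercept: float


def sample_names(n_per_group: int) -> list[str]:
    return [f"Control-{i + 1}" for i in range(n_per_group)] + [
        f"Feeding-{i + 1}" for i in range(n_per_group)
    ]


def sample_groups(n_per_group: int) -> pd.Series:
    """Group label per sample, indexed by sample id."""
    names = sample_names(n_per_group)
    labels = ["control"] * n_per_group + ["feeding"] * n_per_group
    return pd.Series(labels, index=pd.Index(names, name="sample"), name="group")


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Draw a genes x samples expression matrix with planted modules.

    Returns ``(expression, groups, truth)``.  ``expression`` is continuous
    (log-scale) by default; with ``config.emit_counts`` the values are
    Poisson draws with rate ``exp(x)``.  ``groups`` maps sample id to
    {control, feeding}.  Gene order is module 1 genes, module 2 genes, ...,
    then background genes; the order carries no information downstream.
    """
    rng = np.random.default_rng(config.seed)
    n_modules = len(config.module_sizes)
    n_samples = 2 * config.n_per_group
    groups = sample_groups(config.n_per_group)
    feeding_mask = (groups == "feeding").to_numpy()

    gene_module = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        gene_module[pos : pos + size] = m
        pos += size

    low, high = config.loading_range
    gene_loading = np.zeros(config.n_genes)
    in_module = gene_module > 0
    gene_loading[in_module] = rng.uniform(low, high, size=int(in_module.sum()))

    latents = rng.standard_normal((n_modules, n_samples))
    driven_label = config.driven_module_index + 1
    latents[config.driven_module_index, feeding_mask] += config.trait_effect

    noise = config.noise_sd * rng.standard_normal((config.n_genes, n_samples))
    x = np.empty((config.n_genes, n_samples))
    a = gene_loading[in_module][:, None]
    x[in_module] = a * latents[gene_module[in_module] - 1] + np.sqrt(1.0 - a**2) * noise[in_module]
    x[~in_module] = noise[~in_module]

    de_genes = set(np.flatnonzero(gene_module == driven_label))
    if config.n_independent_de:
        background = np.flatnonzero(gene_module == 0)
        chosen = rng.choice(background, size=config.n_independent_de, replace=False)
        x[np.ix_(chosen, np.flatnonzero(feeding_mask))] += config.independent_de_log2fc
        de_genes.update(chosen.tolist())

    if config.emit_counts:
        x = rng.poisson(np.exp(x)).astype(float)

    width = len(str(config.n_genes))
    gene_ids = [f"gene_{i + 1:0{width}d}" for i in range(config.n_genes)]
    expression = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene"), columns=groups.index)

    truth = SimTruth(
        gene_module=gene_module,
        gene_loading=gene_loading,
        eigengene_trajectories=pd.DataFrame(
            latents,
            index=pd.Index(range(1, n_modules + 1), name="module"),
            columns=groups.index,
        ),
        de_genes=frozenset(gene_ids[i] for i in de_genes),
        driven_module=driven_label,
        module_sizes=config.module_sizes,
    )
    return expression, groups, truth


def simulate_physiology(
    config: SimConfig, trait_params: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Draw per-colony physiological traits from group-wise normals.

    Returns a wide table: one row per colony (sample ids match
    :func:`simulate_expression`), a ``group`` column, and one column per
    trait.  Deterministic under ``config.seed``; the generator stream is
    decoupled from the expression stream.
    """
    if trait_params is None:
        trait_params = DEFAULT_TRAIT_PARAMS
    if (trait_params["sd"] < 0).any():
        raise ValueError("trait sd values must be non-negative")
    unknown = set(trait_params["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    groups = sample_groups(config.n_per_group)
    table = pd.DataFrame({"group": groups})
    for trait in trait_params["trait"].unique():
        values = np.empty(len(groups))
        for grp in GROUPS:
            rows = trait_params[(trait_params["trait"] == trait) & (trait_params["group"] == grp)]
            if rows.empty:
                raise ValueError(f"trait {trait!r} missing parameters for group {grp!r}")
            mean, sd = float(rows["mean"].iloc[0]), float(rows["sd"].iloc[0])
            mask = (groups == grp).to_numpy()
            values[mask] = mean + sd * rng.standard_normal(int(mask.sum()))
        table[trait] = values
    return table


def simulate_assay_plate(
    slope: float,
    intercept: float,
    standards: tuple[float, ...] = GLUCOSE_STANDARDS_MG_ML,
    unknowns_conc: tuple[float, ...] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AssayPlate:
    """Simulate a plate read: absorbance = slope*conc + intercept + noise."""
    standards = tuple(float(c) for c in standards)
    if not standards:
        raise ValueError("standards must be non-empty")
    if any(c < 0 for c in standards):
        raise ValueError("standard concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    conc = np.array(standards + tuple(float(c) for c in unknowns_conc))
    absorbance = slope * conc + intercept + noise_sd * rng.standard_normal(conc.size)
    roles = ["standard"] * len(standards) + ["unknown"] * len(unknowns_conc)
    wells = pd.DataFrame(
        {
            "well": [f"W{i + 1:02d}" for i in range(conc.size)],
            "role": roles,
            "true_concentration": conc,
            "absorbance": absorbance,
        }
    )
    return AssayPlate(wells=wells, slope=slope, intercept=intercept)
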