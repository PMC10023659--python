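"""Synthetic two-species cohort generator.

Generates negative-binomial bulk RNA-seq counts that emulate the structure
the downstream analysis assumes: a human-like case/control cohort whose
cases fall into toxicology subgroups with graded disease-signature strength
(antipsychotic-negative, atypical, typical, mixed), a macaque-like drug
cohort (placebo / clozapine / low- and high-dose haloperidol), planted
co-expression modules whose condition effects can agree or disagree in sign
between the two datasets, covariate effects on the log scale, optional
planted PCA outliers, and bulk samples mixed from known cell-type
proportions against a single-cell reference.

Default group sizes are the study conditions: 113 controls and 23/28/27/10
cases (negative/atypical/typical/mixed) in the human-like cohort;
7/9/10/7 (placebo/clozapine/haloperidol-low/haloperidol-high) in the
macaque-like cohort.  Subgroup signature-strength multipliers default to
atypical 1.5 > mixed 1.2 > negative 1.0 > typical 0.8.

All randomness flows from a single seed through isolated per-sub-generator
streams (``numpy`` SeedSequence spawning), so outputs are bit-identical
across runs and platforms for a fixed config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, OrthologyMap, SampleTable

HUMAN_GROUP_SIZES = {"control": 113, "neg": 23, "atypical": 28, "typical": 27, "mixed": 10}
MACAQUE_GROUP_SIZES = {"placebo": 7, "clz": 9, "hal_lo": 10, "hal_hi": 7}
SUBGROUP_MULTIPLIERS = {"atypical": 1.5, "mixed": 1.2, "neg": 1.0, "typical": 0.8}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_genes: int = 4000
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(HUMAN_GROUP_SIZES))
    n_de_genes: int = 400
    base_lfc: float = 1.0  # log2 units
    subgroup_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(SUBGROUP_MULTIPLIERS)
    )
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (1e6, 3e6)
    covariate_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "sex": 0.10, "age": 0.10, "rin": 0.20, "pmi": 0.10, "ph": 0.05,
            "batch": 0.20, "effective_mapping_rate": 0.05, "intergenic_rate": 0.05,
        }
    )
    n_modules: int = 5
    module_size_range: tuple[int, int] = (30, 60)
    #: per-module latent-factor mean shifts (dataset A, dataset B); signs plant
    #: convergent (same sign) or divergent (opposite sign) modules.  The
    #: magnitudes are sized per dataset for comparable association strength
    #: (|t| well above 4): ~0.8 SD suffices in the large case/control cohort,
    #: ~2 SD in the small drug cohort.  Keeping shifts modest relative to the
    #: unit factor variance also keeps distinct modules' factors from
    #: correlating through the shared condition indicator.
    module_condition_effects: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.8, 2.0), (-0.8, -2.0), (0.8, -2.0), (-0.8, 2.0), (0.0, 0.0)]
    )
    module_loading: float = 1.0  # log2 amplitude per unit latent factor (well-defined modules)
    n_outliers: int = 0
    outlier_log_sd: float = 2.0  # SD of the global log2 distortion of outlier samples
    #: fraction of dataset-A DE genes whose fold change is shared (same sign)
    #: by the treated groups of dataset B in the paired-species design
    shared_de_fraction: float = 0.3
    #: group -> cell-type proportion vector for reference/mixture simulation
    celltype_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "control": {"ExN": 0.50, "InN": 0.25, "Astro": 0.25},
            "case": {"ExN": 0.50, "InN": 0.20, "Astro": 0.30},
        }
    )
    proportion_concentration: float = 100.0  # Dirichlet concentration around group means
    cells_per_type: int = 100
    n_markers_per_type: int = 30
    n_bulk_mixtures: int = 80
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 2")
        if any(m <= 0 for m in self.subgroup_multipliers.values()):
            raise ValueError("subgroup multipliers must be positive")
        if self.n_de_genes > 0 and self.base_lfc != 0 and self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if self.n_de_genes == 0 and self.base_lfc != 0:
            raise ValueError("nonzero base_lfc requested with 0 DE genes")
        for group, props in self.celltype_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in props.values()):
                raise ValueError(f"cell-type proportions for {group!r} not on the simplex")


@dataclass
class GroundTruth:
    """Planted truth recorded alongside each simulated dataset."""

    true_lfc: np.ndarray | None = None
    de_mask: np.ndarray | None = None
    module_labels: np.ndarray | None = None  # 0 = background, 1..n_modules
    module_effects_a: np.ndarray | None = None
    module_effects_b: np.ndarray | None = None
    true_proportions: pd.DataFrame | None = None
    outlier_sample_ids: list[str] = field(default_factory=list)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha*mu^2, via gamma-Poisson mixture."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _draw_metadata(group_labels: list[str], diagnosis: list[str], prefix: str,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = len(group_labels)
    return pd.DataFrame({
        "sample_id": [f"{prefix}{i:04d}" for i in range(n)],
        "diagnosis": diagnosis,
        "tox_group": group_labels,
        "sex": rng.choice(["f", "m"], size=n),
        "age": np.round(np.clip(rng.normal(47, 14, n), 18, 90), 1),
        "rin": np.round(np.clip(rng.normal(7.5, 0.9, n), 4.0, 10.0), 2),
        "pmi": np.round(np.clip(rng.normal(35, 15, n), 2, 120), 1),
        "ph": np.round(np.clip(rng.normal(6.4, 0.25, n), 5.8, 7.2), 2),
        "batch": rng.choice([f"b{j}" for j in range(4)], size=n),
        "effective_mapping_rate": np.round(np.clip(rng.normal(0.85, 0.04, n), 0.5, 0.99), 4),
        "intergenic_rate": np.round(np.clip(rng.normal(0.08, 0.02, n), 0.01, 0.4), 4),
    })


def _covariate_log2_effects(meta: pd.DataFrame, n_genes: int,
                            effect_sizes: dict[str, float],
                            rng: np.random.Generator) -> np.ndarray:
    """Per-gene random covariate coefficients applied to standardized covariates."""
    total = np.zeros((n_genes, len(meta)))
    for col, size in effect_sizes.items():
        if size == 0 or col not in meta.columns:
            continue
        vals = meta[col]
        if vals.dtype.kind in "if":
            x = np.asarray(vals, dtype=float)
            sd = x.std()
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
            coefs = rng.normal(0.0, size, n_genes)
            total += np.outer(coefs, x)
        else:
            for level in sorted(set(vals)):
                ind = (vals == level).to_numpy().astype(float)
                total += np.outer(rng.normal(0.0, size, n_genes), ind)
    return total


def _assign_modules(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous non-overlapping gene blocks, label 0 = background."""
    labels = np.zeros(config.n_genes, dtype=int)
    lo, hi = config.module_size_range
    pos = 0
    for m in range(1, config.n_modules + 1):
        size = int(rng.integers(lo, hi + 1))
        if pos + size > config.n_genes:
            raise ValueError("module sizes exceed n_genes")
        labels[pos:pos + size] = m
        pos += size
    return labels


def simulate_bulk_cohort(
    config: SimulationConfig, seed: int | None = None, *, prefix: str = "S",
    condition_effects: Sequence[float] | None = None,
    group_recode: dict[str, str] | None = None,
    fixed_lfc: np.ndarray | None = None,
    module_plan: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Simulate one bulk cohort with planted DE, covariate, and module effects.

    ``condition_effects`` overrides the dataset-A column of
    ``config.module_condition_effects`` (used by :func:`simulate_paired_species`
    to plant the dataset-B signs).  Case samples receive a diagnosis effect of
    ``base_lfc x subgroup_multiplier[tox_group]`` on the planted DE genes, and
    module latent factors are shifted by the module's condition effect.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng_meta, rng_base, rng_cov, rng_mod, rng_counts, rng_out = _spawn(seed, 6)

    groups: list[str] = []
    diagnosis: list[str] = []
    for name, n in config.group_sizes.items():
        is_control = name in ("control", "placebo")
        groups += ["none" if is_control else name] * n
        diagnosis += ["control" if is_control else "case"] * n
    meta = _draw_metadata(groups, diagnosis, prefix, rng_meta)
    if group_recode is not None:
        meta["treatment"] = ["placebo" if g == "none" else g for g in meta["tox_group"]]
        meta["tox_group"] = meta["tox_group"].map(lambda g: group_recode.get(g, g))
    n_samples = len(meta)
    case = (meta["diagnosis"] == "case").to_numpy()

    # baseline abundance: log2 mean CPM ~ N(4, 2), heavier tail on the right
    base_log2_cpm = rng_base.normal(4.0, 2.0, config.n_genes)
    lib_lo, lib_hi = config.library_size_range
    lib = np.exp(rng_base.uniform(np.log(lib_lo), np.log(lib_hi), n_samples))

    # planted DE genes with random sign, scaled per sample by subgroup multiplier
    de_mask = np.zeros(config.n_genes, dtype=bool)
    true_lfc = np.zeros(config.n_genes)
    if fixed_lfc is not None:
        true_lfc = np.asarray(fixed_lfc, dtype=float).copy()
        de_mask = true_lfc != 0
    elif config.n_de_genes > 0:
        de_idx = rng_base.choice(config.n_genes, config.n_de_genes, replace=False)
        de_mask[de_idx] = True
        true_lfc[de_idx] = config.base_lfc * rng_base.choice([-1.0, 1.0], config.n_de_genes)
    groups_arr = np.asarray(groups)  # pre-recode labels drive the planted effect
    mult = np.zeros(n_samples)
    for g, m in config.subgroup_multipliers.items():
        mult[groups_arr == g] = m

    log2_mu = base_log2_cpm[:, None] + np.outer(true_lfc, mult)
    log2_mu += _covariate_log2_effects(meta, config.n_genes, config.covariate_effect_sizes, rng_cov)

    # planted modules: latent factor ~ N(effect * 1[case], 1) per sample.
    # A module_plan (labels + per-gene loadings) can be supplied so two
    # cohorts share identical module structure on ortholog-matched genes.
    module_labels = np.zeros(config.n_genes, dtype=int)
    effects = np.zeros(max(config.n_modules, 1))
    if config.n_modules > 0:
        if module_plan is None:
            module_labels = _assign_modules(config, rng_mod)
            loadings = config.module_loading * rng_mod.uniform(0.5, 1.0, config.n_genes)
        else:
            module_labels, loadings = module_plan
        if condition_effects is None:
            condition_effects = [e[0] for e in config.module_condition_effects]
        effects = np.zeros(config.n_modules)
        effects[: len(condition_effects)] = list(condition_effects)[: config.n_modules]
        factors = rng_mod.normal(0.0, 1.0, (config.n_modules, n_samples))
        factors += np.outer(effects, case.astype(float))
        for m in range(1, config.n_modules + 1):
            members = module_labels == m
            if members.any():
                log2_mu[members] += np.outer(loadings[members], factors[m - 1])

    # outliers: globally distorted samples (degraded-tissue emulation).  Each
    # outlier's log2 distortion = a shared degradation direction + an
    # individual one, so a pair of outliers is extreme on >= 2 PCs (the shared
    # axis and the contrast); a lone distorted sample defines only one
    # extreme direction and would escape a two-PC rule.
    outlier_ids: list[str] = []
    if config.n_outliers > 0:
        out_idx = rng_out.choice(n_samples, config.n_outliers, replace=False)
        shared = rng_out.normal(0.0, config.outlier_log_sd, config.n_genes)
        for i in out_idx:
            log2_mu[:, i] += shared + rng_out.normal(0.0, config.outlier_log_sd, config.n_genes)
        outlier_ids = [meta["sample_id"].iloc[i] for i in out_idx]

    rel = 2.0 ** log2_mu / 1e6  # log2 CPM -> relative abundance
    mu = rel * lib[None, :]
    counts = _nb_counts(mu, config.nb_dispersion, rng_counts)

    cm = CountMatrix([f"g{prefix}{i:05d}" for i in range(config.n_genes)],
                     list(meta["sample_id"]), counts)
    truth = GroundTruth(
        true_lfc=true_lfc, de_mask=de_mask, module_labels=module_labels,
        module_effects_a=effects, outlier_sample_ids=outlier_ids,
    )
    return cm, SampleTable(meta), truth


def simulate_paired_species(
    config: SimulationConfig, seed: int | None = None,
) -> tuple[
    tuple[CountMatrix, SampleTable], tuple[CountMatrix, SampleTable], OrthologyMap, GroundTruth
]:
    """Simulate the paired design: a case/control cohort (dataset A) and a
    drug-treatment cohort (dataset B) sharing module structure on
    ortholog-matched genes, with per-dataset condition-effect signs.

    Dataset B's metadata carries a ``treatment`` column
    (placebo/clz/hal_lo/hal_hi, default sizes 7/9/10/7); treated animals are
    coded ``case`` so two-level contrasts work uniformly.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    seq = np.random.SeedSequence(seed).spawn(3)
    seed_a = int(seq[0].generate_state(1)[0] % (2**31))
    seed_b = int(seq[1].generate_state(1)[0] % (2**31))

    effects_a = [e[0] for e in config.module_condition_effects]
    effects_b = [e[1] for e in config.module_condition_effects]

    # one module plan shared by both cohorts: identical gene membership and
    # loadings on ortholog-matched genes (dataset-specific factors and noise)
    module_plan = None
    if config.n_modules > 0:
        rng_plan = np.random.Generator(np.random.PCG64(
            int(seq[2].generate_state(1)[0] % (2**31)) ^ 0x3A7))
        labels_plan = _assign_modules(config, rng_plan)
        loadings_plan = config.module_loading * rng_plan.uniform(0.5, 1.0, config.n_genes)
        module_plan = (labels_plan, loadings_plan)

    cm_a, meta_a, truth_a = simulate_bulk_cohort(
        config, seed_a, prefix="A", condition_effects=effects_a, module_plan=module_plan)

    config_b = replace(
        config,
        group_sizes=dict(MACAQUE_GROUP_SIZES),
        subgroup_multipliers={"clz": 1.0, "hal_lo": 1.0, "hal_hi": 1.0},
        n_outliers=0,
    )
    # dataset B shares a configurable fraction of A's fold changes (same sign),
    # applied to all treated groups; the rest of B carries no gene-level effect
    lfc_b = np.zeros(config.n_genes)
    de_idx = np.where(truth_a.de_mask)[0]
    if len(de_idx) and config.shared_de_fraction > 0:
        rng_share = np.random.Generator(np.random.PCG64(seq[2]))
        n_shared = int(round(config.shared_de_fraction * len(de_idx)))
        shared = rng_share.choice(de_idx, n_shared, replace=False)
        lfc_b[shared] = truth_a.true_lfc[shared]
    cm_b, meta_b, truth_b = simulate_bulk_cohort(
        config_b, seed_b, prefix="B", condition_effects=effects_b,
        group_recode={"clz": "atypical", "hal_lo": "typical", "hal_hi": "typical"},
        fixed_lfc=lfc_b, module_plan=module_plan)

    if len(cm_a.gene_ids) < config.n_genes or len(cm_b.gene_ids) < config.n_genes:
        raise ValueError("orthology coverage below n_genes")
    omap = OrthologyMap(list(zip(cm_a.gene_ids, cm_b.gene_ids)))

    truth = GroundTruth(
        true_lfc=truth_a.true_lfc, de_mask=truth_a.de_mask,
        module_labels=truth_a.module_labels,
        module_effects_a=truth_a.module_effects_a,
        module_effects_b=truth_b.module_effects_a,
        outlier_sample_ids=truth_a.outlier_sample_ids,
    )
    return (cm_a, meta_a), (cm_b, meta_b), omap, truth


def simulate_reference(
    config: SimulationConfig, seed: int | None = None,
):
    """Simulate a labeled single-cell reference plus bulk mixtures of known
    cell-type proportions.

    Returns ``(reference, bulk_counts, bulk_meta, truth)`` where ``reference``
    is a :class:`~sigconfound.deconv.CellTypeReference`, bulk samples are
    convex combinations of per-type CPM profiles with NB noise, and
    ``truth.true_proportions`` records the per-sample mixing weights.  Case
    samples draw proportions around the case group means (default: inhibitory
    neurons down 0.05, astrocytes up) — the planted cell-type shift.
    """
    from .deconv import CellTypeReference

    config.validate()
    if seed is None:
        seed = config.seed
    rng_prof, rng_cells, rng_props, rng_bulk, rng_meta = _spawn(seed ^ 0x5EED, 5)

    types = list(next(iter(config.celltype_proportions.values())).keys())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    if config.cells_per_type < 20:
        raise ValueError("need >= 20 cells per type")
    n_genes = config.n_genes

    base = 2.0 ** rng_prof.normal(4.0, 1.5, n_genes)
    profiles = np.tile(base, (len(types), 1))
    # type-exclusive marker blocks: strongly elevated in one type only
    for t in range(len(types)):
        lo = t * config.n_markers_per_type
        hi = lo + config.n_markers_per_type
        if hi > n_genes:
            raise ValueError("marker blocks exceed n_genes")
        profiles[t, lo:hi] *= 16.0
        for other in range(len(types)):
            if other != t:
                profiles[other, lo:hi] *= 0.25
    profiles = profiles / profiles.sum(axis=1, keepdims=True)  # rows: relative abundance

    # single cells: NB around type profile, library ~2k-10k counts
    cell_counts, cell_types = [], []
    for t, name in enumerate(types):
        libs = np.exp(rng_cells.uniform(np.log(2e3), np.log(1e4), config.cells_per_type))
        mu = np.outer(libs, profiles[t])
        cell_counts.append(_nb_counts(mu, 0.2, rng_cells))
        cell_types += [name] * config.cells_per_type
    reference = CellTypeReference(
        counts=np.vstack(cell_counts),
        gene_ids=[f"g{i:05d}" for i in range(n_genes)],
        cell_types=cell_types,
    )

    # bulk mixtures: half control, half case, Dirichlet around group means
    n_bulk = config.n_bulk_mixtures
    n_ctrl = n_bulk // 2
    diagnosis = ["control"] * n_ctrl + ["case"] * (n_bulk - n_ctrl)
    props = np.zeros((n_bulk, len(types)))
    for i, diag in enumerate(diagnosis):
        mean = np.array([config.celltype_proportions[diag][t] for t in types])
        props[i] = rng_props.dirichlet(mean * config.proportion_concentration)
    rel_bulk = props @ profiles  # convex mixture of relative profiles
    lib_lo, lib_hi = config.library_size_range
    libs = np.exp(rng_bulk.uniform(np.log(lib_lo), np.log(lib_hi), n_bulk))
    bulk = _nb_counts(rel_bulk.T * libs[None, :], 0.05, rng_bulk)

    meta = _draw_metadata(
        ["none" if d == "control" else "neg" for d in diagnosis], diagnosis, "M", rng_meta)
    bulk_cm = CountMatrix(reference.gene_ids, list(meta["sample_id"]), bulk)
    truth = GroundTruth(true_proportions=pd.DataFrame(
        props, index=list(meta["sample_id"]), columns=types))
    return reference, bulk_cm, SampleTable(meta), truth
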