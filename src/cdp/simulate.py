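"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the three input families of a pan-cancer drug
prescription study so every stage can be exercised without external data:

* paired tumor/normal cohorts — log-normal background expression with
  gene-specific (heteroscedastic) variances; genes belonging to planted
  "up" pathways are shifted upward in cases by a configurable effect size
  (in units of the gene's log-scale sigma), planted "down" pathways downward;
* clinical survival tables — exponential survival whose hazard scales as
  HR^z with the standardized per-patient pathway-activation score, plus
  independent uniform censoring;
* perturbation libraries — per-drug treated-vs-control ranked gene lists
  where "reverser" drugs push planted-up genes to the bottom (and planted-
  down genes to the top) with a configurable strength, while decoy drugs
  rank genes at random; drugs carry several instances each (3 by default,
  matching the multiple-instances-per-drug structure of public perturbation
  compendia).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    CASE,
    CONTROL,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
)
from .enrichment import RankedList, _sort_genes
from .prescription import PerturbationProfile


@dataclass
class SimulationConfig:
    """Study-shape parameters for the synthetic generators.

    Defaults keep a full pipeline run to desk scale: 2,000 genes, 50 gene
    sets of 20-80 genes, 3 cancers with 20 case + 20 control samples each,
    planted shifts of 2 sigma, exponential survival with a per-unit-PA hazard
    ratio of 3 and ~30% censoring, and a 50-drug library with 3 instances per
    drug.
    """

    n_genes: int = 2000
    n_sets: int = 50
    set_size_range: tuple[int, int] = (20, 80)
    n_cancers: int = 3
    n_case: int = 20
    n_control: int = 20
    planted_up: dict[str, float] = field(default_factory=dict)  # set -> effect (sigma)
    planted_down: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 365.0
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.3
    n_drugs: int = 50
    n_instances: int = 3
    reversal_strength: float = 2.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducible fixtures")
        for name, value in (
            ("n_genes", self.n_genes), ("n_sets", self.n_sets),
            ("n_cancers", self.n_cancers), ("n_case", self.n_case),
            ("n_control", self.n_control), ("n_drugs", self.n_drugs),
            ("n_instances", self.n_instances),
        ):
            if value < 1:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.censoring_rate <= 1:
            raise ValidationError("censoring_rate must be in [0, 1]")
        lo, hi = self.set_size_range
        if not 2 <= lo <= hi:
            raise ValidationError("set_size_range must satisfy 2 <= lo <= hi")
        if hi > self.n_genes:
            raise ValidationError("set sizes cannot exceed the gene universe")


def gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes - 1))
    return [f"G{i:0{width}d}" for i in range(config.n_genes)]


def simulate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """Random non-overlapping-name gene sets drawn from the gene universe."""
    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config)
    lo, hi = config.set_size_range
    sets = {}
    for i in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(config.n_genes, size=size, replace=False)
        sets[f"SET_{i:03d}"] = [genes[j] for j in sorted(members)]
    return GeneSetCollection(sets)


def simulate_paired_cohort(
    config: SimulationConfig,
    sets: GeneSetCollection,
    cohort_id: str = "C0",
    seed: int | None = None,
) -> ExpressionMatrix:
    """One paired case/control cohort with planted pathway shifts.

    Background expression is log-normal: log2 values ~ Normal(mu_g, sigma_g)
    with per-gene mu_g ~ U(3, 8) and sigma_g ~ U(0.5, 1.5) (heteroscedastic,
    so variance-stabilization steps are exercised nontrivially). For each set
    in ``planted_up`` with effect delta, member genes gain +delta*sigma_g on
    the log2 scale in case samples; ``planted_down`` subtracts the shift.
    """
    for name in (*config.planted_up, *config.planted_down):
        if name not in sets.sets:
            raise ValidationError(f"planted set {name!r} not in the collection")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = gene_ids(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = config.n_case + config.n_control
    mu = rng.uniform(3.0, 8.0, size=config.n_genes)
    sigma = rng.uniform(0.5, 1.5, size=config.n_genes)
    log2x = rng.normal(mu[:, None], sigma[:, None], size=(config.n_genes, n))
    shift = np.zeros(config.n_genes)
    for name, delta in config.planted_up.items():
        idx = [gene_pos[g] for g in sets.sets[name]]
        shift[idx] += delta * sigma[idx]
    for name, delta in config.planted_down.items():
        idx = [gene_pos[g] for g in sets.sets[name]]
        shift[idx] -= delta * sigma[idx]
    log2x[:, : config.n_case] += shift[:, None]
    values = 2.0**log2x
    samples = [f"{cohort_id}_T{i:03d}" for i in range(config.n_case)] + [
        f"{cohort_id}_N{i:03d}" for i in range(config.n_control)
    ]
    condition = [CASE] * config.n_case + [CONTROL] * config.n_control
    return ExpressionMatrix(genes, samples, values, condition)


def simulate_survival_cohort(
    config: SimulationConfig,
    pa_scores: np.ndarray,
    sample_ids: list[str],
    seed: int | None = None,
) -> ClinicalTable:
    """Exponential survival tied to a per-patient pathway-activation score.

    The hazard for patient j is h0 * HR^z_j with z the standardized PA score,
    so HR is the hazard ratio per PA standard deviation. Censoring is
    independent uniform on [0, T95] applied to a ``censoring_rate`` fraction
    of patients (T95 = the 95th percentile of the drawn event times).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pa = np.asarray(pa_scores, dtype=float)
    if pa.size != len(sample_ids):
        raise ValidationError("PA scores and sample ids must align")
    sd = pa.std(ddof=0)
    z = (pa - pa.mean()) / sd if sd > 0 else np.zeros_like(pa)
    hazard = config.baseline_hazard * config.hazard_ratio**z
    t_event = rng.exponential(1.0 / hazard)
    time = t_event.copy()
    event = np.ones(pa.size, dtype=int)
    if config.censoring_rate > 0:
        censored = rng.random(pa.size) < config.censoring_rate
        t95 = np.percentile(t_event, 95)
        c_time = rng.uniform(0, t95, size=pa.size)
        apply = censored & (c_time < t_event)
        time[apply] = c_time[apply]
        event[apply] = 0
        if config.censoring_rate >= 1.0:
            time = np.minimum(t_event, c_time)
            event[:] = 0
    return ClinicalTable(list(sample_ids), time, event)


def simulate_perturbation_library(
    config: SimulationConfig,
    sets: GeneSetCollection,
    reverser_drugs: dict[str, list[str]] | None = None,
    seed: int | None = None,
) -> list[PerturbationProfile]:
    """Per-drug instance rankings; reversers suppress planted-up genes.

    ``reverser_drugs`` maps a drug id to the planted set names it reverses.
    Each instance's per-gene metric is N(0, 1) noise; for a reverser, genes
    of its target sets get an offset of -reversal_strength when the target
    was planted up (the drug pushes them down) and +reversal_strength when
    planted down. Decoy drugs are pure noise. Ranked lists sort descending
    with ties broken by gene id.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = gene_ids(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    reverser_drugs = reverser_drugs or {}
    for drug, targets in reverser_drugs.items():
        for t in targets:
            if t not in sets.sets:
                raise ValidationError(f"reverser target {t!r} not in the collection")
    profiles = []
    drug_ids = list(reverser_drugs) + [
        f"decoy_{i:03d}" for i in range(config.n_drugs - len(reverser_drugs))
    ]
    for drug in drug_ids:
        for k in range(config.n_instances):
            metric = rng.normal(0.0, 1.0, size=config.n_genes)
            for target in reverser_drugs.get(drug, ()):
                idx = [gene_pos[g] for g in sets.sets[target]]
                if target in config.planted_down:
                    metric[idx] += config.reversal_strength
                else:
                    metric[idx] -= config.reversal_strength
            ids, vals = _sort_genes(genes, metric)
            profiles.append(
                PerturbationProfile(drug, f"{drug}_inst{k}", RankedList(ids, vals))
            )
    return profiles


def simulate_study(
    config: SimulationConfig,
) -> tuple[
    GeneSetCollection,
    dict[str, ExpressionMatrix],
    dict[str, ClinicalTable],
    list[PerturbationProfile],
]:
    """Full synthetic study: sets, per-cancer cohorts + clinical, drug library.

    The first planted-up set drives survival in every cancer (its mean
    member expression on the log2 scale is the PA proxy), and one reverser
    drug ("reverser_000") targets every planted set.
    """
    sets = simulate_gene_sets(config)
    rng = np.random.default_rng(config.seed)
    cohorts: dict[str, ExpressionMatrix] = {}
    clinical: dict[str, ClinicalTable] = {}
    planted = list(config.planted_up) + list(config.planted_down)
    driver = planted[0] if planted else sets.names()[0]
    genes = gene_ids(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    driver_idx = [gene_pos[g] for g in sets.sets[driver]]
    for c in range(config.n_cancers):
        cancer = f"CANCER_{c}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cohorts[cancer] = simulate_paired_cohort(config, sets, cancer, seed=sub_seed)
        case_vals = cohorts[cancer].case_values()
        pa_proxy = np.log2(case_vals[driver_idx] + 1).mean(axis=0)
        case_ids = [
            s for s, cond in zip(cohorts[cancer].sample_ids, cohorts[cancer].condition)
            if cond == CASE
        ]
        clinical[cancer] = simulate_survival_cohort(
            config, pa_proxy, case_ids, seed=int(rng.integers(0, 2**31 - 1))
        )
    reversers = {"reverser_000": planted} if planted else None
    library = simulate_perturbation_library(
        config, sets, reversers, seed=int(rng.integers(0, 2**31 - 1))
    )
    return sets, cohorts, clinical, library
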