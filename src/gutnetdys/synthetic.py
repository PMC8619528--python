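"""Synthetic study-design generator.

Emulates the full cage experiment so every downstream stage is testable
without sequencing data: 120 activity samples (3 gut sections × 4
clothianidin doses × 5 cages × 2 replicates, sampled at day 7),
genus-structured compositions dominated by the honeybee core taxa, planted
inter-genus rank correlations, dose-dependent activity shifts, sporadic
low-activity genera, and survival (4000 bees over 28 days) and feeding
ledgers.

Activity model: a Gaussian copula over genera.  Latent standard normals
with a planted correlation matrix are pushed through per-genus lognormal
marginals (section profile mean + dose effect, per-genus log-sd).
Spearman's rho is invariant under the monotone marginal transform, so a
planted rank correlation survives to the absolute genus activities by
construction; the latent Pearson correlation needed for a Spearman target
ρ_s is 2·sin(π·ρ_s/6).  Genus activities are split into 1–4 ASVs by fixed
Dirichlet weights, scaled to a negative-binomial sequencing depth and
rounded to integer counts.

One caveat is inherent to compositional data: downstream correlation
screens run on *relative* activities, and dividing by the per-sample total
perturbs ranks whenever that total itself varies.  The perturbation scales
with the activity-share-weighted variance of the community log-total, so
planted correlations survive closure essentially intact when the planted
genera are mid-tier (a few percent of activity each) and the dominant taxa
are stable — which is how the defaults are arranged.  Strong *negative*
rank correlations between proportions are mathematically unreachable
outside that regime, no matter the copula.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from .types import (
    DOSES_PPB,
    GUT_SECTIONS,
    ActivityTable,
    Lineage,
    validate_feeding_ledger,
    validate_metadata,
    validate_survival_ledger,
)

logger = logging.getLogger("gutnetdys.synthetic")

__all__ = [
    "PlantedEdge",
    "SynthConfig",
    "generate_design",
    "generate_activity",
    "generate_lineages",
    "generate_survival",
    "generate_feeding",
    "generate_all",
]


@dataclass(frozen=True)
class PlantedEdge:
    """A target Spearman correlation between two genera, active in the
    listed sections/doses ("all" applies everywhere)."""

    genus_a: str
    genus_b: str
    rho: float
    sections: tuple[str, ...] | str = "all"
    doses: tuple[float, ...] | str = "all"

    def active_in(self, section: str, dose: float) -> bool:
        sec_ok = self.sections == "all" or section in self.sections
        dose_ok = self.doses == "all" or any(
            math.isclose(dose, d) for d in self.doses
        )
        return sec_ok and dose_ok


# Higher taxonomy used for the synthetic ASV lineages.
_GENUS_TAXONOMY: dict[str, tuple[str, str, str, str, str]] = {
    "Lactobacillus": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Pediococcus": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Bifidobacterium": ("Bacteria", "Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae"),
    "Gilliamella": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Orbales", "Orbaceae"),
    "Frischella": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Orbales", "Orbaceae"),
    "Snodgrassella": ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae"),
    "Bartonella": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Bartonellaceae"),
    "Bombella": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhodospirillales", "Acetobacteraceae"),
    "Parasaccharibacter": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhodospirillales", "Acetobacteraceae"),
    "Ralstonia": ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae"),
    "Devosia": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Devosiaceae"),
    "Leifsonia": ("Bacteria", "Actinobacteria", "Actinomycetia", "Micrococcales", "Microbacteriaceae"),
    "Flavobacterium": ("Bacteria", "Bacteroidota", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae"),
    "Moraxella": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Moraxellales", "Moraxellaceae"),
}


def _default_profiles() -> dict[str, dict[str, float]]:
    # Mean natural-log activity per genus per gut section: the rectum is
    # Lactobacillus/Bifidobacterium-dominated, the ileum Gilliamella/
    # Snodgrassella-dominated, the midgut mixed with lower biomass.
    return {
        "midgut": {
            "Lactobacillus": 6.5, "Gilliamella": 5.5, "Snodgrassella": 5.0,
            "Bifidobacterium": 5.0, "Frischella": 4.5, "Bartonella": 4.2,
            "Bombella": 4.2, "Parasaccharibacter": 4.4, "Pediococcus": 3.8,
            "unassigned": 4.8,
        },
        "ileum": {
            "Lactobacillus": 5.5, "Gilliamella": 6.5, "Snodgrassella": 6.2,
            "Bifidobacterium": 4.5, "Frischella": 5.2, "Bartonella": 4.0,
            "Bombella": 3.8, "Parasaccharibacter": 4.0, "Pediococcus": 3.5,
            "unassigned": 4.5,
        },
        "rectum": {
            "Lactobacillus": 7.0, "Gilliamella": 5.0, "Snodgrassella": 4.8,
            "Bifidobacterium": 6.0, "Frischella": 4.2, "Bartonella": 4.5,
            "Bombella": 3.8, "Parasaccharibacter": 4.0, "Pediococcus": 4.2,
            "unassigned": 4.6,
        },
    }


def _default_planted_edges() -> tuple[PlantedEdge, ...]:
    # The control carries more positive couplings than the exposed groups,
    # and negative couplings appear under exposure — the qualitative
    # dysbiosis pattern.  Edges are planted among mid-tier genera (< ~10%
    # of community activity): correlations between proportions equal the
    # planted rank correlations only when neither partner dominates the
    # per-sample total, because closure (dividing by the total) perturbs
    # the ranks of dominant taxa.
    return (
        PlantedEdge("Bartonella", "Bombella", 0.95, "all", "all"),
        PlantedEdge("Bartonella", "Parasaccharibacter", 0.95, "all", (0.0,)),
        PlantedEdge("Bombella", "Parasaccharibacter", 0.95, "all", (0.0,)),
        PlantedEdge("Frischella", "Pediococcus", 0.9, "all", (0.0, 10.0)),
        PlantedEdge("Frischella", "Pediococcus", -0.9, "all", (0.1,)),
        PlantedEdge("Parasaccharibacter", "Pediococcus", -0.9, "all", (1.0,)),
    )


def _default_dose_effects() -> dict[str, dict[float, float]]:
    # log2 shifts of mean activity at each nonzero dose.  Frischella drops
    # everywhere, Bifidobacterium rises everywhere; Gilliamella and
    # Lactobacillus vary with dose.
    return {
        "Frischella": {0.1: -1.0, 1.0: -1.0, 10.0: -1.0},
        "Bifidobacterium": {0.1: 0.5, 1.0: 0.5, 10.0: 0.5},
        "Gilliamella": {0.1: -0.2, 1.0: -1.6, 10.0: 0.7},
        "Lactobacillus": {0.1: 0.3, 1.0: 0.2, 10.0: -0.3},
    }


@dataclass
class SynthConfig:
    """All knobs of the synthetic experiment; defaults reproduce the study
    design (120 samples, 4000 bees, 28 days)."""

    seed: int = 0
    sections: tuple[str, ...] = GUT_SECTIONS
    doses_ppb: tuple[float, ...] = DOSES_PPB
    cages_per_group: int = 5
    replicates_per_cage: int = 2
    bees_per_cage: int = 200
    horizon_days: int = 28
    sampling_days: tuple[int, ...] = (7, 14, 21, 28)
    bees_sampled_per_cage: int = 20
    timepoint_day: int = 7

    genus_profiles: dict[str, dict[str, float]] = field(default_factory=_default_profiles)
    #: Log-activity s.d. across samples: base value plus per-genus
    #: overrides.  The dominant core genera are modelled as stable (small
    #: sd) and the planted mid-tier genera as dynamic (large sd) — besides
    #: being the usual shape of microbiome variability, a near-constant
    #: community total is what lets planted rank correlations survive the
    #: closure to relative activities (see module docstring).
    genus_sigma: float = 0.6
    sigma_overrides: dict[str, float] = field(default_factory=lambda: {
        "Lactobacillus": 0.4, "Gilliamella": 0.4, "Snodgrassella": 0.4,
        "Bifidobacterium": 0.4, "Bartonella": 1.2, "Bombella": 1.2,
        "Parasaccharibacter": 1.2, "Pediococcus": 1.2, "Frischella": 1.2,
    })
    planted_edges: tuple[PlantedEdge, ...] = field(default_factory=_default_planted_edges)
    dose_effects: dict[str, dict[float, float]] = field(default_factory=_default_dose_effects)

    depth_mean: float = 25000.0
    depth_dispersion: float = 5.0
    max_asvs_per_genus: int = 4

    rare_genera: tuple[str, ...] = (
        "Ralstonia", "Devosia", "Leifsonia", "Flavobacterium", "Moraxella",
    )
    rare_fraction: float = 5e-5
    rare_max_samples: int = 2

    #: Daily per-bee death hazard per dose.  The default schedule encodes the
    #: inverse dose–mortality ordering observed in the experiment:
    #: hazard(0.1) > hazard(1) > hazard(10) ≈ hazard(0), tuned so constant
    #: hazards put the group median survivals near days 16 / 20 / 22 / 22.
    hazards: dict[float, float] = field(default_factory=lambda: {
        0.0: 0.0310, 0.1: 0.0424, 1.0: 0.0341, 10.0: 0.0315,
    })

    #: Mean syrup intake in g/bee/day per dose; the 1 ppb group feeds most.
    intake_g_per_bee: dict[float, float] = field(default_factory=lambda: {
        0.0: 0.050, 0.1: 0.052, 1.0: 0.060, 10.0: 0.048,
    })
    feeding_noise_sd: float = 0.3  # grams per cage-day

    #: Planted correlations must survive nearest-positive-definite repair to
    #: within this absolute deviation (in Spearman units).
    pd_repair_tolerance: float = 0.05

    def __post_init__(self) -> None:
        for edge in self.planted_edges:
            if not -1.0 <= edge.rho <= 1.0:
                raise ValueError(f"planted rho {edge.rho} outside [-1, 1]")
        for dose, h in self.hazards.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"hazard {h} for dose {dose} outside [0, 1]")
        for section in self.sections:
            if section not in self.genus_profiles:
                raise ValueError(f"no genus profile for section {section!r}")

    @property
    def modeled_genera(self) -> list[str]:
        return list(self.genus_profiles[self.sections[0]])

    def with_seed(self, seed: int) -> "SynthConfig":
        return dataclasses.replace(self, seed=seed)


def _streams(config: SynthConfig) -> dict[str, np.random.SeedSequence]:
    """Named child seed sequences so each stage has its own stream."""
    children = np.random.SeedSequence(config.seed).spawn(4)
    return dict(zip(("asv_structure", "activity", "survival", "feeding"), children))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(config: SynthConfig) -> pd.DataFrame:
    """Sample metadata: one row per section × dose × cage × replicate.

    The default design yields 3·4·5·2 = 120 rows, all at day 7 (the RNA
    sampling time point).  Row order and sample ids are deterministic.
    """
    rows = []
    for section in config.sections:
        for dose in config.doses_ppb:
            for cage in range(1, config.cages_per_group + 1):
                for rep in range(1, config.replicates_per_cage + 1):
                    rows.append(
                        {
                            "sample_id": f"{section}_d{dose:g}_c{cage}_r{rep}",
                            "cage": f"d{dose:g}_c{cage}",
                            "gut_section": section,
                            "dose_ppb": float(dose),
                            "replicate": rep,
                            "timepoint_day": config.timepoint_day,
                        }
                    )
    return validate_metadata(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def _asv_structure(config: SynthConfig) -> dict[str, np.ndarray]:
    """Fixed Dirichlet split of each genus into 1–4 ASVs (rare genera: 1)."""
    rng = np.random.default_rng(_streams(config)["asv_structure"])
    weights: dict[str, np.ndarray] = {}
    for genus in config.modeled_genera:
        n_asvs = int(rng.integers(1, config.max_asvs_per_genus + 1))
        weights[genus] = rng.dirichlet(np.full(n_asvs, 5.0))
    for genus in config.rare_genera:
        weights[genus] = np.ones(1)
    return weights


def generate_lineages(config: SynthConfig) -> dict[str, Lineage]:
    """Synthetic lineage per ASV id, matching :func:`generate_activity`."""
    lineages: dict[str, Lineage] = {}
    for genus, weights in _asv_structure(config).items():
        for k in range(len(weights)):
            asv_id = f"ASV_{genus}_{k + 1}"
            if genus == "unassigned":
                lineages[asv_id] = Lineage.unassigned()
            else:
                sk, phylum, cls, order, family = _GENUS_TAXONOMY.get(
                    genus,
                    ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     "unclassified_Gammaproteobacteria", "unclassified_order"),
                )
                lineages[asv_id] = Lineage((sk, phylum, cls, order, family, genus, ""))
    return lineages


def _latent_correlation(
    config: SynthConfig, genera: list[str], section: str, dose: float
) -> np.ndarray:
    """Latent Pearson matrix realising the planted Spearman targets, after
    nearest-positive-definite repair when needed."""
    g = len(genera)
    target_s = np.eye(g)
    index = {genus: i for i, genus in enumerate(genera)}
    for edge in config.planted_edges:
        if not edge.active_in(section, dose):
            continue
        if edge.genus_a not in index or edge.genus_b not in index:
            continue
        i, j = index[edge.genus_a], index[edge.genus_b]
        target_s[i, j] = target_s[j, i] = edge.rho
    latent = 2.0 * np.sin(np.pi * target_s / 6.0)
    np.fill_diagonal(latent, 1.0)

    eigvals = np.linalg.eigvalsh(latent)
    if eigvals.min() < 1e-10:
        repaired = corr_nearest(latent, threshold=1e-8, n_fact=200)
        achieved_s = (6.0 / np.pi) * np.arcsin(repaired / 2.0)
        dev = np.abs(achieved_s - target_s).max()
        logger.info(
            "condition (%s, %g ppb): planted matrix repaired to nearest PD "
            "(max Spearman deviation %.4f)", section, dose, dev,
        )
        if dev > config.pd_repair_tolerance:
            raise ValueError(
                f"planted correlations for ({section}, {dose:g} ppb) are "
                f"inconsistent: nearest-PD repair moved a target by {dev:.3f} "
                f"(> {config.pd_repair_tolerance}); weaken the rho targets"
            )
        latent = repaired
    return latent


def generate_activity(
    design: pd.DataFrame, config: SynthConfig
) -> ActivityTable:
    """ASV-level integer activity table for every sample in ``design``.

    Per condition subset: correlated latent normals (Gaussian copula) →
    lognormal genus activities (section profile + dose effect) → Dirichlet
    ASV split → negative-binomial sequencing depth → rounded counts.
    Rare genera are injected in at most ``rare_max_samples`` samples per
    condition at below 0.01% relative activity.
    """
    weights = _asv_structure(config)
    genera = config.modeled_genera
    asv_ids = [f"ASV_{g}_{k + 1}" for g in list(genera) + list(config.rare_genera)
               for k in range(len(weights[g]))]

    conditions = [
        (section, dose)
        for section in config.sections
        for dose in config.doses_ppb
    ]
    activity_seed = _streams(config)["activity"]
    cond_seeds = activity_seed.spawn(len(conditions))

    counts = pd.DataFrame(
        0.0, index=design["sample_id"], columns=asv_ids
    )
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)

    for (section, dose), seed in zip(conditions, cond_seeds):
        rng = np.random.default_rng(seed)
        ids = design.loc[
            (design["gut_section"] == section) & (design["dose_ppb"] == dose),
            "sample_id",
        ].tolist()
        n = len(ids)
        if n == 0:
            continue
        latent = _latent_correlation(config, genera, section, dose)
        chol = np.linalg.cholesky(latent + 1e-12 * np.eye(len(genera)))
        z = rng.standard_normal((n, len(genera))) @ chol.T

        mu = np.array([
            config.genus_profiles[section][g]
            + math.log(2.0) * config.dose_effects.get(g, {}).get(dose, 0.0)
            for g in genera
        ])
        sigma = np.array([
            config.sigma_overrides.get(g, config.genus_sigma) for g in genera
        ])
        activity = np.exp(mu + sigma * z)  # (n, g)
        comp = activity / activity.sum(axis=1, keepdims=True)
        depths = rng.negative_binomial(nb_n, nb_p, size=n).astype(float)
        depths = np.maximum(depths, 1000.0)  # floor: no failed libraries

        for gi, genus in enumerate(genera):
            genus_counts = comp[:, gi] * depths  # per sample
            split = np.outer(genus_counts, weights[genus])
            for k in range(len(weights[genus])):
                counts.loc[ids, f"ASV_{genus}_{k + 1}"] = np.round(split[:, k])

        # sporadic low-activity genera
        for genus in config.rare_genera:
            k = int(rng.integers(1, config.rare_max_samples + 1))
            chosen = rng.choice(n, size=min(k, n), replace=False)
            for s in chosen:
                c = max(1.0, np.round(config.rare_fraction * depths[s]))
                counts.loc[ids[s], f"ASV_{genus}_1"] = c

    counts = counts.loc[:, counts.sum(axis=0) > 0]  # drop empty ASV columns
    return ActivityTable(counts)


# ---------------------------------------------------------------------------
# survival and feeding
# ---------------------------------------------------------------------------

def generate_survival(config: SynthConfig) -> pd.DataFrame:
    """Per-cage per-day survival ledger.

    Daily deaths are binomial draws at the dose's constant hazard; the
    weekly 20-bee samplings are recorded as right-censoring at the end of
    the sampling day.  The default design starts 200 × 5 × 4 = 4000 bees.
    """
    rng = np.random.default_rng(_streams(config)["survival"])
    rows = []
    for dose in config.doses_ppb:
        hazard = config.hazards[dose]
        for cage in range(1, config.cages_per_group + 1):
            alive = config.bees_per_cage
            for day in range(1, config.horizon_days + 1):
                at_risk = alive
                deaths = int(rng.binomial(alive, hazard)) if alive > 0 else 0
                alive -= deaths
                censored = 0
                if day in config.sampling_days and alive > 0:
                    censored = min(config.bees_sampled_per_cage, alive)
                    alive -= censored
                rows.append(
                    {
                        "group": f"{dose:g} ppb",
                        "cage": f"d{dose:g}_c{cage}",
                        "day": day,
                        "n_at_risk": at_risk,
                        "deaths": deaths,
                        "censored": censored,
                    }
                )
    return validate_survival_ledger(pd.DataFrame(rows), horizon=config.horizon_days)


def generate_feeding(
    config: SynthConfig, survival_ledger: pd.DataFrame
) -> pd.DataFrame:
    """Per-cage per-day syrup consumption driven by the survival ledger.

    cage mass = per-bee intake(dose) × mean(alive before, alive after)
    + Gaussian noise, truncated at zero.
    """
    rng = np.random.default_rng(_streams(config)["feeding"])
    dose_of_group = {f"{d:g} ppb": d for d in config.doses_ppb}
    rows = []
    for row in survival_ledger.itertuples(index=False):
        dose = dose_of_group[row.group]
        alive_prev = int(row.n_at_risk)
        alive_now = int(row.n_at_risk - row.deaths - row.censored)
        mean_alive = (alive_prev + alive_now) / 2.0
        mass = config.intake_g_per_bee[dose] * mean_alive
        if config.feeding_noise_sd > 0:
            mass += rng.normal(0.0, config.feeding_noise_sd)
        rows.append(
            {
                "group": row.group,
                "cage": row.cage,
                "day": row.day,
                "syrup_consumed": max(0.0, mass),
                "alive_prev": alive_prev,
                "alive_now": alive_now,
            }
        )
    return validate_feeding_ledger(pd.DataFrame(rows))


def recovery_benchmark_config(
    seed: int, rho: float = 0.95, null: bool = False
) -> SynthConfig:
    """Benchmark configuration for planted-edge recovery experiments.

    One condition (midgut control) of 10 samples: a stable dominant
    background genus (85% of activity, small log-sd — keeping the
    per-sample total, hence the closure denominator, nearly rank-neutral)
    plus six dynamic test genera carrying three disjoint planted pairs at
    ±``rho``.  With ``null=True`` no correlations are planted, for
    false-edge-rate experiments.  Seven genera give a Bonferroni family of
    21 pairs, an n = 10 detection threshold of |rho| ≈ 0.82 — clearable by
    a planted 0.95 — versus ≈ 0.87 for the full ten-genus community, which
    0.95 cannot clear reliably at this sample size.
    """
    test_genera = ("Bartonella", "Bombella", "Parasaccharibacter",
                   "Pediococcus", "Frischella", "Moraxella")
    profiles = {"midgut": {g: 5.0 for g in test_genera}}
    profiles["midgut"]["Lactobacillus"] = 8.6
    if null:
        planted: tuple[PlantedEdge, ...] = ()
    else:
        planted = (
            PlantedEdge("Bartonella", "Bombella", rho, "all", "all"),
            PlantedEdge("Parasaccharibacter", "Pediococcus", rho, "all", "all"),
            PlantedEdge("Frischella", "Moraxella", -rho, "all", "all"),
        )
    return SynthConfig(
        seed=seed,
        sections=("midgut",),
        doses_ppb=(0.0,),
        genus_profiles=profiles,
        sigma_overrides={**{g: 1.2 for g in test_genera},
                         "Lactobacillus": 0.05},
        planted_edges=planted,
        dose_effects={},
        rare_genera=(),
    )


def generate_all(config: SynthConfig) -> dict:
    """Generate the complete synthetic study: metadata, ASV activity,
    lineages, survival and feeding ledgers."""
    design = generate_design(config)
    table = generate_activity(design, config)
    survival = generate_survival(config)
    return {
        "meta": design,
        "activity": table,
        "lineages": generate_lineages(config),
        "survival": survival,
        "feeding": generate_feeding(config, survival),
    }
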