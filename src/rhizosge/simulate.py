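"""Synthetic co-inoculation experiments with known genetic architecture.

The generator draws a complete experiment — design, shoot masses, nodule
tallies, nodule CFU counts — from the same statistical structure the analysis
assumes, with every latent effect stored for parameter-recovery tests.

Generative model
----------------
Each strain carries a *quality* value ``q_i`` (its benefit to the host, in
arbitrary units).  For a two-strain pot with strains i (focal) and j:

* expected nodule share of i is ``logistic(choice_strength * (q_i - q_j))``
  — the partner-choice signal;
* the focal-strain latent nodule score is
  ``total_mean * share + marker + d_i + s_j + g_ij + b_block + p_pot + e``
  with independent Gaussian direct (d), social (s), ordered-pair interaction
  (g), block, pot and residual effects;
* integer tallies are recovered by drawing a Poisson mixed-colour count and
  rounding singles so that ``singles + 0.5 * mixed`` tracks the latent score
  (``gaussian_mode=True`` skips the rounding and emits real-valued scores);
* log shoot mass is an occupancy-weighted mixture of the two strains'
  one-strain expectations (the benefit of partner choice; switchable off for
  null simulations) plus strain effects entering with equal focal/competitor
  weight, an unordered-pair interaction, block and residual terms;
* single-colour nodule CFU is log-normal with log-mean linear in quality
  (``cfu_link``); mixed-nodule CFU is split with expected share logistic in
  the quality difference — the sanctions signal.

By default the quality axis drives host benefit, nodulation success and CFU
proliferation simultaneously — the empirically motivated confounding; the
coupling switches allow partner-choice-free and sanctions-free nulls.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .datamodel import (
    TREATMENT_CONTROL,
    TREATMENT_ONE_STRAIN,
    TREATMENT_TWO_STRAIN,
    NoduleCFU,
    NoduleTally,
    PlantUnit,
    StrainPotObservation,
    generate_design,
)
from .tables import ExperimentData


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class NoduleVariances:
    """Variance components of the latent per-strain nodule score.

    Defaults put 32/14/7/3/7/37 percent of a total phenotypic variance of 9
    into DGE / main SGE / G x G / block / pot / residual.
    """

    dge: float = 2.88
    sge: float = 1.26
    gxg: float = 0.63
    block: float = 0.27
    pot: float = 0.63
    resid: float = 3.33

    def proportions(self) -> dict[str, float]:
        total = self.dge + self.sge + self.gxg + self.block + self.pot + self.resid
        if total == 0:
            return {k: float("nan") for k in asdict(self)}
        return {k: v / total for k, v in asdict(self).items()}


@dataclass(frozen=True)
class ShootVariances:
    """Variance components of log shoot mass (strain effect enters twice per pot).

    Defaults put 2.9/2.9/6.3/10.9/77 percent of a total of 0.25 into
    DGE / SGE (one shared strain variance) / G x G / block / residual.
    """

    strain: float = 0.00725
    gxg: float = 0.01575
    block: float = 0.02725
    resid: float = 0.1925


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative configuration; the seed determines the dataset bit-for-bit."""

    n_strains: int = 8
    n_blocks: int = 8
    n_controls_per_block: int = 2
    seed: int = 0
    strain_quality: Optional[tuple[float, ...]] = None  # default: linspace(0, 1)

    # nodulation
    nodule_total_mean: float = 16.0       # expected nodules per two-strain pot
    choice_strength: float = 3.0          # logistic slope, share vs quality difference
    quality_nodulation_slope: float = 8.0  # one-strain nodules per unit quality
    marker_effect: float = 0.0            # additive green-marker offset on the score
    mixed_rate: float = 1.5               # Poisson mean of mixed-colour nodules
    nodule_var: NoduleVariances = field(default_factory=NoduleVariances)
    gaussian_mode: bool = False           # keep latent real-valued scores (no tallies)

    # host benefit (log-scale shoot mass)
    shoot_log_mean: float = -1.204        # log grams for a quality-0 strain (~0.3 g)
    control_log_mean: float = -3.0        # uninoculated baseline (~0.05 g)
    quality_benefit_slope: float = 1.0    # log-scale benefit per unit quality
    couple_benefit_to_occupancy: bool = True
    shoot_var: ShootVariances = field(default_factory=ShootVariances)

    # within-nodule proliferation
    cfu_log_mean: float = 11.5            # ~1e5 CFU for a quality-0 strain
    cfu_link: float = 1.0                 # log-CFU (and intra-nodule logit) per unit quality
    cfu_log_sd: float = 0.5
    cfu_concentration: float = 20.0       # Beta concentration of mixed-nodule shares
    cfu_blocks: int = 2                   # nodule dissection restricted to first blocks

    def __post_init__(self) -> None:
        for name, value in {**asdict(self.nodule_var), **asdict(self.shoot_var)}.items():
            if value < 0:
                raise ConfigError(f"negative variance component {name!r}")
        if self.strain_quality is not None and len(self.strain_quality) != self.n_strains:
            raise ConfigError("strain_quality length disagrees with n_strains")
        if self.n_strains < 2:
            raise ConfigError("need at least 2 strains")

    def quality(self) -> np.ndarray:
        if self.strain_quality is not None:
            return np.asarray(self.strain_quality, float)
        return np.linspace(0.0, 1.0, self.n_strains)


@dataclass
class SyntheticDataset:
    """A simulated experiment plus the latent truths that generated it."""

    config: SimulationConfig
    data: ExperimentData
    truth: dict

    @property
    def strains(self) -> list[str]:
        return sorted({s for u in self.data.units for s in u.strain_ids})


def _draw_effects(config: SimulationConfig, rng: np.random.Generator) -> dict:
    S, B = config.n_strains, config.n_blocks
    nv, sv = config.nodule_var, config.shoot_var
    return {
        "quality": config.quality(),
        "dge": rng.normal(0, np.sqrt(nv.dge), S),
        "sge": rng.normal(0, np.sqrt(nv.sge), S),
        "gxg_ordered": rng.normal(0, np.sqrt(nv.gxg), (S, S)),
        "block_nodule": rng.normal(0, np.sqrt(nv.block), B),
        "strain_shoot": rng.normal(0, np.sqrt(sv.strain), S),
        "gxg_shoot": {
            (i, j): rng.normal(0, np.sqrt(sv.gxg))
            for i in range(S) for j in range(i + 1, S)
        },
        "block_shoot": rng.normal(0, np.sqrt(sv.block), B),
    }


def simulate_phenotypes(config: SimulationConfig) -> SyntheticDataset:
    """Generate design, shoot masses, nodule tallies and occupancy records."""
    ss = np.random.SeedSequence(config.seed)
    rng_eff, rng_nod, rng_shoot, _rng_cfu = [np.random.default_rng(c) for c in ss.spawn(4)]

    units = generate_design(config.n_strains, config.n_blocks, config.n_controls_per_block)
    strains = sorted({s for u in units for s in u.strain_ids})
    sidx = {s: i for i, s in enumerate(strains)}
    eff = _draw_effects(config, rng_eff)
    q = eff["quality"]
    nv, sv = config.nodule_var, config.shoot_var
    one_strain_log_mass = config.shoot_log_mean + config.quality_benefit_slope * q

    tallies: list[NoduleTally] = []
    observations: list[StrainPotObservation] = []
    new_units: list[PlantUnit] = []
    pot_effects: dict[str, float] = {}
    resid_nodule: list[float] = []       # realized two-strain residual draws
    score_noise: list[float] = []        # discretization offsets (score - latent)
    resid_shoot: list[float] = []        # realized two-strain log-shoot residuals

    for u in units:
        b = u.block - 1
        if u.treatment == TREATMENT_CONTROL:
            log_w = (config.control_log_mean + eff["block_shoot"][b]
                     + rng_shoot.normal(0, np.sqrt(sv.resid)))
            new_units.append(replace(u, shoot_mass=float(np.exp(log_w))))
            continue

        if u.treatment == TREATMENT_ONE_STRAIN:
            i = sidx[u.strain_ids[0]]
            latent = (config.nodule_total_mean
                      + config.quality_nodulation_slope * (q[i] - q.mean())
                      + (config.marker_effect if u.labels[0].marker == "green" else 0.0)
                      + eff["dge"][i] + eff["block_nodule"][b]
                      + rng_nod.normal(0, np.sqrt(nv.resid)))
            latent = max(latent, 0.0)
            log_w = (one_strain_log_mass[i] + eff["strain_shoot"][i]
                     + eff["block_shoot"][b] + rng_shoot.normal(0, np.sqrt(sv.resid)))
            unit = replace(u, shoot_mass=float(np.exp(log_w)))
            new_units.append(unit)
            if config.gaussian_mode:
                score = float(latent)
                observations.append(StrainPotObservation(
                    u.pot_id, u.strain_ids[0], None, u.labels[0].marker,
                    score, 1.0 if score > 0 else None))
            else:
                singles = int(max(np.rint(latent), 0))
                tallies.append(NoduleTally(u.pot_id, {u.strain_ids[0]: singles}, 0))
            continue

        # two-strain pot
        (la, lb) = u.labels
        i, j = sidx[la.strain_id], sidx[lb.strain_id]
        p_pot = rng_nod.normal(0, np.sqrt(nv.pot))
        pot_effects[u.pot_id] = float(p_pot)
        latents = {}
        for (focal, comp, lab) in ((i, j, la), (j, i, lb)):
            share = expit(config.choice_strength * (q[focal] - q[comp]))
            e = rng_nod.normal(0, np.sqrt(nv.resid))
            resid_nodule.append(float(e))
            latents[focal] = (
                config.nodule_total_mean * share
                + (config.marker_effect if lab.marker == "green" else 0.0)
                + eff["dge"][focal] + eff["sge"][comp] + eff["gxg_ordered"][focal, comp]
                + eff["block_nodule"][b] + p_pot + e
            )
        scores: dict[int, float] = {}
        if config.gaussian_mode:
            for k in (i, j):
                scores[k] = max(float(latents[k]), 0.0)
        else:
            mixed = int(rng_nod.poisson(config.mixed_rate))
            singles = {k: int(max(np.rint(latents[k] - 0.5 * mixed), 0)) for k in (i, j)}
            tallies.append(NoduleTally(
                u.pot_id,
                {strains[k]: singles[k] for k in (i, j)},
                mixed,
            ))
            scores = {k: singles[k] + 0.5 * mixed for k in (i, j)}
        for k in (i, j):
            score_noise.append(float(scores[k] - latents[k]))

        total = scores[i] + scores[j]
        prop_i = scores[i] / total if total > 0 else None
        if config.gaussian_mode:
            for (focal, comp, lab) in ((i, j, la), (j, i, lb)):
                prop = (scores[focal] / total) if total > 0 else None
                observations.append(StrainPotObservation(
                    u.pot_id, strains[focal], strains[comp], lab.marker,
                    scores[focal], prop))

        # host benefit: occupancy-weighted mixture of one-strain expectations
        wa, wb = np.exp(one_strain_log_mass[i]), np.exp(one_strain_log_mass[j])
        if config.couple_benefit_to_occupancy and prop_i is not None:
            w_det = prop_i * wa + (1.0 - prop_i) * wb
        else:
            w_det = 0.5 * (wa + wb)
        key = (min(i, j), max(i, j))
        e_shoot = rng_shoot.normal(0, np.sqrt(sv.resid))
        resid_shoot.append(float(e_shoot))
        log_w = (np.log(w_det)
                 + eff["strain_shoot"][i] + eff["strain_shoot"][j]
                 + eff["gxg_shoot"][key] + eff["block_shoot"][b] + e_shoot)
        new_units.append(replace(u, shoot_mass=float(np.exp(log_w))))

    eff["pot"] = pot_effects
    eff["resid_nodule"] = np.array(resid_nodule)
    eff["score_noise"] = np.array(score_noise)
    eff["resid_shoot"] = np.array(resid_shoot)
    eff["true_nodule_proportions"] = config.nodule_var.proportions()
    data = ExperimentData(
        units=new_units,
        tallies=tallies,
        precomputed_observations=observations if config.gaussian_mode else None,
    )
    return SyntheticDataset(config=config, data=data, truth=eff)


def simulate_cfu(config: SimulationConfig, dataset: SyntheticDataset) -> list[NoduleCFU]:
    """Draw per-nodule CFU counts for the dissected-block subset.

    One nodule per one-strain plant; up to two single-colour nodules and one
    mixed-colour nodule per two-strain plant, following the tally.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])
    strains = dataset.strains
    sidx = {s: i for i, s in enumerate(strains)}
    q = config.quality()
    tallies = {t.pot_id: t for t in dataset.data.tallies}
    cfus: list[NoduleCFU] = []

    def draw_single(pot_id: str, nod_id: str, strain: str) -> NoduleCFU:
        mu = config.cfu_log_mean + config.cfu_link * q[sidx[strain]]
        count = int(np.rint(np.exp(rng.normal(mu, config.cfu_log_sd))))
        return NoduleCFU(pot_id, nod_id, "single_colour", {strain: count})

    for u in dataset.data.units:
        if u.block > config.cfu_blocks or u.treatment == TREATMENT_CONTROL:
            continue
        tally = tallies.get(u.pot_id)
        if tally is None:
            continue
        if u.treatment == TREATMENT_ONE_STRAIN:
            strain = u.strain_ids[0]
            if tally.singles.get(strain, 0) > 0:
                cfus.append(draw_single(u.pot_id, f"{u.pot_id}-n1", strain))
            continue
        n = 1
        for strain in u.strain_ids:
            if tally.singles.get(strain, 0) > 0:
                cfus.append(draw_single(u.pot_id, f"{u.pot_id}-n{n}", strain))
                n += 1
        if tally.mixed > 0:
            a, b = u.strain_ids
            total = np.exp(rng.normal(
                config.cfu_log_mean
                + config.cfu_link * 0.5 * (q[sidx[a]] + q[sidx[b]]),
                config.cfu_log_sd,
            ))
            mean_share = float(expit(config.cfu_link * (q[sidx[a]] - q[sidx[b]])))
            kappa = config.cfu_concentration
            share = float(rng.beta(mean_share * kappa, (1.0 - mean_share) * kappa))
            ca = int(np.rint(total * share))
            cb = int(max(np.rint(total) - ca, 0))
            cfus.append(NoduleCFU(u.pot_id, f"{u.pot_id}-n{n}", "mixed_colour",
                                  {a: ca, b: cb}))
    return cfus


def simulate_experiment(config: SimulationConfig) -> SyntheticDataset:
    """Phenotypes plus CFU tables in one call."""
    ds = simulate_phenotypes(config)
    ds.data.cfus = simulate_cfu(config, ds)
    return ds
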