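"""Simulator contracts: determinism, degenerate configs, moments, signatures."""

import dataclasses

import numpy as np
import pytest

from rhizosge import (
    NoduleVariances,
    ShootVariances,
    SimulationConfig,
    fit_means_regression,
    genotypic_means,
    simulate_cfu,
    simulate_experiment,
    simulate_phenotypes,
)
from rhizosge.simulate import ConfigError
from rhizosge.tables import nodules_frame, plants_frame, validate


def test_same_seed_identical_dataset():
    cfg = SimulationConfig(n_strains=4, n_blocks=2, seed=99)
    a, b = simulate_experiment(cfg), simulate_experiment(cfg)
    assert plants_frame(a.data.units).equals(plants_frame(b.data.units))
    assert nodules_frame(a.data.tallies).equals(nodules_frame(b.data.tallies))
    assert [(c.pot_id, c.nodule_id, c.cfu) for c in a.data.cfus] == \
           [(c.pot_id, c.nodule_id, c.cfu) for c in b.data.cfus]
    c = simulate_experiment(dataclasses.replace(cfg, seed=100))
    assert not plants_frame(a.data.units).equals(plants_frame(c.data.units))


def test_degenerate_config_gives_even_occupancy():
    """All variances, marker and choice at zero: both strains in every pot
    have equal expected scores; realized proportions are exactly 0.5."""
    cfg = SimulationConfig(
        n_strains=3, n_blocks=2, seed=1,
        choice_strength=0.0, marker_effect=0.0, quality_nodulation_slope=0.0,
        nodule_var=NoduleVariances(0, 0, 0, 0, 0, 0),
        shoot_var=ShootVariances(0, 0, 0, 0),
    )
    ds = simulate_phenotypes(cfg)
    props = [o.nodule_proportion for o in ds.data.observations()
             if o.competitor_strain is not None and o.nodule_proportion is not None]
    assert props and all(p == pytest.approx(0.5) for p in props)


@pytest.mark.parametrize("gaussian", [False, True])
def test_generated_data_passes_validation(gaussian):
    cfg = SimulationConfig(n_strains=4, n_blocks=3, seed=5, gaussian_mode=gaussian)
    ds = simulate_experiment(cfg)
    validate(ds.data)  # raises on any inconsistency
    for obs in ds.data.observations():
        assert obs.nodule_score >= 0


def test_block_effect_moments():
    """Across many blocks, the realized block-effect variance approaches its target."""
    cfg = SimulationConfig(n_strains=2, n_blocks=400, n_controls_per_block=0, seed=3)
    ds = simulate_phenotypes(cfg)
    target = cfg.nodule_var.block
    realized = np.var(ds.truth["block_nodule"], ddof=1)
    assert realized == pytest.approx(target, rel=0.25)


def test_partner_choice_signature_positive_slope():
    """With choice coupled to quality, the occupancy-vs-benefit genotypic-mean
    slope is positive across replicate simulations."""
    slopes = []
    for seed in range(5):
        ds = simulate_phenotypes(SimulationConfig(n_strains=6, n_blocks=4, seed=seed))
        benefit = genotypic_means(ds.data, "shoot_mass")["mean"]
        occupancy = genotypic_means(ds.data, "nodule_proportion")["mean"]
        slopes.append(fit_means_regression(benefit, occupancy).slope)
    assert np.mean(slopes) > 0
    assert sum(s > 0 for s in slopes) >= 4


def test_cfu_link_null_and_power():
    """cfu_link = 0 leaves the among-nodule regression flat at roughly the nominal
    rate; a strong link drives it positive and significant in most replicates."""
    null_rej, power_rej, power_slopes = 0, 0, []
    for seed in range(12):
        # choice off so every strain keeps single-colour nodules to dissect
        base = SimulationConfig(n_strains=8, n_blocks=4, seed=seed, cfu_blocks=4,
                                choice_strength=0.0)
        for link, strong in ((0.0, False), (3.0, True)):
            ds = simulate_experiment(dataclasses.replace(base, cfu_link=link))
            benefit = genotypic_means(ds.data, "shoot_mass")["mean"]
            cfu = genotypic_means(ds.data, "cfu_single")["mean"]
            res = fit_means_regression(benefit, cfu)
            if strong:
                power_rej += res.p_value < 0.05
                power_slopes.append(res.slope)
            else:
                null_rej += res.p_value < 0.05
    assert null_rej <= 3          # ~ nominal 5% of 12, with binomial slack
    # the CFU-benefit relation is convex, so a linear fit leaves power short of 1
    assert power_rej >= 9
    assert all(s > 0 for s in power_slopes)


def test_gaussian_mode_skips_discretization():
    ds = simulate_phenotypes(SimulationConfig(n_strains=3, n_blocks=2, seed=8,
                                              gaussian_mode=True))
    assert not ds.data.tallies
    scores = [o.nodule_score for o in ds.data.observations()]
    assert any(s % 0.5 != 0 for s in scores)


def test_cfu_restricted_to_dissected_blocks(small_dataset):
    cfg = small_dataset.config
    assert {u.block for u in small_dataset.data.units
            for c in small_dataset.data.cfus if c.pot_id == u.pot_id} <= \
        set(range(1, cfg.cfu_blocks + 1))
    again = simulate_cfu(cfg, small_dataset)
    assert [(c.pot_id, c.nodule_id, c.cfu) for c in again] == \
           [(c.pot_id, c.nodule_id, c.cfu) for c in small_dataset.data.cfus]


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(nodule_var=NoduleVariances(dge=-1.0))
    with pytest.raises(ConfigError):
        SimulationConfig(n_strains=4, strain_quality=(0.1, 0.2))
    with pytest.raises(ConfigError):
        SimulationConfig(n_strains=1)
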