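"""Genotypic means and the fixed-effects regression engine."""

import numpy as np
import pytest
from scipy.special import betainc

from rhizosge import (
    NoduleVariances,
    ShootVariances,
    SimulationConfig,
    fit_means_regression,
    genotypic_mean_table,
    genotypic_means,
    sanctions_summaries,
)
from rhizosge.datamodel import NoduleCFU, NoduleTally, PlantUnit, StrainLabel
from rhizosge.discrimination import (
    DegeneratePredictorError,
    InsufficientDataError,
    derived_traits,
)
from rhizosge.simulate import simulate_phenotypes
from rhizosge.tables import ExperimentData


def _tiny_data():
    units = [
        PlantUnit("P1", 1, "one_strain", (StrainLabel("A", "red"),), 0.5),
        PlantUnit("P2", 2, "one_strain", (StrainLabel("A", "green"),), 0.5),
        PlantUnit("P3", 1, "one_strain", (StrainLabel("B", "red"),), 0.2),
    ]
    tallies = [
        NoduleTally("P1", {"A": 2}, 0),
        NoduleTally("P2", {"A": 4}, 0),
        NoduleTally("P3", {"B": 10}, 0),
    ]
    return ExperimentData(units=units, tallies=tallies)


def test_genotypic_mean_arithmetic():
    means = genotypic_means(_tiny_data(), "nodule_number")
    assert means.loc["A", "mean"] == pytest.approx(3.0)  # mean of {2, 4}
    assert means.loc["A", "n"] == 2
    assert means.loc["B", "mean"] == pytest.approx(10.0)


def test_strain_without_observations_gets_missing_mean(caplog):
    data = _tiny_data()
    data.units.append(PlantUnit("P4", 1, "one_strain", (StrainLabel("C", "red"),), None))
    with caplog.at_level("WARNING"):
        means = genotypic_means(data, "shoot_mass")
    assert np.isnan(means.loc["C", "mean"]) and means.loc["C", "n"] == 0
    assert any("no observations" in r.message for r in caplog.records)


def test_means_invariant_to_row_order_and_marker():
    data = _tiny_data()
    shuffled = ExperimentData(units=list(reversed(data.units)),
                              tallies=list(reversed(data.tallies)))
    a = genotypic_means(data, "nodule_number")
    b = genotypic_means(shuffled, "nodule_number")
    assert a.equals(b)


def test_zero_noise_simulation_recovers_configured_expectations():
    """Without any noise, one-strain shoot-mass means equal exp(mu + beta * q)."""
    cfg = SimulationConfig(
        n_strains=4, n_blocks=2, seed=0,
        nodule_var=NoduleVariances(0, 0, 0, 0, 0, 0),
        shoot_var=ShootVariances(0, 0, 0, 0),
    )
    ds = simulate_phenotypes(cfg)
    means = genotypic_means(ds.data, "shoot_mass")["mean"]
    expected = np.exp(cfg.shoot_log_mean + cfg.quality_benefit_slope * cfg.quality())
    assert np.allclose(means.to_numpy(), expected, rtol=1e-12)


def test_regression_matches_normal_equations(rng):
    """OLS slope/intercept/F agree with an explicit normal-equations solve."""
    for _ in range(10):
        n = int(rng.integers(4, 12))
        x = rng.normal(size=n)
        y = 1.0 + 0.7 * x + rng.normal(0, 0.5, n)
        res = fit_means_regression(x, y)
        A = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        sxx = ((x - x.mean()) ** 2).sum()
        se2 = resid @ resid / (n - 2)
        f_brute = beta[1] ** 2 * sxx / se2
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.f_stat == pytest.approx(f_brute, rel=1e-10)
        assert (res.df1, res.df2) == (1, n - 2)


def test_p_value_matches_f_distribution(rng):
    """p equals the F(1, n-2) survival function, checked via the incomplete
    beta identity (an independent formulation)."""
    x = rng.normal(size=8)
    y = 0.3 * x + rng.normal(0, 1.0, 8)
    res = fit_means_regression(x, y)
    d1, d2, f = res.df1, res.df2, res.f_stat
    p_beta = betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * f))
    assert res.p_value == pytest.approx(p_beta, rel=1e-10)


def test_regression_edge_cases():
    x = np.arange(8.0)
    res = fit_means_regression(x, 2.0 * x)          # exact collinearity
    assert res.r_squared == pytest.approx(1.0)
    assert res.p_value < 1e-10
    flat = fit_means_regression(x, np.full(8, 3.0))  # constant response
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    assert flat.f_stat == 0.0 and flat.p_value == 1.0
    with pytest.raises(InsufficientDataError):
        fit_means_regression([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(DegeneratePredictorError):
        fit_means_regression(np.ones(5), np.arange(5.0))
    # missing means are dropped before the count check
    with pytest.raises(InsufficientDataError):
        fit_means_regression([1.0, 2.0, np.nan, np.nan], [1.0, 2.0, 3.0, 4.0])


def test_derived_trait_ratios_and_guards():
    units = [
        PlantUnit("P1", 1, "one_strain", (StrainLabel("A", "red"),), 0.5),
        PlantUnit("P2", 1, "one_strain", (StrainLabel("B", "red"),), 0.4),
        PlantUnit("P3", 1, "one_strain", (StrainLabel("A", "green"),), 0.0),
    ]
    tallies = [NoduleTally("P1", {"A": 10}, 0), NoduleTally("P2", {"B": 0}, 0),
               NoduleTally("P3", {"A": 5}, 0)]
    ratios = derived_traits(ExperimentData(units=units, tallies=tallies)).set_index("pot_id")
    assert ratios.loc["P1", "nodules_per_gram"] == pytest.approx(20.0)
    assert ratios.loc["P1", "shoot_per_nodule"] == pytest.approx(0.05)
    assert np.isnan(ratios.loc["P2", "shoot_per_nodule"])  # zero nodules
    assert np.isnan(ratios.loc["P3", "nodules_per_gram"])  # zero shoot mass


def test_intra_nodule_share_arithmetic():
    units = [
        PlantUnit("P1", 1, "two_strain",
                  (StrainLabel("A", "red"), StrainLabel("B", "green")), 0.4),
        PlantUnit("P2", 1, "two_strain",
                  (StrainLabel("A", "green"), StrainLabel("B", "red")), 0.4),
        PlantUnit("P3", 1, "two_strain",
                  (StrainLabel("A", "red"), StrainLabel("C", "green")), 0.4),
    ]
    cfus = [NoduleCFU("P1", "n1", "mixed_colour", {"A": 300, "B": 100})]
    data = ExperimentData(units=units, cfus=cfus)
    means = genotypic_means(data, "cfu_mixed_share")
    assert means.loc["A", "mean"] == pytest.approx(0.75)
    assert means.loc["B", "mean"] == pytest.approx(0.25)


def test_full_mean_table_and_sanctions(small_dataset):
    import pandas as pd

    from rhizosge import discrimination_report

    table = genotypic_mean_table(small_dataset.data)
    assert set(table.columns) >= {"shoot_mass", "nodule_number", "nodule_proportion",
                                  "cfu_single", "cfu_mixed_share"}
    assert len(table) == small_dataset.config.n_strains
    # an externally measured growth-rate column rides through the same battery
    growth = pd.Series(np.linspace(1.0, 2.0, len(table)), index=table.index)
    report = discrimination_report(small_dataset.data, growth_rate=growth)
    assert "nodule_number_vs_growth_rate" in report.results
    assert report.results["nodule_proportion_vs_growth_rate"].df2 == len(table) - 2
    res = sanctions_summaries(small_dataset.data)
    assert set(res) == {"among_nodule_sanctions", "intra_nodule_sanctions"}
    for r in res.values():
        assert r.df1 == 1 and r.df2 == r.n - 2
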