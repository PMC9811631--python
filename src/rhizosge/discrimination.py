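"""Partner-choice and sanctions statistics on strain genotypic means.

Host discrimination is tested with fixed-effects regressions at the strain
level: each strain is summarized by its genotypic mean for a trait (an
unweighted mean over pots, across blocks and markers), and one mean is
regressed on another by ordinary least squares with an F test of the slope on
(1, n_strains - 2) degrees of freedom.

The canonical comparisons:

* partner choice — one-strain nodule number, and two-strain nodule
  proportion, each against one-strain shoot-mass benefit;
* allometry-adjusted variants — nodules per gram of shoot, shoot per nodule;
* sanctions — mean CFU in single-colour nodules (among-nodule) and mean CFU
  share within mixed-colour nodules (intra-nodule), against benefit, both
  restricted to two-strain pots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import TREATMENT_ONE_STRAIN, TREATMENT_TWO_STRAIN
from .tables import ExperimentData

logger = logging.getLogger(__name__)

MEAN_TRAITS = (
    "shoot_mass", "nodule_number", "nodule_proportion",
    "nodules_per_gram", "shoot_per_nodule",
    "cfu_single", "cfu_mixed_share",
)


class InsufficientDataError(ValueError):
    """Fewer usable points than the regression needs."""


class DegeneratePredictorError(ValueError):
    """The predictor has zero variance."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS of one genotypic-mean column on another, with an F test of the slope."""

    slope: float
    intercept: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    r_squared: float
    n: int


def fit_means_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least squares of y on x at the strain level; F test with df (1, n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 strains with both means, got {n}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("predictor means are constant")
    with warnings.catch_warnings():
        # a perfectly flat or collinear response triggers harmless divide warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        fval = float(model.fvalue)
        pval = float(model.f_pvalue)
    if not np.isfinite(fval):  # zero residual variance (exact collinearity)
        fval, pval = np.inf, 0.0
    if np.ptp(y) == 0:
        fval, pval = 0.0, 1.0
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        f_stat=fval,
        df1=1,
        df2=n - 2,
        p_value=pval,
        r_squared=float(model.rsquared) if np.ptp(y) > 0 else 0.0,
        n=n,
    )


def derived_traits(data: ExperimentData) -> pd.DataFrame:
    """Per-pot allometric ratios for one-strain pots.

    nodules_per_gram requires positive shoot mass; shoot_per_nodule requires a
    nonzero nodule count.  Undefined values are left NaN and counted in the log.
    """
    totals = {}
    for obs in data.observations():
        totals[obs.pot_id] = totals.get(obs.pot_id, 0.0) + obs.nodule_score
    rows = []
    n_excluded = 0
    for u in data.units:
        if u.treatment != TREATMENT_ONE_STRAIN:
            continue
        total = totals.get(u.pot_id)
        mass = u.shoot_mass
        per_gram = total / mass if (total is not None and mass and mass > 0) else np.nan
        per_nodule = mass / total if (total and mass is not None) else np.nan
        if np.isnan(per_gram) or np.isnan(per_nodule):
            n_excluded += 1
        rows.append({
            "pot_id": u.pot_id,
            "strain": u.strain_ids[0],
            "nodules_per_gram": per_gram,
            "shoot_per_nodule": per_nodule,
        })
    if n_excluded:
        logger.info("derived traits: %d pot(s) with undefined ratio excluded", n_excluded)
    return pd.DataFrame(rows, columns=["pot_id", "strain", "nodules_per_gram",
                                       "shoot_per_nodule"])


def _strain_mean_frame(values: dict[str, list[float]], strains: Sequence[str],
                       trait: str) -> pd.DataFrame:
    rows = []
    for s in strains:
        vals = np.asarray(values.get(s, []), float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("trait %s: strain %s has no observations", trait, s)
            rows.append({"strain": s, "mean": np.nan, "n": 0, "se": np.nan})
        else:
            se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            rows.append({"strain": s, "mean": float(vals.mean()),
                         "n": int(vals.size), "se": se})
    return pd.DataFrame(rows).set_index("strain")


def genotypic_means(
    data: ExperimentData,
    trait: str,
    treatment_filter: Optional[str] = None,
) -> pd.DataFrame:
    """Per-strain unweighted mean of a trait, with n and standard error.

    The default treatment filter is the one the analysis uses for that trait:
    one-strain pots for shoot mass / nodule number / allometric ratios,
    two-strain pots for nodule proportion and the CFU traits.
    """
    if trait not in MEAN_TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {MEAN_TRAITS}")
    if treatment_filter is None:
        treatment_filter = (
            TREATMENT_TWO_STRAIN
            if trait in ("nodule_proportion", "cfu_single", "cfu_mixed_share")
            else TREATMENT_ONE_STRAIN
        )
    units = [u for u in data.units if u.treatment == treatment_filter]
    strains = sorted({s for u in units for s in u.strain_ids})
    pot_ids = {u.pot_id for u in units}
    values: dict[str, list[float]] = {}

    if trait == "shoot_mass":
        for u in units:
            if u.shoot_mass is not None and len(u.strain_ids) == 1:
                values.setdefault(u.strain_ids[0], []).append(u.shoot_mass)
    elif trait in ("nodule_number", "nodule_proportion"):
        for obs in data.observations():
            if obs.pot_id not in pot_ids:
                continue
            val = obs.nodule_score if trait == "nodule_number" else obs.nodule_proportion
            if val is not None:
                values.setdefault(obs.focal_strain, []).append(val)
    elif trait in ("nodules_per_gram", "shoot_per_nodule"):
        ratios = derived_traits(data)
        for _, row in ratios.iterrows():
            values.setdefault(row["strain"], []).append(row[trait])
    elif trait == "cfu_single":
        for nod in data.cfus:
            if nod.pot_id in pot_ids and nod.nodule_class == "single_colour":
                for s, c in nod.cfu.items():
                    values.setdefault(s, []).append(float(c))
    elif trait == "cfu_mixed_share":
        for nod in data.cfus:
            if nod.pot_id in pot_ids and nod.nodule_class == "mixed_colour":
                total = sum(nod.cfu.values())
                if total > 0:
                    for s, c in nod.cfu.items():
                        values.setdefault(s, []).append(c / total)
    return _strain_mean_frame(values, strains, trait)


def genotypic_mean_table(data: ExperimentData,
                         growth_rate: Optional[pd.Series] = None) -> pd.DataFrame:
    """All genotypic-mean columns side by side (one row per strain).

    ``growth_rate`` optionally supplies an externally measured axenic growth
    rate per strain, carried through as one more column.
    """
    parts = {t: genotypic_means(data, t)["mean"] for t in MEAN_TRAITS}
    table = pd.DataFrame(parts)
    if growth_rate is not None:
        table["growth_rate"] = growth_rate
    return table


@dataclass(frozen=True)
class DiscriminationReport:
    """The standard regression battery, one result per trait pair."""

    results: dict[str, RegressionResult]

    def frame(self) -> pd.DataFrame:
        rows = [
            {"comparison": name, "slope": r.slope, "f_stat": r.f_stat,
             "df1": r.df1, "df2": r.df2, "p_value": r.p_value,
             "r_squared": r.r_squared, "n": r.n}
            for name, r in self.results.items()
        ]
        return pd.DataFrame(rows)


def sanctions_summaries(data: ExperimentData,
                        benefit: Optional[pd.Series] = None) -> dict[str, RegressionResult]:
    """Among-nodule and intra-nodule sanctions regressions on benefit means."""
    if benefit is None:
        benefit = genotypic_means(data, "shoot_mass")["mean"]
    out = {}
    for name, trait in (("among_nodule_sanctions", "cfu_single"),
                        ("intra_nodule_sanctions", "cfu_mixed_share")):
        means = genotypic_means(data, trait)["mean"]
        aligned = pd.concat([benefit.rename("x"), means.rename("y")], axis=1)
        out[name] = fit_means_regression(aligned["x"], aligned["y"])
    return out


def discrimination_report(data: ExperimentData,
                          growth_rate: Optional[pd.Series] = None) -> DiscriminationReport:
    """Run the full partner-choice (and, if CFU data exist, sanctions) battery."""
    table = genotypic_mean_table(data, growth_rate)
    benefit = table["shoot_mass"]
    comparisons = {
        "nodule_number_vs_benefit": "nodule_number",
        "nodule_proportion_vs_benefit": "nodule_proportion",
        "nodules_per_gram_vs_benefit": "nodules_per_gram",
        "shoot_per_nodule_vs_benefit": "shoot_per_nodule",
    }
    results = {
        name: fit_means_regression(benefit, table[trait])
        for name, trait in comparisons.items()
    }
    if growth_rate is not None:
        results["nodule_number_vs_growth_rate"] = fit_means_regression(
            table["growth_rate"], table["nodule_number"])
        results["nodule_proportion_vs_growth_rate"] = fit_means_regression(
            table["growth_rate"], table["nodule_proportion"])
    if data.cfus:
        results.update(sanctions_summaries(data, benefit))
    return DiscriminationReport(results=results)
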