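"""Host benefit of partner choice: deviation from the neutral expectation.

If a host exerted no partner choice, two strains inoculated in equal
proportions should found equal numbers of nodules, and host fitness in the
pair should be the average of host fitness with each strain alone.  The
deviation statistic scales the departure from that expectation by its size:

    deviation = (W_pair - (W1 + W2) / 2) / ((W1 + W2) / 2)

where ``W_pair`` is host fitness (shoot mass, g) in the two-strain pot and
``W1``, ``W2`` are the strains' one-strain genotypic means.  A positive value
means the host did better than the no-choice expectation.  Whether stronger
partner choice pays is then tested with a linear mixed model of the deviation
on the proportion of nodules founded by the more beneficial strain, with
random intercepts for strain, competitor strain and block, fitted by maximum
likelihood and tested with a 1-df likelihood-ratio chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import TREATMENT_TWO_STRAIN
from .discrimination import genotypic_means
from .reml import LRTResult, MixedModel, RandomTerm, likelihood_ratio_test
from .tables import ExperimentData

logger = logging.getLogger(__name__)


class UndefinedDenominatorError(ValueError):
    """The one-strain mean fitness is non-positive; the scaled deviation is undefined."""


def neutral_deviation(w_pair: float, w1: float, w2: float) -> float:
    """Scaled deviation of paired-inoculum host fitness from the one-strain average."""
    m = 0.5 * (w1 + w2)
    if m <= 0:
        raise UndefinedDenominatorError(f"mean one-strain fitness {m} is not positive")
    return (w_pair - m) / m


@dataclass(frozen=True)
class DeviationRecord:
    """One two-strain pot's deviation, oriented by the benefit ranking.

    ``strain_beneficial`` (R1) is the pair's more beneficial strain by the
    global one-strain shoot-mass ranking; ``prop_beneficial`` is the share of
    the pot's nodules it founded.
    """

    pot_id: str
    block: int
    strain_beneficial: str
    strain_other: str
    w_pair: float
    w1: float
    w2: float
    deviation: float
    prop_beneficial: float
    tie_broken: bool = False


def benefit_ranking(data: ExperimentData) -> pd.Series:
    """One-strain shoot-mass genotypic means, the global benefit axis."""
    return genotypic_means(data, "shoot_mass")["mean"]


def deviation_table(
    data: ExperimentData,
    benefit: Optional[pd.Series] = None,
    fitness: str = "shoot_mass",
) -> list[DeviationRecord]:
    """Deviation records for all two-strain pots with defined occupancy.

    ``fitness="per_nodule"`` measures host fitness as shoot mass per nodule
    (both in the pair and in the one-strain means) instead of raw shoot mass.
    Pots with zero nodules, missing shoot mass, or a strain lacking a
    one-strain mean are skipped with a logged count.
    """
    if fitness not in ("shoot_mass", "per_nodule"):
        raise ValueError(f"unknown fitness measure {fitness!r}")
    if benefit is None:
        benefit = benefit_ranking(data)
    one_strain_mean = (
        benefit if fitness == "shoot_mass"
        else genotypic_means(data, "shoot_per_nodule")["mean"]
    )

    props: dict[str, dict[str, float]] = {}
    totals: dict[str, float] = {}
    for obs in data.observations():
        if obs.competitor_strain is None:
            continue
        if obs.nodule_proportion is not None:
            props.setdefault(obs.pot_id, {})[obs.focal_strain] = obs.nodule_proportion
        totals[obs.pot_id] = totals.get(obs.pot_id, 0.0) + obs.nodule_score

    records: list[DeviationRecord] = []
    n_skipped = 0
    for u in data.units:
        if u.treatment != TREATMENT_TWO_STRAIN:
            continue
        a, b = u.strain_ids
        pot_props = props.get(u.pot_id)
        w_pair = u.shoot_mass
        if fitness == "per_nodule":
            total = totals.get(u.pot_id, 0.0)
            w_pair = (w_pair / total) if (w_pair is not None and total > 0) else None
        if (pot_props is None or w_pair is None
                or a not in one_strain_mean.index or b not in one_strain_mean.index
                or not np.isfinite(one_strain_mean[a])
                or not np.isfinite(one_strain_mean[b])):
            n_skipped += 1
            continue
        ba, bb = benefit.get(a, np.nan), benefit.get(b, np.nan)
        tie = bool(np.isclose(ba, bb))
        if tie:
            r1, r2 = sorted((a, b))  # deterministic lexicographic tie-break
        else:
            r1, r2 = (a, b) if ba > bb else (b, a)
        w1, w2 = float(one_strain_mean[r1]), float(one_strain_mean[r2])
        try:
            dev = neutral_deviation(float(w_pair), w1, w2)
        except UndefinedDenominatorError:
            n_skipped += 1
            continue
        records.append(DeviationRecord(
            pot_id=u.pot_id, block=u.block,
            strain_beneficial=r1, strain_other=r2,
            w_pair=float(w_pair), w1=w1, w2=w2,
            deviation=dev, prop_beneficial=float(pot_props[r1]),
            tie_broken=tie,
        ))
    if n_skipped:
        logger.info("deviation table: %d pot(s) skipped (undefined inputs)", n_skipped)
    return records


def records_frame(records: Sequence[DeviationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass(frozen=True)
class DeviationModelResult:
    """Fixed-effect slope of deviation on occupancy, with an ML likelihood-ratio test."""

    slope: float
    intercept: float
    lrt: LRTResult
    n: int


def fit_deviation_model(records: Sequence[DeviationRecord]) -> DeviationModelResult:
    """Mixed model: deviation ~ prop_beneficial + (1 | strain) + (1 | competitor)
    + (1 | block), fitted by ML; the slope is tested against the intercept-only
    model by likelihood ratio (1 df)."""
    if len(records) < 4:
        raise ValueError("too few records to fit the deviation model")
    y = np.array([r.deviation for r in records])
    prop = np.array([r.prop_beneficial for r in records])
    terms = [
        RandomTerm.from_codes("strain", [r.strain_beneficial for r in records]),
        RandomTerm.from_codes("competitor", [r.strain_other for r in records]),
        RandomTerm.from_codes("block", [r.block for r in records]),
    ]
    for t in terms:
        if t.Z.shape[1] < 2:
            raise ValueError(f"random grouping {t.name!r} has fewer than 2 levels")
    X_full = np.column_stack([np.ones(y.size), prop])
    full = MixedModel(y, X_full, terms).fit(method="ml")
    null = MixedModel(y, np.ones((y.size, 1)), terms).fit(method="ml")
    lrt = likelihood_ratio_test(full, null, df=1)

    # recover the fixed-effect estimates at the fitted variances (GLS)
    model = MixedModel(y, X_full, terms)
    gamma = np.array([max(full.gammas[t.name], 0.0) for t in terms])
    from .reml import GAMMA_FLOOR
    core = model._core(np.clip(gamma, GAMMA_FLOOR, None))
    beta = core[8]
    return DeviationModelResult(
        slope=float(beta[1]), intercept=float(beta[0]), lrt=lrt, n=y.size,
    )
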