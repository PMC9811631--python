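"""Variance partitioning of symbiotic fitness into direct and social genetic effects.

For two-strain pots, a focal strain's phenotype is modelled with random
effects for its own genotype (direct genetic effect, DGE), the co-inoculated
competitor's genotype (main social genetic effect, SGE), their pair-specific
interaction (G x G SGE), block, and — where the data are dyadic — pot.

Three traits, three parameterizations:

``nodule_number``
    Two rows per pot (one per strain); separate DGE and SGE incidence,
    ordered-pair G x G, block and pot terms; no constraints.
``nodule_proportion``
    One row per pot (the two orientations are linearly dependent: the shares
    sum to 1).  DGE and SGE are constrained equal with focal/competitor
    correlation -1, implemented exactly by a single strain effect entering
    +1 for the focal strain and -1 for the competitor; G x G is indexed by
    unordered pair.  Identity scale.
``shoot_mass``
    One row per pot on the natural-log scale.  DGE = SGE with correlation +1:
    one strain effect entering +1 for each of the two strains; unordered-pair
    G x G; block.

Each variance component is tested by removing it and comparing restricted
log-likelihoods (chi-square, 1 df; for a constrained model the single shared
strain parameter carries both the DGE and the SGE row, so those two rows
report the same test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import TREATMENT_TWO_STRAIN, PlantUnit, StrainPotObservation
from .reml import LRTResult, MixedModel, RandomTerm, VarianceComponentFit, likelihood_ratio_test
from .tables import ExperimentData

TRAITS = ("nodule_number", "nodule_proportion", "shoot_mass")

UNCONSTRAINED = "unconstrained"
DGE_EQ_SGE_CORR_PLUS1 = "dge_eq_sge_corr_plus1"
DGE_EQ_SGE_CORR_MINUS1 = "dge_eq_sge_corr_minus1"


@dataclass(frozen=True)
class ModelSpec:
    """Trait, transform and constraint mode for one variance-partition model."""

    trait: str
    transform: str = "identity"          # "identity" | "log"
    constraint: str = UNCONSTRAINED
    include_marker: bool = True          # fluorescent marker as a fixed effect

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.constraint not in (UNCONSTRAINED, DGE_EQ_SGE_CORR_PLUS1,
                                   DGE_EQ_SGE_CORR_MINUS1):
            raise ValueError(f"unknown constraint {self.constraint!r}")


def default_spec(trait: str, include_marker: bool = True) -> ModelSpec:
    """The analysis defaults: nodule number unconstrained with a pot effect;
    nodule proportion with DGE = SGE, corr -1; shoot mass on the log scale
    with DGE = SGE, corr +1."""
    if trait == "nodule_number":
        return ModelSpec(trait, "identity", UNCONSTRAINED, include_marker)
    if trait == "nodule_proportion":
        return ModelSpec(trait, "identity", DGE_EQ_SGE_CORR_MINUS1, include_marker)
    if trait == "shoot_mass":
        return ModelSpec(trait, "log", DGE_EQ_SGE_CORR_PLUS1, include_marker)
    raise ValueError(f"unknown trait {trait!r}")


@dataclass
class ModelMatrices:
    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm]
    n_excluded: int                      # rows dropped for undefined responses
    row_pots: list[str] = field(default_factory=list)


class AssemblyError(ValueError):
    """Raised when the requested model cannot be built from the data."""


def _canonical_pot_rows(units: Sequence[PlantUnit],
                        obs: Sequence[StrainPotObservation]):
    """One observation per two-strain pot, lexicographically smaller strain focal."""
    by_pot: dict[str, dict[str, StrainPotObservation]] = {}
    for o in obs:
        if o.competitor_strain is not None:
            by_pot.setdefault(o.pot_id, {})[o.focal_strain] = o
    rows = []
    for u in units:
        if u.treatment != TREATMENT_TWO_STRAIN:
            continue
        focal = min(u.strain_ids)
        rows.append((u, by_pot.get(u.pot_id, {}).get(focal)))
    return rows


def build_matrices(data: ExperimentData, spec: ModelSpec) -> ModelMatrices:
    """Assemble response, fixed design and random-effect incidence for one trait."""
    units = [u for u in data.units if u.treatment == TREATMENT_TWO_STRAIN]
    if not units:
        raise AssemblyError("no two-strain pots in the dataset")
    strains = sorted({s for u in units for s in u.strain_ids})
    obs = [o for o in data.observations() if o.competitor_strain is not None]

    if spec.trait == "nodule_number":
        return _matrices_dyadic(units, obs, strains, spec)
    return _matrices_pot_level(data, units, obs, strains, spec)


def _marker_col(markers: Sequence[str]) -> np.ndarray:
    return np.array([1.0 if m == "green" else 0.0 for m in markers])


def _matrices_dyadic(units, obs, strains, spec) -> ModelMatrices:
    if spec.constraint != UNCONSTRAINED:
        raise AssemblyError("nodule number is modelled without variance constraints")
    if not obs:
        raise AssemblyError("no dyadic nodule observations")
    block_of = {u.pot_id: u.block for u in units}
    y = np.array([o.nodule_score for o in obs], float)
    if spec.transform == "log":
        y = np.log(y + 1.0)
    X = np.column_stack([np.ones(len(obs))] + (
        [_marker_col([o.focal_marker for o in obs])] if spec.include_marker else []))
    pairs = [(o.focal_strain, o.competitor_strain) for o in obs]
    blocks = [block_of[o.pot_id] for o in obs]
    pots = [o.pot_id for o in obs]
    terms = [
        RandomTerm.from_codes("dge", [o.focal_strain for o in obs], levels=strains),
        RandomTerm.from_codes("sge", [o.competitor_strain for o in obs], levels=strains),
        RandomTerm.from_codes("gxg", pairs),
        RandomTerm.from_codes("block", blocks),
        RandomTerm.from_codes("pot", pots),
    ]
    return ModelMatrices(y=y, X=X, terms=terms, n_excluded=0, row_pots=pots)


def _matrices_pot_level(data, units, obs, strains, spec) -> ModelMatrices:
    rows = _canonical_pot_rows(units, obs)
    y_vals, markers, strain_rows, pair_codes, blocks, pots = [], [], [], [], [], []
    n_excluded = 0
    sindex = {s: j for j, s in enumerate(strains)}
    comp_sign = -1.0 if spec.constraint == DGE_EQ_SGE_CORR_MINUS1 else 1.0

    for unit, ob in rows:
        focal = min(unit.strain_ids)
        competitor = max(unit.strain_ids)
        if spec.trait == "nodule_proportion":
            if ob is None or ob.nodule_proportion is None:
                n_excluded += 1
                continue
            value = ob.nodule_proportion
        else:  # shoot_mass
            if unit.shoot_mass is None or (spec.transform == "log" and unit.shoot_mass <= 0):
                n_excluded += 1
                continue
            value = math.log(unit.shoot_mass) if spec.transform == "log" else unit.shoot_mass
        y_vals.append(value)
        markers.append(unit.marker_of(focal))
        strain_rows.append((sindex[focal], sindex[competitor]))
        pair_codes.append((focal, competitor))
        blocks.append(unit.block)
        pots.append(unit.pot_id)

    if not y_vals:
        raise AssemblyError(f"no usable pots for trait {spec.trait!r}")
    if spec.constraint == UNCONSTRAINED:
        raise AssemblyError(
            f"{spec.trait} uses the constrained (DGE = SGE) parameterization"
        )
    n = len(y_vals)
    Zs = np.zeros((n, len(strains)))
    for i, (jf, jc) in enumerate(strain_rows):
        Zs[i, jf] += 1.0
        Zs[i, jc] += comp_sign
    X = np.column_stack([np.ones(n)] + ([_marker_col(markers)] if spec.include_marker else []))
    terms = [
        RandomTerm("strain", Zs),
        RandomTerm.from_codes("gxg", pair_codes),
        RandomTerm.from_codes("block", blocks),
    ]
    return ModelMatrices(y=np.array(y_vals), X=X, terms=terms,
                         n_excluded=n_excluded, row_pots=pots)


@dataclass
class TraitAnalysis:
    """One Table-row bundle: fit, variance proportions and component LRTs."""

    spec: ModelSpec
    fit: VarianceComponentFit
    proportions: dict[str, float]        # DGE/SGE listed separately even if shared
    lrts: dict[str, LRTResult]
    n_obs: int
    n_excluded: int


#: Table rows, in display order
COMPONENTS = ("dge", "sge", "gxg", "block", "pot", "residual")


def _term_for_component(spec: ModelSpec, component: str) -> str:
    if component in ("dge", "sge") and spec.constraint != UNCONSTRAINED:
        return "strain"
    return component


def reml_fit(data: ExperimentData, spec: ModelSpec, **fit_kw) -> VarianceComponentFit:
    mm = build_matrices(data, spec)
    return MixedModel(mm.y, mm.X, mm.terms).fit(**fit_kw)


def lrt_component(data: ExperimentData, spec: ModelSpec, component: str,
                  **fit_kw) -> LRTResult:
    """Refit without one component and test it by likelihood ratio (1 df)."""
    mm = build_matrices(data, spec)
    model = MixedModel(mm.y, mm.X, mm.terms)
    term = _term_for_component(spec, component)
    full = model.fit(**fit_kw)
    if term not in {t.name for t in model.terms}:
        # component not in this trait's model: full and reduced coincide
        return LRTResult(chi2=0.0, df=1, p_value=1.0,
                         loglik_full=full.loglik, loglik_reduced=full.loglik)
    reduced = model.drop_term(term).fit(**fit_kw)
    return likelihood_ratio_test(full, reduced, df=1)


def analyze_trait(data: ExperimentData, spec: Optional[ModelSpec] = None,
                  trait: Optional[str] = None, with_lrt: bool = True,
                  **fit_kw) -> TraitAnalysis:
    """Fit one trait's variance-partition model and (optionally) all component LRTs."""
    if spec is None:
        if trait is None:
            raise ValueError("give either a ModelSpec or a trait name")
        spec = default_spec(trait)
    mm = build_matrices(data, spec)
    model = MixedModel(mm.y, mm.X, mm.terms)
    fit = model.fit(**fit_kw)

    constrained = spec.constraint != UNCONSTRAINED
    raw = fit.variance_proportions(count_twice=("strain",) if constrained else ())
    proportions: dict[str, float] = {}
    for comp in COMPONENTS:
        if comp == "residual":
            proportions[comp] = raw["residual"]
        elif comp in ("dge", "sge") and constrained:
            proportions[comp] = raw["strain"]
        elif comp in raw:
            proportions[comp] = raw[comp]

    lrts: dict[str, LRTResult] = {}
    if with_lrt:
        tested: dict[str, LRTResult] = {}
        for comp in proportions:
            if comp == "residual":
                continue
            term = _term_for_component(spec, comp)
            if term not in tested:
                reduced = model.drop_term(term).fit(**fit_kw)
                tested[term] = likelihood_ratio_test(fit, reduced, df=1)
            lrts[comp] = tested[term]

    return TraitAnalysis(spec=spec, fit=fit, proportions=proportions, lrts=lrts,
                         n_obs=fit.n_obs, n_excluded=mm.n_excluded)


def variance_table(analyses: dict[str, TraitAnalysis]) -> pd.DataFrame:
    """Assemble the components x traits partition table (percent variance,
    likelihood-ratio chi-square and p per component)."""
    rows = []
    for comp in COMPONENTS:
        row: dict[str, object] = {"component": comp}
        for trait, an in analyses.items():
            if comp in an.proportions:
                row[f"{trait}_pct"] = 100.0 * an.proportions[comp]
                lrt = an.lrts.get(comp)
                row[f"{trait}_chi2"] = lrt.chi2 if lrt else np.nan
                row[f"{trait}_p"] = lrt.p_value if lrt else np.nan
            else:
                row[f"{trait}_pct"] = np.nan
                row[f"{trait}_chi2"] = np.nan
                row[f"{trait}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
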