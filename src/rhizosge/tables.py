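"""Tidy-table I/O for the co-inoculation data model.

Three delimited text tables carry a full experiment:

* ``plants``  — one row per pot: pot_id, block, treatment, strain_a, marker_a,
  strain_b, marker_b, shoot_mass_g (empty cells for missing values).
* ``nodules`` — one row per (pot, strain): pot_id, strain, singles, mixed,
  where ``mixed`` is the pot's mixed-colour nodule count (repeated on both
  rows of a two-strain pot and cross-checked on read).
* ``cfu``     — one row per (nodule, strain): pot_id, nodule_id, class, strain, cfu.

Column names in files can differ from the canonical names above; a schema
mapping (``{table: {canonical: actual}}``, e.g. loaded from YAML) adapts
external deposits without code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .datamodel import (
    MARKERS,
    TREATMENT_CONTROL,
    TREATMENT_ONE_STRAIN,
    TREATMENT_TWO_STRAIN,
    NoduleCFU,
    NoduleTally,
    PlantUnit,
    StrainLabel,
    StrainPotObservation,
    observations_for,
)

PLANT_COLUMNS = [
    "pot_id", "block", "treatment",
    "strain_a", "marker_a", "strain_b", "marker_b", "shoot_mass_g",
]
NODULE_COLUMNS = ["pot_id", "strain", "singles", "mixed"]
CFU_COLUMNS = ["pot_id", "nodule_id", "class", "strain", "cfu"]


class ValidationError(ValueError):
    """Schema or consistency violation; message lists offending rows."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass
class ExperimentData:
    """In-memory experiment: pots, nodule tallies and (optionally) nodule CFUs.

    ``precomputed_observations`` bypasses the tally-derived occupancy records;
    the simulator's pure-Gaussian mode uses it to carry real-valued scores that
    no integer tally could reproduce.
    """

    units: list[PlantUnit]
    tallies: list[NoduleTally] = field(default_factory=list)
    cfus: list[NoduleCFU] = field(default_factory=list)
    precomputed_observations: Optional[list[StrainPotObservation]] = None

    def observations(self) -> list[StrainPotObservation]:
        if self.precomputed_observations is not None:
            return self.precomputed_observations
        return observations_for(self.units, self.tallies)

    def unit(self, pot_id: str) -> PlantUnit:
        for u in self.units:
            if u.pot_id == pot_id:
                return u
        raise KeyError(pot_id)


def _rename(df: pd.DataFrame, table: str, schema: Optional[Mapping]) -> pd.DataFrame:
    if schema and table in schema:
        mapping = {actual: canonical for canonical, actual in schema[table].items()}
        df = df.rename(columns=mapping)
    return df


def _require(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError([f"{table}: missing required column(s) {missing}"])


def _read_delim(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_plants(path: str | Path, schema: Optional[Mapping] = None) -> list[PlantUnit]:
    df = _rename(_read_delim(path), "plants", schema)
    _require(df, ["pot_id", "block", "treatment"], "plants")
    problems: list[str] = []
    dup = df["pot_id"][df["pot_id"].duplicated()]
    for idx, pid in dup.items():
        problems.append(f"plants row {idx + 2}: duplicated pot_id {pid!r}")
    units = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based + header
        labels = []
        for suffix in ("a", "b"):
            strain = row.get(f"strain_{suffix}", "")
            marker = row.get(f"marker_{suffix}", "")
            if strain:
                if marker not in MARKERS:
                    problems.append(f"plants row {rowno}: bad marker {marker!r}")
                    continue
                labels.append(StrainLabel(strain, marker))
        mass_raw = row.get("shoot_mass_g", "")
        mass = None
        if mass_raw != "":
            try:
                mass = float(mass_raw)
            except ValueError:
                problems.append(f"plants row {rowno}: non-numeric shoot mass {mass_raw!r}")
        try:
            units.append(
                PlantUnit(
                    pot_id=row["pot_id"],
                    block=int(row["block"]),
                    treatment=row["treatment"],
                    labels=tuple(labels),
                    shoot_mass=mass,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"plants row {rowno}: {exc}")
    if problems:
        raise ValidationError(problems)
    return units


def read_nodules(path: str | Path, schema: Optional[Mapping] = None) -> list[NoduleTally]:
    df = _rename(_read_delim(path), "nodules", schema)
    _require(df, NODULE_COLUMNS, "nodules")
    problems: list[str] = []
    tallies: dict[str, NoduleTally] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2
        pid = row["pot_id"]
        try:
            singles = int(row["singles"])
            mixed = int(row["mixed"])
        except ValueError:
            problems.append(f"nodules row {rowno}: non-integer count")
            continue
        if singles < 0 or mixed < 0:
            problems.append(f"nodules row {rowno}: negative count")
            continue
        tally = tallies.setdefault(pid, NoduleTally(pot_id=pid, mixed=mixed))
        if row["strain"] in tally.singles:
            problems.append(f"nodules row {rowno}: duplicated (pot, strain) key")
        tally.singles[row["strain"]] = singles
        if tally.mixed != mixed:
            problems.append(f"nodules row {rowno}: inconsistent mixed count for pot {pid}")
    if problems:
        raise ValidationError(problems)
    return list(tallies.values())


def read_cfu(path: str | Path, schema: Optional[Mapping] = None) -> list[NoduleCFU]:
    df = _rename(_read_delim(path), "cfu", schema)
    _require(df, CFU_COLUMNS, "cfu")
    problems: list[str] = []
    nodules: dict[tuple[str, str], NoduleCFU] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2
        key = (row["pot_id"], row["nodule_id"])
        try:
            count = int(row["cfu"])
        except ValueError:
            problems.append(f"cfu row {rowno}: non-integer CFU")
            continue
        if count < 0:
            problems.append(f"cfu row {rowno}: negative CFU")
            continue
        nod = nodules.setdefault(
            key, NoduleCFU(pot_id=key[0], nodule_id=key[1], nodule_class=row["class"])
        )
        if nod.nodule_class != row["class"]:
            problems.append(f"cfu row {rowno}: inconsistent class for nodule {key[1]}")
        nod.cfu[row["strain"]] = count
    if problems:
        raise ValidationError(problems)
    return list(nodules.values())


def validate(data: ExperimentData) -> None:
    """Cross-table checks: tallies/CFUs reference known pots and inoculated strains,
    derived proportions lie in [0, 1]."""
    problems: list[str] = []
    by_pot = {u.pot_id: u for u in data.units}
    for tally in data.tallies:
        pot = by_pot.get(tally.pot_id)
        if pot is None:
            problems.append(f"nodule tally for unknown pot {tally.pot_id}")
            continue
        extra = set(tally.singles) - set(pot.strain_ids)
        if extra:
            problems.append(f"pot {tally.pot_id}: tally strain(s) {sorted(extra)} not inoculated")
    for nod in data.cfus:
        pot = by_pot.get(nod.pot_id)
        if pot is None:
            problems.append(f"CFU record for unknown pot {nod.pot_id}")
            continue
        extra = set(nod.cfu) - set(pot.strain_ids)
        if extra:
            problems.append(
                f"nodule {nod.nodule_id}: CFU strain(s) {sorted(extra)} not inoculated"
            )
    if problems:
        raise ValidationError(problems)
    for obs in data.observations():  # raises ConsistencyError on tally/pot mismatch
        if obs.nodule_proportion is not None and not (0.0 <= obs.nodule_proportion <= 1.0):
            raise ValidationError(
                [f"pot {obs.pot_id}: derived proportion {obs.nodule_proportion} outside [0,1]"]
            )


def read_tables(
    plants_path: str | Path,
    nodules_path: Optional[str | Path] = None,
    cfu_path: Optional[str | Path] = None,
    schema: Optional[Mapping] = None,
) -> ExperimentData:
    """Read and validate an experiment from delimited text tables."""
    data = ExperimentData(
        units=read_plants(plants_path, schema),
        tallies=read_nodules(nodules_path, schema) if nodules_path else [],
        cfus=read_cfu(cfu_path, schema) if cfu_path else [],
    )
    validate(data)
    return data


def plants_frame(units: Sequence[PlantUnit]) -> pd.DataFrame:
    rows = []
    for u in units:
        labs = list(u.labels) + [None, None]
        rows.append(
            {
                "pot_id": u.pot_id,
                "block": u.block,
                "treatment": u.treatment,
                "strain_a": labs[0].strain_id if labs[0] else "",
                "marker_a": labs[0].marker if labs[0] else "",
                "strain_b": labs[1].strain_id if labs[1] else "",
                "marker_b": labs[1].marker if labs[1] else "",
                "shoot_mass_g": "" if u.shoot_mass is None else repr(u.shoot_mass),
            }
        )
    return pd.DataFrame(rows, columns=PLANT_COLUMNS)


def nodules_frame(tallies: Sequence[NoduleTally]) -> pd.DataFrame:
    rows = [
        {"pot_id": t.pot_id, "strain": s, "singles": n, "mixed": t.mixed}
        for t in tallies
        for s, n in sorted(t.singles.items())
    ]
    return pd.DataFrame(rows, columns=NODULE_COLUMNS)


def cfu_frame(cfus: Sequence[NoduleCFU]) -> pd.DataFrame:
    rows = [
        {"pot_id": n.pot_id, "nodule_id": n.nodule_id, "class": n.nodule_class,
         "strain": s, "cfu": c}
        for n in cfus
        for s, c in sorted(n.cfu.items())
    ]
    return pd.DataFrame(rows, columns=CFU_COLUMNS)


def write_tables(data: ExperimentData, out_dir: str | Path) -> dict[str, Path]:
    """Write plants/nodules/cfu CSVs; shoot mass uses repr so reads round-trip."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"plants": out / "plants.csv"}
    plants_frame(data.units).to_csv(paths["plants"], index=False)
    if data.tallies:
        paths["nodules"] = out / "nodules.csv"
        nodules_frame(data.tallies).to_csv(paths["nodules"], index=False)
    if data.cfus:
        paths["cfu"] = out / "cfu.csv"
        cfu_frame(data.cfus).to_csv(paths["cfu"], index=False)
    return paths
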