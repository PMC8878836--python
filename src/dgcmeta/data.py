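"""Study-level data model, delimited-table IO, taxonomy, and unit conversions.

The pipeline starts from study-level summaries: per experimental arm a mean,
a dispersion (SD or SE, tagged explicitly), a sample size and a unit tag.
Two-arm records compare respiratory vs cuticular water loss (mg/h) or
metabolic rate under normoxia vs altered oxygen (ml/g/h); temperature records
carry a series of per-temperature means for the log-linear slope analysis.

Rates reported per animal (ml/h) are normalised to mass-specific units
(ml/g/h) by dividing by mean body mass, with the dispersion propagated by a
first-order Taylor (delta-method) expression for the SD of a ratio of
independent quantities.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmSummary",
    "TemperatureSeries",
    "StudyRecord",
    "Taxonomy",
    "SchemaError",
    "ParseError",
    "TaxonLookupError",
    "read_study_table",
    "write_study_table",
    "read_taxonomy",
    "convert_rate_units",
    "convert_water_loss_units",
    "OBJECTIVES",
    "TWO_ARM_COLUMNS",
    "TEMPERATURE_COLUMNS",
]

OBJECTIVES = ("hygric", "chthonic_hyperoxia", "chthonic_hypoxia", "temperature")

RATE_UNITS = ("ml/h", "ml/g/h")
WATER_LOSS_UNITS = ("mg/h", "ug/h", "mg/min")
MASS_UNITS = ("g",)
KNOWN_UNITS = RATE_UNITS + WATER_LOSS_UNITS + MASS_UNITS

#: multiplicative factor taking a water-loss unit to mg/h
_WATER_LOSS_FACTORS = {"mg/h": 1.0, "ug/h": 1e-3, "mg/min": 60.0}


class SchemaError(ValueError):
    """A required column is missing or an enum value is unknown."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""


class TaxonLookupError(KeyError):
    """A study's taxon label does not resolve in the supplied taxonomy."""


@dataclass(frozen=True)
class ArmSummary:
    """One experimental arm: mean, dispersion (SD or SE), n and a unit tag."""

    mean: float
    dispersion: float
    n: int
    units: str
    dispersion_type: Literal["sd", "se"] = "sd"

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"arm mean must be finite, got {self.mean}")
        if self.dispersion < 0 or not math.isfinite(self.dispersion):
            raise ValueError(f"dispersion must be finite and >= 0, got {self.dispersion}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if self.units not in KNOWN_UNITS:
            raise SchemaError(f"unknown units tag {self.units!r}; known: {KNOWN_UNITS}")
        if self.dispersion_type not in ("sd", "se"):
            raise SchemaError(f"dispersion_type must be 'sd' or 'se', got {self.dispersion_type!r}")

    @property
    def sd(self) -> float:
        """SD of individuals; SE is converted via SD = SE * sqrt(n)."""
        if self.dispersion_type == "sd":
            return self.dispersion
        return self.dispersion * math.sqrt(self.n)

    def as_sd(self) -> "ArmSummary":
        """Return an equivalent arm with the dispersion stored as SD."""
        if self.dispersion_type == "sd":
            return self
        return replace(self, dispersion=self.sd, dispersion_type="sd")

    @property
    def variance(self) -> float:
        """Variance of individuals (SD squared)."""
        return self.sd**2


@dataclass(frozen=True)
class TemperatureSeries:
    """Per-temperature mean metabolic rates (ml/g/h) with SD and n.

    Temperatures are sorted ascending on construction; at least two distinct
    temperatures are required and all means must be positive so the log
    transform exists.
    """

    temperatures: tuple[float, ...]
    means: tuple[float, ...]
    dispersions: tuple[float, ...]
    ns: tuple[int, ...]
    dispersion_type: Literal["sd", "se"] = "sd"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.dispersions, dtype=float)
        n = np.asarray(self.ns)
        if not (len(t) == len(m) == len(s) == len(n)):
            raise ValueError("temperature series fields must have equal length")
        if len(t) < 2:
            raise ValueError("a temperature series needs at least two temperatures")
        if len(np.unique(t)) < 2:
            raise ValueError("a temperature series needs at least two distinct temperatures")
        if np.any(m <= 0):
            raise ValueError("all mean rates must be > 0 (log transform required)")
        if np.any(s < 0):
            raise ValueError("dispersions must be >= 0")
        if np.any(n < 1):
            raise ValueError("per-temperature n must be >= 1")
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "temperatures", tuple(float(x) for x in t[order]))
        object.__setattr__(self, "means", tuple(float(x) for x in m[order]))
        object.__setattr__(self, "dispersions", tuple(float(x) for x in s[order]))
        object.__setattr__(self, "ns", tuple(int(x) for x in n[order]))

    def __len__(self) -> int:
        return len(self.temperatures)

    def sds(self) -> np.ndarray:
        """Per-temperature SD of individuals (SE rows converted via SE*sqrt(n))."""
        s = np.asarray(self.dispersions, dtype=float)
        if self.dispersion_type == "se":
            s = s * np.sqrt(np.asarray(self.ns, dtype=float))
        return s


@dataclass(frozen=True)
class StudyRecord:
    """One comparison extracted from a study, with its taxonomy labels."""

    study_id: str
    species: str
    family: str
    order: str
    objective: str
    arms: tuple[ArmSummary, ...] | None = None
    series: TemperatureSeries | None = None
    temperature_C: float | None = None
    mass: ArmSummary | None = None

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise SchemaError(f"unknown objective {self.objective!r}; known: {OBJECTIVES}")
        for label, value in (("species", self.species), ("family", self.family), ("order", self.order)):
            if not str(value).strip():
                raise ValueError(f"taxon label {label!r} must be nonempty")
        if self.objective == "temperature":
            if self.series is None:
                raise ValueError("temperature records carry a TemperatureSeries payload")
            if self.arms is not None:
                raise ValueError("temperature records must not carry two-arm payloads")
        else:
            if self.arms is None or len(self.arms) != 2:
                raise ValueError(f"{self.objective} records carry exactly two arms")
            if self.series is not None:
                raise ValueError("two-arm records must not carry a temperature series")

    @property
    def taxonomy_path(self) -> tuple[str, str, str]:
        return (self.order, self.family, self.species)


# ---------------------------------------------------------------------------
# Taxonomy

class Taxonomy:
    """Order/family/species hierarchy, from a rooted Newick tree or a label table.

    The tree's tips are insect-order labels (matched byte-for-byte against the
    study table); a label table supplies full order→family→species paths.
    When both are given, the tree is authoritative for order membership and a
    mismatch is an error.
    """

    def __init__(self, paths: dict[tuple[str, str, str], None] | Iterable[tuple[str, str, str]] | None = None,
                 tree=None):
        self._paths: set[tuple[str, str, str]] = set(paths or [])
        self.tree = tree  # dendropy.Tree or None
        if tree is not None:
            tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            tree_orders = tips
            table_orders = {p[0] for p in self._paths}
            missing = table_orders - tree_orders
            if missing:
                raise TaxonLookupError(
                    f"orders in study table absent from tree: {sorted(missing)}")
            self._orders = tree_orders
        else:
            self._orders = {p[0] for p in self._paths}

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "Taxonomy":
        required = {"order", "family", "species"}
        if not required <= set(table.columns):
            raise SchemaError(f"taxonomy table needs columns {sorted(required)}")
        paths = [
            (str(r.order), str(r.family), str(r.species))
            for r in table.itertuples(index=False)
        ]
        return cls(paths)

    @classmethod
    def from_newick(cls, path: str | Path, paths: Iterable[tuple[str, str, str]] | None = None) -> "Taxonomy":
        import dendropy

        tree = dendropy.Tree.get(path=str(path), schema="newick")
        if tree.seed_node is not None and len(tree.seed_node.child_nodes()) > 2 and not tree.is_rooted:
            # dendropy reads plain newick as unrooted by default; a trifurcating
            # root with no rooting statement is genuinely unrooted
            raise ValueError("unrooted trees are rejected; supply a rooted Newick tree")
        return cls(paths, tree=tree)

    @property
    def orders(self) -> set[str]:
        return set(self._orders)

    @property
    def paths(self) -> set[tuple[str, str, str]]:
        return set(self._paths)

    def resolve(self, path: tuple[str, str, str]) -> tuple[str, str, str]:
        """Validate a study's taxon path against the taxonomy."""
        if self._paths:
            if path not in self._paths:
                raise TaxonLookupError(f"taxon path {path} not in taxonomy")
        elif path[0] not in self._orders:
            raise TaxonLookupError(f"order {path[0]!r} not in taxonomy tree")
        return path

    def order_correlation(self, orders: Sequence[str]) -> np.ndarray:
        """Order-level correlation matrix from shared root-to-tip path lengths.

        cor(i, j) = (shared path length from root) / (total root-to-tip depth),
        under an ultrametric reading of the tree.  Without a tree (or without
        branch lengths) the identity matrix is returned: orders are treated as
        exchangeable categorical levels.
        """
        q = len(orders)
        ident = np.eye(q)
        if self.tree is None:
            return ident
        tree = self.tree
        if all(e.length is None for e in tree.preorder_edge_iter()):
            return ident
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        leaf = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        for o in orders:
            if o not in leaf:
                raise TaxonLookupError(f"order {o!r} not a tip of the taxonomy tree")
        pdm = tree.phylogenetic_distance_matrix()
        depth = max(lf.root_distance for lf in leaf.values())
        corr = np.eye(q)
        for i in range(q):
            for j in range(i + 1, q):
                ti, tj = leaf[orders[i]].taxon, leaf[orders[j]].taxon
                # shared path = (d_i + d_j - distance_ij) / 2
                shared = (leaf[orders[i]].root_distance + leaf[orders[j]].root_distance
                          - pdm.patristic_distance(ti, tj)) / 2.0
                corr[i, j] = corr[j, i] = shared / depth
        return corr


def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read a taxonomy from a Newick file (.nwk/.newick/.tre) or a label table."""
    path = Path(path)
    if path.suffix.lower() in (".nwk", ".newick", ".tre", ".tree"):
        return Taxonomy.from_newick(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return Taxonomy.from_table(pd.read_csv(path, sep=sep))


# ---------------------------------------------------------------------------
# Unit conversions

def convert_rate_units(rate: ArmSummary, mass: ArmSummary) -> ArmSummary:
    """Normalise a whole-animal rate (ml/h) to mass-specific units (ml/g/h).

    The mean is divided by mean body mass (g).  The dispersion is propagated
    with the first-order Taylor expression for the SD of a ratio A/B of
    independent quantities::

        SD_out = (A/B) * sqrt(V_A / A**2 + V_B / B**2)

    where ``V_A`` and ``V_B`` are the variances (SD squared) of the rate and
    mass respectively.  A mass row without a usable dispersion can be entered
    with dispersion 0, which reduces the expression to ``sqrt(V_A) / B``.
    """
    if rate.units != "ml/h":
        raise ValueError(f"rate must be in ml/h, got {rate.units!r}")
    if mass.units != "g":
        raise ValueError(f"mass must be in g, got {mass.units!r}")
    if rate.mean <= 0:
        raise ValueError("rate mean must be > 0")
    if mass.mean <= 0:
        raise ValueError("mass mean must be > 0")
    a, b = rate.mean, mass.mean
    va, vb = rate.as_sd().variance, mass.as_sd().variance
    mean_out = a / b
    sd_out = mean_out * math.sqrt(va / a**2 + vb / b**2)
    return ArmSummary(mean=mean_out, dispersion=sd_out, n=rate.n,
                      units="ml/g/h", dispersion_type="sd")


def convert_water_loss_units(arm: ArmSummary) -> ArmSummary:
    """Convert a water-loss arm to mg/h (exact factors; dispersion scales too)."""
    if arm.units not in WATER_LOSS_UNITS:
        raise ValueError(f"not a water-loss unit: {arm.units!r}")
    f = _WATER_LOSS_FACTORS[arm.units]
    return replace(arm, mean=arm.mean * f, dispersion=arm.dispersion * f, units="mg/h")


# ---------------------------------------------------------------------------
# Delimited study tables

TWO_ARM_COLUMNS = [
    "study_id", "order", "family", "species",
    "mean_ref", "disp_ref", "disp_type_ref", "n_ref",
    "mean_cmp", "disp_cmp", "disp_type_cmp", "n_cmp",
    "units",
]
#: optional two-arm columns: temperature_C, mass_mean, mass_disp, mass_disp_type, mass_n

TEMPERATURE_COLUMNS = [
    "study_id", "order", "family", "species",
    "temperature_C", "mean", "disp", "disp_type", "n", "units",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _num(row, col, idx) -> float:
    try:
        return float(row[col])
    except (TypeError, ValueError) as exc:
        raise ParseError(f"row {idx}: column {col!r} is not numeric: {row[col]!r}") from exc


def read_study_table(path: str | Path, schema: str) -> list[StudyRecord]:
    """Read and validate a delimited study table for one objective.

    Delimiter is autodetected from the extension (.csv comma, otherwise tab).
    SE-tagged dispersions are converted to SD via SD = SE*sqrt(n) at read
    time.  Rows violating invariants are rejected with a row-level warning;
    a missing column raises :class:`SchemaError`, a non-numeric cell raises
    :class:`ParseError` naming the row.
    """
    path = Path(path)
    if schema not in OBJECTIVES:
        raise SchemaError(f"unknown schema {schema!r}; known: {OBJECTIVES}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = TEMPERATURE_COLUMNS if schema == "temperature" else TWO_ARM_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"study table missing required column(s): {missing}")
    if schema == "temperature":
        return _read_temperature_rows(df, schema)
    return _read_two_arm_rows(df, schema)


def _read_two_arm_rows(df: pd.DataFrame, schema: str) -> list[StudyRecord]:
    records: list[StudyRecord] = []
    for idx, row in df.iterrows():
        try:
            ref = ArmSummary(
                mean=_num(row, "mean_ref", idx), dispersion=_num(row, "disp_ref", idx),
                n=int(_num(row, "n_ref", idx)), units=str(row["units"]),
                dispersion_type=str(row["disp_type_ref"]).lower(),
            ).as_sd()
            cmp_ = ArmSummary(
                mean=_num(row, "mean_cmp", idx), dispersion=_num(row, "disp_cmp", idx),
                n=int(_num(row, "n_cmp", idx)), units=str(row["units"]),
                dispersion_type=str(row["disp_type_cmp"]).lower(),
            ).as_sd()
            mass = None
            if "mass_mean" in row.index and pd.notna(row.get("mass_mean")):
                mass = ArmSummary(
                    mean=_num(row, "mass_mean", idx),
                    dispersion=_num(row, "mass_disp", idx) if pd.notna(row.get("mass_disp")) else 0.0,
                    n=int(_num(row, "mass_n", idx)) if pd.notna(row.get("mass_n")) else ref.n,
                    units="g",
                    dispersion_type=str(row.get("mass_disp_type", "sd") or "sd").lower(),
                ).as_sd()
            temp = float(row["temperature_C"]) if "temperature_C" in row.index and pd.notna(row.get("temperature_C")) else None
            records.append(StudyRecord(
                study_id=str(row["study_id"]), order=str(row["order"]),
                family=str(row["family"]), species=str(row["species"]),
                objective=schema, arms=(ref, cmp_), temperature_C=temp, mass=mass,
            ))
        except ParseError:
            raise
        except (ValueError, SchemaError) as exc:
            warnings.warn(f"row {idx} rejected: {exc}", stacklevel=2)
    return records


def _read_temperature_rows(df: pd.DataFrame, schema: str) -> list[StudyRecord]:
    records: list[StudyRecord] = []
    for study_id, grp in df.groupby("study_id", sort=False):
        idx0 = grp.index[0]
        try:
            temps, means, sds, ns = [], [], [], []
            for idx, row in grp.iterrows():
                arm = ArmSummary(
                    mean=_num(row, "mean", idx), dispersion=_num(row, "disp", idx),
                    n=int(_num(row, "n", idx)), units=str(row["units"]),
                    dispersion_type=str(row["disp_type"]).lower(),
                ).as_sd()
                temps.append(_num(row, "temperature_C", idx))
                means.append(arm.mean)
                sds.append(arm.sd)
                ns.append(arm.n)
            series = TemperatureSeries(tuple(temps), tuple(means), tuple(sds), tuple(ns))
            first = grp.iloc[0]
            records.append(StudyRecord(
                study_id=str(study_id), order=str(first["order"]),
                family=str(first["family"]), species=str(first["species"]),
                objective="temperature", series=series,
            ))
        except ParseError:
            raise
        except (ValueError, SchemaError) as exc:
            warnings.warn(f"study {study_id!r} (rows from {idx0}) rejected: {exc}", stacklevel=2)
    return records


def write_study_table(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write records back to a delimited table readable by :func:`read_study_table`."""
    path = Path(path)
    sep = _sep_for(path)
    if not records:
        raise ValueError("nothing to write")
    objective = records[0].objective
    rows = []
    if objective == "temperature":
        for rec in records:
            s = rec.series
            for t, m, d, n in zip(s.temperatures, s.means, s.dispersions, s.ns):
                rows.append(dict(study_id=rec.study_id, order=rec.order,
                                 family=rec.family, species=rec.species,
                                 temperature_C=t, mean=m, disp=d,
                                 disp_type=s.dispersion_type, n=n, units="ml/g/h"))
    else:
        for rec in records:
            ref, cmp_ = rec.arms
            row = dict(study_id=rec.study_id, order=rec.order, family=rec.family,
                       species=rec.species,
                       mean_ref=ref.mean, disp_ref=ref.dispersion,
                       disp_type_ref=ref.dispersion_type, n_ref=ref.n,
                       mean_cmp=cmp_.mean, disp_cmp=cmp_.dispersion,
                       disp_type_cmp=cmp_.dispersion_type, n_cmp=cmp_.n,
                       units=ref.units)
            if rec.temperature_C is not None:
                row["temperature_C"] = rec.temperature_C
            if rec.mass is not None:
                row.update(mass_mean=rec.mass.mean, mass_disp=rec.mass.dispersion,
                           mass_disp_type=rec.mass.dispersion_type, mass_n=rec.mass.n)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
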