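"""FFQ-derived trait preprocessing.

Turns raw per-survey intake records into the analysis-ready trait matrix:
energy-reporting exclusion, per-person averaging over repeated surveys,
nutrient density (per 1000 kcal) and percent-of-energy scaling, age
adjustment by OLS residuals, and the rank-based inverse normal transform.
The pipeline order is fixed (filter -> average -> scale -> age-adjust ->
INT) and recorded step by step in the output's provenance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: Atwater factors, kcal per gram.  All fatty-acid classes count as fat.
KCAL_PER_G = {
    "carbohydrate": 4.0,
    "protein": 4.0,
    "fat": 9.0,
    "pufa": 9.0,
    "mufa": 9.0,
    "sfa": 9.0,
    "tfa": 9.0,
}

#: Blom offset for the inverse normal transform.
BLOM_OFFSET = 3.0 / 8.0

ID_COLUMNS = ("fid", "iid", "survey", "age", "sex")


class TraitError(ValueError):
    """Invalid trait input (units, energy, structure)."""


@dataclass
class SurveyTable:
    """Per-survey intake records: one row per (iid, survey).

    ``records`` columns: fid, iid, survey, age, sex, energy_kcal, then one
    column per nutrient.  ``units`` declares the unit of every intake
    column; mixing units for one nutrient across records is rejected at
    read time rather than silently converted.
    """

    records: pd.DataFrame
    units: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS + ("energy_kcal",) if c not in self.records]
        if missing:
            raise TraitError(f"survey table lacks columns {missing}")
        if (self.records["energy_kcal"] <= 0).any():
            bad = self.records.loc[self.records["energy_kcal"] <= 0, ["iid", "survey"]]
            raise TraitError(
                f"non-positive energy for {bad.to_records(index=False).tolist()[:5]}"
            )
        if self.records.duplicated(["fid", "iid", "survey"]).any():
            raise TraitError("duplicate (iid, survey) records")
        undeclared = [c for c in self.nutrient_columns if c not in self.units]
        if undeclared:
            raise TraitError(f"no unit declared for {undeclared}")

    @property
    def nutrient_columns(self) -> list[str]:
        return [
            c for c in self.records.columns
            if c not in ID_COLUMNS and c != "energy_kcal"
        ]


def read_surveys_wide(path, units: dict[str, str] | str) -> SurveyTable:
    """Wide delimited text (one column per nutrient) + unit declaration.

    ``units`` is a mapping column -> unit, or a path to a JSON file with
    that mapping.
    """
    if isinstance(units, str):
        with open(units) as fh:
            units = json.load(fh)
    df = pd.read_csv(path, sep=None, engine="python",
                     dtype={"fid": str, "iid": str})
    return SurveyTable(records=df, units=dict(units))


def read_surveys_long(path) -> SurveyTable:
    """Long delimited text: fid iid survey age sex energy_kcal nutrient amount unit."""
    df = pd.read_csv(path, sep=None, engine="python",
                     dtype={"fid": str, "iid": str})
    need = set(ID_COLUMNS) | {"energy_kcal", "nutrient", "amount", "unit"}
    if not need.issubset(df.columns):
        raise TraitError(f"long survey table lacks columns {sorted(need - set(df.columns))}")
    units: dict[str, str] = {}
    for nut, sub in df.groupby("nutrient"):
        uu = sub["unit"].unique()
        if len(uu) > 1:
            raise TraitError(f"nutrient {nut!r} recorded in mixed units {list(uu)}")
        units[str(nut)] = str(uu[0])
    wide = (
        df.pivot_table(
            index=list(ID_COLUMNS) + ["energy_kcal"],
            columns="nutrient",
            values="amount",
            aggfunc="first",
        )
        .reset_index()
    )
    wide.columns.name = None
    units["energy_kcal"] = "kcal/d"
    return SurveyTable(records=wide, units=units)


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------


def filter_energy(
    table: SurveyTable,
    lo: float = 800.0,
    hi: float = 4200.0,
    mode: str = "per-survey",
) -> tuple[SurveyTable, pd.DataFrame]:
    """Drop implausible energy reports (under/over-reporting screen).

    Records with lo <= energy <= hi are kept (bounds inclusive; only
    strictly lower/higher reports are excluded).  ``mode="per-survey"``
    drops offending person-surveys only; ``mode="per-person"`` drops every
    record of any person with at least one offending survey.  Returns the
    kept table and the excluded rows (with an ``excluded_reason`` column).
    """
    if mode not in ("per-survey", "per-person"):
        raise ValueError(f"unknown filter mode {mode!r}")
    energy = table.records["energy_kcal"]
    bad = (energy < lo) | (energy > hi)
    if mode == "per-person":
        bad_persons = table.records.loc[bad, ["fid", "iid"]].drop_duplicates()
        marker = (
            table.records.merge(
                bad_persons.assign(_bad=True), on=["fid", "iid"], how="left"
            )["_bad"]
            .notna()
            .to_numpy()
        )
        bad = pd.Series(marker, index=table.records.index)
    excluded = table.records[bad].copy()
    excluded["excluded_reason"] = np.where(
        excluded["energy_kcal"] < lo, "energy below bound", "energy above bound"
    )
    kept = table.records[~bad].reset_index(drop=True)
    logger.info(
        "energy filter [%g, %g] (%s): kept %d, excluded %d person-surveys",
        lo, hi, mode, len(kept), len(excluded),
    )
    return SurveyTable(records=kept, units=table.units), excluded


def average_surveys(table: SurveyTable) -> pd.DataFrame:
    """Per-person arithmetic mean of energy and each nutrient.

    Each person's intake is the sum of their surviving measurements
    divided by the number of measurements.  Age is averaged over the same
    surveys; the count of contributing surveys is kept in ``n_surveys``.
    """
    value_cols = ["energy_kcal"] + table.nutrient_columns
    grouped = table.records.groupby(["fid", "iid"], sort=False)
    out = grouped[value_cols + ["age"]].mean()
    out["sex"] = grouped["sex"].first()
    out["n_surveys"] = grouped.size()
    return out.reset_index()


def nutrient_density(amount, energy) -> np.ndarray:
    """Intake per 1000 kcal of energy; unit becomes <unit>/1000 kcal."""
    amount = np.asarray(amount, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if np.any(energy <= 0):
        raise TraitError("nutrient_density requires positive energy")
    return amount * 1000.0 / energy


def percent_energy(amount, macro: str, energy, kcal_per_g: dict | None = None) -> np.ndarray:
    """Percent of total energy supplied by a macronutrient (g/d input)."""
    factors = KCAL_PER_G if kcal_per_g is None else kcal_per_g
    key = macro.lower().removesuffix("_g").removesuffix("s")
    if key not in factors:
        raise TraitError(f"unknown macronutrient {macro!r} (no kcal/g factor)")
    amount = np.asarray(amount, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if np.any(energy <= 0):
        raise TraitError("percent_energy requires positive energy")
    return 100.0 * amount * factors[key] / energy


def adjust_age(values, age) -> np.ndarray:
    """OLS residuals of a trait on intercept + age.

    Residuals sum to zero.  With a constant age vector the regression is
    undefined; the values are centred instead and a warning emitted.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(age, dtype=float)
    if len(y) != len(x):
        raise TraitError("values and age differ in length")
    if np.unique(x).size < 2:
        warnings.warn("constant age vector: centering only", stacklevel=2)
        return y - y.mean()
    if np.unique(x).size < 3:
        raise TraitError("need >=3 distinct ages for a stable adjustment")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(model.resid)


def inverse_normal_transform(values, offset: float = BLOM_OFFSET,
                             min_distinct: int = 5) -> np.ndarray:
    """Rank-based inverse normal transform.

    score_i = Probit((rank_i - c) / (n - 2c + 1)) with Blom offset
    c = 3/8 by default; ties get the average rank.  With fewer than
    ``min_distinct`` distinct values the mapping is heavily tie-degraded
    and a warning is emitted; with all values tied it is undefined.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 2:
        raise TraitError("inverse normal transform needs n >= 2")
    n_distinct = np.unique(y).size
    if n_distinct == 1:
        raise TraitError("inverse normal transform undefined: all values tied")
    if n_distinct < n and n_distinct < min_distinct:
        warnings.warn(
            f"only {n_distinct} distinct values: INT scores are tie-dominated",
            stacklevel=2,
        )
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PreprocessConfig:
    """Configuration of the fixed preprocessing pipeline.

    ``density``/``percent``/``gram`` select which nutrients are carried
    forward on which scale; unlisted nutrients are dropped.  Traits are
    age-adjusted by pooled OLS (optionally within sex strata) and then
    inverse-normal transformed.
    """

    energy_lo: float = 800.0
    energy_hi: float = 4200.0
    filter_mode: str = "per-survey"
    density: Sequence[str] = ()
    percent: Sequence[str] = ()
    gram: Sequence[str] = ()
    include_energy: bool = True
    int_offset: float = BLOM_OFFSET
    adjust_age: bool = True
    sex_stratified: bool = False
    apply_int: bool = True
    kcal_per_g: dict | None = None


@dataclass
class TraitTable:
    """Analysis-ready per-person trait matrix with provenance.

    ``values`` columns: fid, iid, sex, age, n_surveys, then one column per
    trait.  ``provenance`` is the append-only list of applied transforms.
    """

    values: pd.DataFrame
    units: dict[str, str]
    provenance: list[dict] = field(default_factory=list)

    @property
    def trait_names(self) -> list[str]:
        drop = {"fid", "iid", "sex", "age", "n_surveys"}
        return [c for c in self.values.columns if c not in drop]

    def trait_vector(self, trait: str) -> pd.Series:
        if trait not in self.values.columns:
            raise KeyError(f"trait {trait!r} not in table")
        return self.values.set_index(["fid", "iid"])[trait]

    def record(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})

    def write(self, path, provenance_path=None) -> None:
        """TSV matrix plus a sidecar JSON with units and provenance."""
        self.values.to_csv(path, sep="\t", index=False)
        if provenance_path is None:
            provenance_path = str(path) + ".provenance.json"
        with open(provenance_path, "w") as fh:
            json.dump(
                {"units": self.units, "provenance": self.provenance},
                fh, indent=1, sort_keys=False,
            )


def preprocess(table: SurveyTable, cfg: PreprocessConfig | None = None) -> TraitTable:
    """Run the full fixed-order pipeline on raw survey records.

    filter -> average -> density / percent-of-energy -> age-adjust -> INT.
    Re-running with identical inputs and config is bit-reproducible (the
    pipeline is deterministic).
    """
    cfg = cfg or PreprocessConfig()
    prov: list[dict] = []

    kept, excluded = filter_energy(table, cfg.energy_lo, cfg.energy_hi, cfg.filter_mode)
    prov.append({
        "step": "filter_energy", "lo": cfg.energy_lo, "hi": cfg.energy_hi,
        "mode": cfg.filter_mode, "n_excluded": int(len(excluded)),
    })
    person = average_surveys(kept)
    prov.append({"step": "average_surveys", "n_persons": int(len(person))})

    units: dict[str, str] = {}
    out = person[["fid", "iid", "sex", "age", "n_surveys"]].copy()
    if cfg.include_energy:
        out["energy_kcal"] = person["energy_kcal"]
        units["energy_kcal"] = "kcal/d"
    gram = list(cfg.gram) if (cfg.gram or cfg.density or cfg.percent) else kept.nutrient_columns
    for nut in gram:
        out[f"{nut}_g"] = person[nut]
        units[f"{nut}_g"] = table.units.get(nut, "g/d")
    for nut in cfg.density:
        out[f"{nut}_per1000kcal"] = nutrient_density(person[nut], person["energy_kcal"])
        units[f"{nut}_per1000kcal"] = f"{table.units.get(nut, 'g/d')} per 1000 kcal"
    for nut in cfg.percent:
        out[f"{nut}_pct_kcal"] = percent_energy(
            person[nut], nut, person["energy_kcal"], cfg.kcal_per_g
        )
        units[f"{nut}_pct_kcal"] = "% of kcal"
    prov.append({
        "step": "scale", "gram": list(gram), "density": list(cfg.density),
        "percent": list(cfg.percent),
    })

    result = TraitTable(values=out, units=units, provenance=prov)
    trait_cols = result.trait_names
    if cfg.adjust_age:
        for col in trait_cols:
            if cfg.sex_stratified:
                resid = np.empty(len(out))
                for _, idx in out.groupby("sex").groups.items():
                    resid[out.index.get_indexer(idx)] = adjust_age(
                        out.loc[idx, col], out.loc[idx, "age"]
                    )
                out[col] = resid
            else:
                out[col] = adjust_age(out[col], out["age"])
        result.record("adjust_age", sex_stratified=cfg.sex_stratified)
    if cfg.apply_int:
        for col in trait_cols:
            out[col] = inverse_normal_transform(out[col], cfg.int_offset)
        result.record("inverse_normal_transform", offset=cfg.int_offset)
    return result


def read_trait_table(path, provenance_path=None) -> TraitTable:
    """Read a trait matrix written by :meth:`TraitTable.write`."""
    df = pd.read_csv(path, sep="\t", dtype={"fid": str, "iid": str})
    units: dict[str, str] = {}
    prov: list[dict] = []
    if provenance_path is None:
        provenance_path = str(path) + ".provenance.json"
    try:
        with open(provenance_path) as fh:
            meta = json.load(fh)
        units = meta.get("units", {})
        prov = meta.get("provenance", [])
    except FileNotFoundError:
        logger.warning("no provenance sidecar found for %s", path)
    return TraitTable(values=df, units=units, provenance=prov)
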