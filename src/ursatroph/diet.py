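"""Diet compositions for terrestrial bears: I/O, validation and arithmetic.

A diet record (one study-year or study-location combination) reports food
items mapped onto 20 macroecological diet categories, quantified as the
relative frequency of occurrence F_i (occurrences of item i over total
occurrences) and/or the relative volume V_i.  Relative volumes are converted
to relative dietary energy contributions with per-category correction factors
for digestibility (c_D) and energy content (c_E):

    E_i = c_Di * c_Ei * V_i / sum_i c_Di * c_Ei * V_i

The trophic position of a record is the animal-prey energy share
P = sum of E_i over vertebrate and invertebrate categories.  For regression
on the probit scale, proportions in the closed unit interval are compressed
into the open interval before the probit:

    y = probit((P * (n - 1) + 0.5) / n)

with n the number of trophic-position observations in the fitted dataset.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

COMPOSITION_TOL = 1e-9


class InvalidComposition(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class TrophicClass(str, enum.Enum):
    ANIMAL_VERTEBRATE = "animal_vertebrate"
    ANIMAL_INVERTEBRATE = "animal_invertebrate"
    PLANT = "plant"
    FUNGI = "fungi"
    OTHER = "other"


#: classes whose energy counts toward animal prey (vertebrates + invertebrates;
#: carrion is classed as animal_vertebrate)
ANIMAL_CLASSES = frozenset(
    {TrophicClass.ANIMAL_VERTEBRATE.value, TrophicClass.ANIMAL_INVERTEBRATE.value}
)

BEAR_SPECIES = (
    "Ursus arctos",
    "Ursus americanus",
    "Ursus thibetanus",
    "Helarctos malayanus",
    "Melursus ursinus",
    "Tremarctos ornatus",
    "Ailuropoda melanoleuca",
)

CO_OCCURRENCE_LEVELS = ("none", "subordinate", "dominant")


@dataclasses.dataclass(frozen=True)
class DietCategory:
    name: str
    trophic_class: TrophicClass
    c_D: float  # digestibility correction factor
    c_E: float  # energy-content correction factor

    def __post_init__(self) -> None:
        if self.c_D <= 0 or self.c_E <= 0:
            raise ValueError(f"correction factors for {self.name} must be > 0")


# The 20-category scheme of the macroecological diet classification.  The
# correction factors shipped here are round placeholder values on the scale of
# published digestibility/energy tables, documented as such; analyses of real
# data should supply the literature table via a categories CSV.
_DEFAULT_ROWS = [
    # name, class, c_D, c_E
    ("mammals_large", "animal_vertebrate", 0.90, 1.6),
    ("mammals_small", "animal_vertebrate", 0.90, 1.5),
    ("carrion", "animal_vertebrate", 0.90, 1.6),
    ("birds", "animal_vertebrate", 0.90, 1.5),
    ("eggs", "animal_vertebrate", 0.95, 1.6),
    ("reptiles_amphibians", "animal_vertebrate", 0.90, 1.3),
    ("fish", "animal_vertebrate", 0.90, 1.5),
    ("insects_social", "animal_invertebrate", 0.80, 1.2),
    ("insects_other", "animal_invertebrate", 0.80, 1.2),
    ("invertebrates_other", "animal_invertebrate", 0.80, 1.1),
    ("fruits_fleshy", "plant", 0.65, 0.9),
    ("seeds_nuts", "plant", 0.70, 1.4),
    ("graminoids", "plant", 0.30, 0.6),
    ("forbs", "plant", 0.35, 0.6),
    ("foliage_browse", "plant", 0.30, 0.6),
    ("roots_tubers", "plant", 0.50, 0.8),
    ("bamboo", "plant", 0.25, 0.6),
    ("other_plant_material", "plant", 0.35, 0.6),
    ("fungi_lichens", "fungi", 0.40, 0.6),
    ("anthropogenic_other", "other", 0.70, 1.0),
]


def default_categories() -> pd.DataFrame:
    """The default 20-category table (category index; trophic_class, c_D, c_E)."""
    df = pd.DataFrame(_DEFAULT_ROWS, columns=["category", "trophic_class", "c_D", "c_E"])
    return df.set_index("category")


def validate_categories(categories: pd.DataFrame) -> pd.DataFrame:
    if categories.index.has_duplicates:
        raise ConfigurationError("duplicate category names in table")
    for col in ("trophic_class", "c_D", "c_E"):
        if col not in categories.columns:
            raise ConfigurationError(f"categories table missing column {col!r}")
    if (categories["c_D"] <= 0).any() or (categories["c_E"] <= 0).any():
        bad = categories.index[(categories["c_D"] <= 0) | (categories["c_E"] <= 0)]
        raise ConfigurationError(f"non-positive correction factors for {list(bad)}")
    valid = {c.value for c in TrophicClass}
    unknown = set(categories["trophic_class"]) - valid
    if unknown:
        raise ConfigurationError(f"unknown trophic classes: {sorted(unknown)}")
    return categories


@dataclasses.dataclass
class DietDataset:
    """One study-location diet composition with environmental covariates.

    ``items`` maps category name -> (F, V); V is NaN when the study reported
    only occurrence data, in which case the record is flagged for imputation.
    """

    dataset_id: str
    study_id: str
    species: str
    lat: float
    lon: float
    sample_type: str  # scat | stomach
    n_samples: int
    items: pd.DataFrame  # index category, columns F, V
    npp: float  # kg C m^-2 a^-1
    gsl: int  # months with mean T > 0 degC
    co_occurrence: str  # none | subordinate | dominant

    def __post_init__(self) -> None:
        if self.sample_type not in ("scat", "stomach"):
            raise ValueError(f"{self.dataset_id}: bad sample_type {self.sample_type!r}")
        if self.co_occurrence not in CO_OCCURRENCE_LEVELS:
            raise ValueError(f"{self.dataset_id}: bad co_occurrence "
                             f"{self.co_occurrence!r}")
        if self.npp <= 0:
            raise ValueError(f"{self.dataset_id}: npp must be > 0")
        if not 0 <= int(self.gsl) <= 12:
            raise ValueError(f"{self.dataset_id}: gsl must be in 0..12")
        if self.n_samples <= 0:
            raise ValueError(f"{self.dataset_id}: n_samples must be positive")
        f = self.items["F"].to_numpy(dtype=float)
        if np.any((f < -COMPOSITION_TOL) | (f > 1 + COMPOSITION_TOL)):
            raise InvalidComposition(f"{self.dataset_id}: F outside [0, 1]")
        if abs(f.sum() - 1.0) > COMPOSITION_TOL:
            raise InvalidComposition(
                f"{self.dataset_id}: F sums to {f.sum():.6g}, expected 1")
        v = self.items["V"].to_numpy(dtype=float)
        if not np.all(np.isnan(v)):
            if np.isnan(v).any():
                raise InvalidComposition(
                    f"{self.dataset_id}: V partially missing; report all or none")
            if np.any((v < -COMPOSITION_TOL) | (v > 1 + COMPOSITION_TOL)):
                raise InvalidComposition(f"{self.dataset_id}: V outside [0, 1]")
            if abs(v.sum() - 1.0) > COMPOSITION_TOL:
                raise InvalidComposition(
                    f"{self.dataset_id}: V sums to {v.sum():.6g}, expected 1")

    @property
    def needs_imputation(self) -> bool:
        return bool(self.items["V"].isna().all())


@dataclasses.dataclass(frozen=True)
class EnergyComposition:
    dataset_id: str
    E: pd.Series  # category -> relative dietary energy contribution
    P: float  # animal-prey energy share


def normalize_frequencies(counts: Mapping[str, float] | pd.Series) -> pd.Series:
    """Occurrence counts -> relative frequencies F_i = f_i / sum f_i."""
    s = pd.Series(counts, dtype=float)
    if (s < 0).any():
        raise InvalidComposition("negative counts")
    total = s.sum()
    if total <= 0:
        raise InvalidComposition("all counts are zero")
    return s / total


def energy_contribution(
    V: Mapping[str, float] | pd.Series,
    categories: pd.DataFrame,
    dataset_id: str = "",
) -> EnergyComposition:
    """Relative dietary energy contribution and animal-prey share from volumes."""
    v = pd.Series(V, dtype=float)
    missing = [c for c in v.index if c not in categories.index]
    if missing:
        raise ConfigurationError(
            f"no correction factors for categories: {missing}")
    cats = categories.loc[v.index]
    w = cats["c_D"].to_numpy() * cats["c_E"].to_numpy() * v.to_numpy()
    total = w.sum()
    if total <= 0:
        raise InvalidComposition("energy weights sum to zero")
    e = pd.Series(w / total, index=v.index)
    animal = cats["trophic_class"].isin(ANIMAL_CLASSES).to_numpy()
    return EnergyComposition(dataset_id=dataset_id, E=e, P=float(e.to_numpy()[animal].sum()))


def probit_compress(P: np.ndarray | float, n: int) -> np.ndarray | float:
    """Compress proportions from [0, 1] into (0, 1) and apply the probit.

    y = probit((P (n - 1) + 0.5) / n); strictly increasing in P, finite for
    all P in the closed unit interval, and invertible.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    p = np.asarray(P, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = ndtri((p * (n - 1) + 0.5) / n)
    return float(out) if np.isscalar(P) else out


def probit_decompress(y: np.ndarray | float, n: int) -> np.ndarray | float:
    """Inverse of :func:`probit_compress`."""
    if n < 2:
        raise ValueError("n must be >= 2")
    out = (ndtr(np.asarray(y, dtype=float)) * n - 0.5) / (n - 1)
    return float(out) if np.isscalar(y) else out


DIET_COLUMNS = ["dataset_id", "study_id", "species", "lat", "lon", "sample_type",
                "n_samples", "category", "F", "V", "npp", "gsl", "co_occurrence"]


class ParseError(ValueError):
    pass


def read_categories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "category" not in df.columns:
        raise ParseError(f"{path}: categories file needs a 'category' column")
    return validate_categories(df.set_index("category"))


def read_diet_table(path: str | Path) -> list[DietDataset]:
    """Read the canonical long-format diet CSV (one row per dataset x category)."""
    df = pd.read_csv(path)
    missing = [c for c in DIET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out: list[DietDataset] = []
    for ds_id, grp in df.groupby("dataset_id", sort=False):
        head = grp.iloc[0]
        items = grp.set_index("category")[["F", "V"]].astype(float)
        if items.index.has_duplicates:
            raise ParseError(f"{path}: duplicate categories in dataset {ds_id}")
        try:
            out.append(DietDataset(
                dataset_id=str(ds_id),
                study_id=str(head["study_id"]),
                species=str(head["species"]),
                lat=float(head["lat"]),
                lon=float(head["lon"]),
                sample_type=str(head["sample_type"]),
                n_samples=int(head["n_samples"]),
                items=items,
                npp=float(head["npp"]),
                gsl=int(head["gsl"]),
                co_occurrence=str(head["co_occurrence"]),
            ))
        except (InvalidComposition, ValueError) as err:
            first_row = int(grp.index.min()) + 2  # 1-based incl. header
            raise type(err)(f"{path} near row {first_row}: {err}") from err
    return out


def write_diet_table(datasets: Iterable[DietDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for cat, rec in ds.items.iterrows():
            rows.append({
                "dataset_id": ds.dataset_id, "study_id": ds.study_id,
                "species": ds.species, "lat": ds.lat, "lon": ds.lon,
                "sample_type": ds.sample_type, "n_samples": ds.n_samples,
                "category": cat, "F": rec["F"], "V": rec["V"],
                "npp": ds.npp, "gsl": ds.gsl, "co_occurrence": ds.co_occurrence,
            })
    pd.DataFrame(rows, columns=DIET_COLUMNS).to_csv(path, index=False)


def read_diet_workbook(path: str | Path, sheet: str | int = 0,
                       column_map: Mapping[str, str] | None = None) -> list[DietDataset]:
    """Read a deposited-workbook layout by mapping its columns onto the CSV schema.

    ``column_map`` maps workbook column names to canonical names; unmapped
    canonical columns must already be present under their canonical name.
    Requires openpyxl.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in DIET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: workbook missing columns {missing}")
    tmp = Path(path).with_suffix(".mapped.csv")
    df[DIET_COLUMNS].to_csv(tmp, index=False)
    try:
        return read_diet_table(tmp)
    finally:
        tmp.unlink(missing_ok=True)
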