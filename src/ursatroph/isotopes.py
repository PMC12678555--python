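"""Collagen isotope samples: quality control, marine screen, time binning.

Collagen δ15N/δ13C measurements on dated bone and tooth material of brown
bear (consumer) and red deer (herbivore baseline).  Reliability follows the
standard collagen-preservation criteria: atomic C/N in the range 2.9–3.6
(inclusive) and carbon and nitrogen content strictly above 8% and 3%.
Calibrated ages (ka BP) are binned into eight stratigraphic periods spanning
the last 55 ka; the 38.2–43.8 ka interval is deliberately unbinned.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TAXA = ("brown_bear", "red_deer")
MATERIALS = ("bone", "tooth")

CN_RANGE = (2.9, 3.6)  # inclusive
PCT_C_MIN = 8.0  # strict
PCT_N_MIN = 3.0  # strict


@dataclasses.dataclass(frozen=True)
class TimeBin:
    name: str
    lower: float  # ka BP (younger edge)
    upper: float  # ka BP (older edge)

    def __contains__(self, age_ka: float) -> bool:
        # half-open [lower, upper): a boundary age belongs to the younger-bounded bin
        return self.lower <= age_ka < self.upper


DEFAULT_BINS: tuple[TimeBin, ...] = (
    TimeBin("Meghalayan", 0.0, 4.2),
    TimeBin("Northgrippian", 4.2, 8.2),
    TimeBin("Greenlandian", 8.2, 11.7),
    TimeBin("GS-1", 11.7, 12.8),
    TimeBin("GI-1", 12.8, 14.6),
    TimeBin("GS-2_GI-2", 14.6, 23.3),
    TimeBin("GS-3_GI-8", 23.3, 38.2),
    TimeBin("GS-9_GI-14", 43.8, 54.2),
)

PERIOD_NAMES = tuple(b.name for b in DEFAULT_BINS)


class BinConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class IsotopeSample:
    sample_id: str
    taxon: str  # brown_bear | red_deer
    d15N: float  # per mil vs AIR
    d13C: float  # per mil vs VPDB
    pctC: float
    pctN: float
    cn_atomic: float
    material: str  # bone | tooth
    elevation: float  # m a.s.l.
    age_ka: float  # calibrated ka BP (point value)
    lat: float = float("nan")
    lon: float = float("nan")
    period: str | None = None

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"{self.sample_id}: unknown taxon {self.taxon!r}")
        if self.material not in MATERIALS:
            raise ValueError(f"{self.sample_id}: unknown material {self.material!r}")


@dataclasses.dataclass(frozen=True)
class QCResult:
    sample_id: str
    passed: bool
    reasons: tuple[str, ...]


@dataclasses.dataclass
class ReferenceTables:
    """Literature reference data feeding the bias-correction sub-models."""

    tooth_bone: np.ndarray  # paired tooth - bone d15N differences (per mil)
    elevation: pd.DataFrame  # columns d15N, elevation, material
    tdf: np.ndarray  # predator - prey d15N differences (per mil)
    marine: pd.DataFrame  # columns d13C, d15N

    def validate(self) -> None:
        if len(self.tooth_bone) == 0:
            raise ValueError("tooth-bone reference table is empty")
        if len(self.elevation) == 0:
            raise ValueError("elevation reference table is empty")
        if len(self.tdf) == 0:
            raise ValueError("TDF reference table is empty")


def qc_collagen(sample: IsotopeSample) -> QCResult:
    """Collagen-preservation check; reasons list every failed criterion."""
    reasons: list[str] = []
    fields = {"cn_atomic": sample.cn_atomic, "pctC": sample.pctC,
              "pctN": sample.pctN}
    missing = [k for k, v in fields.items() if v is None or np.isnan(v)]
    if missing:
        return QCResult(sample.sample_id, False,
                        tuple(f"missing QC field {m}" for m in missing))
    if not CN_RANGE[0] <= sample.cn_atomic <= CN_RANGE[1]:
        reasons.append(f"C/N {sample.cn_atomic:g} outside {CN_RANGE[0]}-{CN_RANGE[1]}")
    if not sample.pctC > PCT_C_MIN:
        reasons.append(f"%C {sample.pctC:g} not above {PCT_C_MIN:g}")
    if not sample.pctN > PCT_N_MIN:
        reasons.append(f"%N {sample.pctN:g} not above {PCT_N_MIN:g}")
    return QCResult(sample.sample_id, not reasons, tuple(reasons))


def validate_bins(bins: Sequence[TimeBin]) -> Sequence[TimeBin]:
    ordered = sorted(bins, key=lambda b: b.lower)
    for b in ordered:
        if not b.lower < b.upper:
            raise BinConfigurationError(f"bin {b.name} has lower >= upper")
    for a, b in zip(ordered, ordered[1:]):
        if b.lower < a.upper:
            raise BinConfigurationError(f"bins {a.name} and {b.name} overlap")
    return bins


def assign_period(age_ka: float, bins: Sequence[TimeBin] = DEFAULT_BINS) -> str | None:
    """Bin whose half-open [lower, upper) interval contains the age, else None."""
    if age_ka < 0:
        raise ValueError("age must be >= 0 ka BP")
    validate_bins(bins)
    for b in bins:
        if age_ka in b:
            return b.name
    return None


def assign_periods(samples: Iterable[IsotopeSample],
                   bins: Sequence[TimeBin] = DEFAULT_BINS) -> list[IsotopeSample]:
    for s in samples:
        s.period = assign_period(s.age_ka, bins)
    return list(samples)


def marine_envelope(marine_refs: pd.DataFrame, expand: float = 1.0):
    """Marine envelope: convex hull of reference (δ13C, δ15N) points, buffered.

    The buffer distance (per mil, both axes) is configurable; 1 per mil by
    default.  Degenerate reference sets (1–2 points) still yield a valid
    buffered region.
    """
    from shapely.geometry import MultiPoint

    pts = MultiPoint(list(zip(marine_refs["d13C"], marine_refs["d15N"])))
    return pts.convex_hull.buffer(expand)


def marine_screen(
    bears: Sequence[IsotopeSample],
    marine_refs: pd.DataFrame,
    expand: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Flag bear samples whose (δ13C, δ15N) fall inside the marine envelope.

    Diagnostic only: returns the per-sample flag table and the flagged
    fraction.
    """
    from shapely.geometry import Point

    if len(marine_refs) == 0:
        raise ValueError("marine reference table is empty")
    env = marine_envelope(marine_refs, expand=expand)
    flags = [env.covers(Point(s.d13C, s.d15N)) for s in bears]
    table = pd.DataFrame({
        "sample_id": [s.sample_id for s in bears],
        "d13C": [s.d13C for s in bears],
        "d15N": [s.d15N for s in bears],
        "marine_flag": flags,
    })
    frac = float(np.mean(flags)) if flags else 0.0
    return table, frac


ISOTOPE_COLUMNS = ["sample_id", "taxon", "d15N", "d13C", "pctC", "pctN",
                   "cn_atomic", "material", "elevation", "age_ka", "lat", "lon"]


def read_isotope_table(path: str | Path) -> list[IsotopeSample]:
    df = pd.read_csv(path)
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(IsotopeSample(
                sample_id=str(row["sample_id"]), taxon=str(row["taxon"]),
                d15N=float(row["d15N"]), d13C=float(row["d13C"]),
                pctC=float(row["pctC"]), pctN=float(row["pctN"]),
                cn_atomic=float(row["cn_atomic"]), material=str(row["material"]),
                elevation=float(row["elevation"]), age_ka=float(row["age_ka"]),
                lat=float(row["lat"]), lon=float(row["lon"]),
            ))
        except ValueError as err:
            raise ValueError(f"{path} row {i + 2}: {err}") from err
    return out


def write_isotope_table(samples: Iterable[IsotopeSample], path: str | Path) -> None:
    rows = [{c: getattr(s, c if c != "age_ka" else "age_ka") for c in ISOTOPE_COLUMNS}
            for s in samples]
    pd.DataFrame(rows, columns=ISOTOPE_COLUMNS).to_csv(path, index=False)


def qc_report(samples: Iterable[IsotopeSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        r = qc_collagen(s)
        rows.append({"sample_id": r.sample_id, "pass": r.passed,
                     "reasons": "; ".join(r.reasons)})
    return pd.DataFrame(rows, columns=["sample_id", "pass", "reasons"])
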