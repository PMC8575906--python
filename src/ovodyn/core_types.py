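"""Shared domain model: controlled vocabularies, per-female records, CSV schemas.

The pipeline revolves around three observation tables joined on ``female_id``:

* biometry (``females.csv``) — length, weight, formalin-preserved ovary weight,
  maturity stage on the IMR 8-stage scale, capture date;
* wholemount diameters (``wholemount.csv``) — formalin-preserved oocyte
  diameters (µm) measured from dissociated-oocyte images;
* histology (``histology_hits.csv`` + ``histology_axes.csv``) — Weibel-grid
  point counts per annotated structure and long/short axis measurements of
  through-the-nucleus oocyte profiles, at the (shrunken) histology scale.

Oocytes are classified into 13 developmental categories, from the smallest
previtellogenic phases (PVO1–PVO4c) through cortical alveoli (CA), the
vitellogenic phases (VO1–VO3) and final maturation (GVM, GVBD, HYD).
Non-oocyte annotations (atresia classes, postovulatory follicles, and a
catch-all OTHERS for stroma, follicle walls, late POFs and beta atresia)
share the grid-count table but never receive packing densities.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PhaseGroup",
    "PhaseCode",
    "OOCYTE_PHASES",
    "PVO_PHASES",
    "DEVELOPING_PHASES",
    "OPD_PHASES",
    "STRUCTURE_CODES",
    "ATRESIA_CODES",
    "FemaleRecord",
    "WholemountSample",
    "HistologySample",
    "Violation",
    "validate_record",
    "map_walsh_to_imr",
    "read_females",
    "write_females",
    "females_to_records",
    "read_wholemount",
    "write_wholemount",
    "wholemount_samples",
    "read_histology_hits",
    "read_histology_axes",
    "write_histology_hits",
    "write_histology_axes",
    "histology_samples",
]


class PhaseGroup(str, Enum):
    """Coarse grouping used by the oocyte-ratio split and reporting."""

    PVO = "PVO"
    CA_VO = "CA_VO"
    FOM = "FOM"
    STRUCTURE = "STRUCTURE"


class PhaseCode(Enum):
    """One of the 13 oocyte categories or a non-oocyte structure annotation.

    Oocyte members carry a total developmental order (``PVO1 < PVO2 < … <
    HYD``) and support comparison; structure annotations do not.
    """

    PVO1 = "PVO1"
    PVO2 = "PVO2"
    PVO3 = "PVO3"
    PVO4a = "PVO4a"
    PVO4b = "PVO4b"
    PVO4c = "PVO4c"
    CA = "CA"
    VO1 = "VO1"
    VO2 = "VO2"
    VO3 = "VO3"
    GVM = "GVM"
    GVBD = "GVBD"
    HYD = "HYD"
    # structure annotations (never assigned a packing density)
    ATR_PVO = "ATR_PVO"
    ATR_EARLY_ALPHA = "ATR_EARLY_ALPHA"
    ATR_LATE_ALPHA = "ATR_LATE_ALPHA"
    POF = "POF"
    OTHERS = "OTHERS"

    @property
    def group(self) -> PhaseGroup:
        if self.value.startswith("PVO"):
            return PhaseGroup.PVO
        if self.value in ("CA", "VO1", "VO2", "VO3"):
            return PhaseGroup.CA_VO
        if self.value in ("GVM", "GVBD", "HYD"):
            return PhaseGroup.FOM
        return PhaseGroup.STRUCTURE

    @property
    def is_oocyte(self) -> bool:
        return self.group is not PhaseGroup.STRUCTURE

    @property
    def rank(self) -> int:
        """Developmental order index (0 = PVO1). Undefined for structures."""
        if not self.is_oocyte:
            raise TypeError(f"{self.value} is a structure annotation, not an oocyte phase")
        return _OOCYTE_ORDER[self]

    def __lt__(self, other: "PhaseCode") -> bool:
        if not isinstance(other, PhaseCode):
            return NotImplemented
        return self.rank < other.rank

    def __le__(self, other: "PhaseCode") -> bool:
        if not isinstance(other, PhaseCode):
            return NotImplemented
        return self.rank <= other.rank


OOCYTE_PHASES: tuple[PhaseCode, ...] = tuple(p for p in PhaseCode if p.value[0] != "A" and p.value not in ("POF", "OTHERS"))
_OOCYTE_ORDER = {p: i for i, p in enumerate(OOCYTE_PHASES)}

PVO_PHASES: tuple[PhaseCode, ...] = tuple(p for p in OOCYTE_PHASES if p.group is PhaseGroup.PVO)
#: phases on the developing side of the oocyte ratio (CA is grouped with VOs)
DEVELOPING_PHASES: tuple[PhaseCode, ...] = tuple(
    p for p in OOCYTE_PHASES if p.group in (PhaseGroup.CA_VO, PhaseGroup.FOM)
)
#: phases that receive a packing density: PVO1 is too sparse on the grid and
#: hydrated oocytes deform too irregularly to measure, so both are excluded.
OPD_PHASES: tuple[PhaseCode, ...] = tuple(
    p for p in OOCYTE_PHASES if p not in (PhaseCode.PVO1, PhaseCode.HYD)
)
STRUCTURE_CODES: tuple[PhaseCode, ...] = tuple(p for p in PhaseCode if not p.is_oocyte)
ATRESIA_CODES: tuple[PhaseCode, ...] = (
    PhaseCode.ATR_PVO,
    PhaseCode.ATR_EARLY_ALPHA,
    PhaseCode.ATR_LATE_ALPHA,
)

_VALID_CODES = {p.value for p in PhaseCode}


class Violation(NamedTuple):
    field: str
    reason: str


@dataclass
class FemaleRecord:
    """Biometry and stage metadata for one female.

    ``maturity_stage`` follows the IMR 8-stage scale (1–2 juvenile, 3–5
    maturing, 6 spawning, 7 spent, 8 resting). ``prespawning_flag`` marks
    females sampled before the spawning season; it is authoritative for
    oocyte-ratio category 0 (see :mod:`ovodyn.ultrametric`).
    """

    female_id: str
    capture_date: _dt.date
    total_length: float  # TL, cm
    body_weight: float  # W, g
    ovary_weight: float  # OW, g (formalin-preserved)
    maturity_stage: int
    prespawning_flag: bool = False

    @property
    def year(self) -> int:
        return self.capture_date.year

    @property
    def month(self) -> int:
        return self.capture_date.month


@dataclass
class WholemountSample:
    """A female's vector of formalin-preserved oocyte diameters (µm)."""

    female_id: str
    diameters: np.ndarray
    n_images: int = 3

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)


@dataclass
class HistologySample:
    """Weibel-grid counts plus axis measurements for one female's section.

    ``grid_hits`` maps phase/structure codes (strings) to point counts out of
    ``total_grid_points``. ``axis_measurements`` holds ``(phase, L, S)``
    triples at the histology (post-dehydration) scale, in µm.
    """

    female_id: str
    grid_hits: dict[str, int]
    total_grid_points: int = 500
    axis_measurements: list[tuple[str, float, float]] = field(default_factory=list)
    section_area_mm2: float = float("nan")

    @property
    def half_section_analysed(self) -> bool:
        # sections >= 100 mm2 are only half-read in the source protocol
        return bool(self.section_area_mm2 >= 100.0)

    def axes_for_phase(self, phase: Union[PhaseCode, str]) -> list[tuple[float, float]]:
        code = phase.value if isinstance(phase, PhaseCode) else str(phase)
        return [(L, S) for p, L, S in self.axis_measurements if p == code]


# ---------------------------------------------------------------------------
# validation


def _validate_female(rec: FemaleRecord) -> list[Violation]:
    v: list[Violation] = []
    if not rec.total_length > 0:
        v.append(Violation("total_length", "TL must be > 0 cm"))
    if not rec.body_weight > 0:
        v.append(Violation("body_weight", "W must be > 0 g"))
    if rec.ovary_weight < 0:
        v.append(Violation("ovary_weight", "OW must be >= 0 g"))
    elif rec.ovary_weight >= rec.body_weight > 0:
        v.append(Violation("ovary_weight", "OW must be smaller than W"))
    if rec.maturity_stage not in range(1, 9):
        v.append(Violation("maturity_stage", "maturity stage must be in 1..8 (IMR scale)"))
    return v


def _validate_wholemount(sample: WholemountSample) -> list[Violation]:
    v: list[Violation] = []
    d = sample.diameters
    if d.size and not np.all(np.isfinite(d)):
        v.append(Violation("diameters", "non-finite diameter present"))
    if d.size and np.any(d <= 0):
        v.append(Violation("diameters", "non-positive diameter present"))
    if sample.n_images < 1:
        v.append(Violation("n_images", "at least one image required"))
    return v


def _validate_histology(sample: HistologySample) -> list[Violation]:
    v: list[Violation] = []
    for code, hits in sample.grid_hits.items():
        if code not in _VALID_CODES:
            v.append(Violation("grid_hits", f"unknown structure code {code!r}"))
        if hits < 0 or int(hits) != hits:
            v.append(Violation("grid_hits", f"hit count for {code} must be a non-negative integer"))
    if sum(sample.grid_hits.values()) > sample.total_grid_points:
        v.append(Violation("grid_hits", "sum of hits exceeds total grid points"))
    for code, L, S in sample.axis_measurements:
        if code not in _VALID_CODES:
            v.append(Violation("axis_measurements", f"unknown phase code {code!r}"))
        if not S > 0:
            v.append(Violation("axis_measurements", f"{code}: short axis must be > 0"))
        elif L < S:
            v.append(Violation("axis_measurements", f"{code}: long axis {L} < short axis {S}"))
    return v


def validate_record(
    record: Union[FemaleRecord, WholemountSample, HistologySample],
) -> list[Violation]:
    """Check a record against its type invariants.

    Returns an empty list iff all invariants hold; violations carry the field
    name and a human-readable reason instead of raising.
    """
    if isinstance(record, FemaleRecord):
        return _validate_female(record)
    if isinstance(record, WholemountSample):
        return _validate_wholemount(record)
    if isinstance(record, HistologySample):
        return _validate_histology(record)
    raise TypeError(f"unsupported record type {type(record).__name__}")


def map_walsh_to_imr(stages: Iterable[int], lookup: Mapping[int, int]) -> list[int]:
    """Reclassify Walsh 6-stage maturities to the IMR 8-stage scale.

    No canonical translation table exists; the caller supplies the lookup
    appropriate to their survey protocol. Unknown stages raise ``KeyError``.
    """
    out = []
    for s in stages:
        if s not in lookup:
            raise KeyError(f"Walsh stage {s} missing from user-supplied lookup")
        imr = lookup[s]
        if imr not in range(1, 9):
            raise ValueError(f"lookup maps Walsh stage {s} to invalid IMR stage {imr}")
        out.append(imr)
    return out


# ---------------------------------------------------------------------------
# CSV schemas (header mandatory, UTF-8, '.' decimal separator)

FEMALES_COLUMNS = [
    "female_id",
    "capture_date",
    "total_length_cm",
    "body_weight_g",
    "ovary_weight_g",
    "maturity_stage",
    "prespawning_flag",
]
WHOLEMOUNT_COLUMNS = ["female_id", "image_no", "diameter_um"]
HITS_COLUMNS = ["female_id", "structure", "hits", "total_points", "section_area_mm2"]
AXES_COLUMNS = ["female_id", "phase", "long_axis_um", "short_axis_um"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required column(s) {missing}")


def read_females(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"female_id": str})
    _require_columns(df, FEMALES_COLUMNS, "females.csv")
    if df["female_id"].duplicated().any():
        dup = df.loc[df["female_id"].duplicated(), "female_id"].iloc[0]
        raise ValueError(f"females.csv: duplicate female_id {dup!r}")
    df["capture_date"] = pd.to_datetime(df["capture_date"], format="ISO8601").dt.date
    df["prespawning_flag"] = df["prespawning_flag"].astype(bool)
    df["maturity_stage"] = df["maturity_stage"].astype(int)
    return df


def write_females(df: pd.DataFrame, path) -> None:
    _require_columns(df, FEMALES_COLUMNS, "females.csv")
    df.loc[:, FEMALES_COLUMNS].to_csv(path, index=False)


def females_to_records(df: pd.DataFrame) -> list[FemaleRecord]:
    return [
        FemaleRecord(
            female_id=str(r.female_id),
            capture_date=r.capture_date,
            total_length=float(r.total_length_cm),
            body_weight=float(r.body_weight_g),
            ovary_weight=float(r.ovary_weight_g),
            maturity_stage=int(r.maturity_stage),
            prespawning_flag=bool(r.prespawning_flag),
        )
        for r in df.itertuples(index=False)
    ]


def read_wholemount(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"female_id": str})
    _require_columns(df, WHOLEMOUNT_COLUMNS, "wholemount.csv")
    return df


def write_wholemount(df: pd.DataFrame, path) -> None:
    _require_columns(df, WHOLEMOUNT_COLUMNS, "wholemount.csv")
    df.loc[:, WHOLEMOUNT_COLUMNS].to_csv(path, index=False)


def wholemount_samples(df: pd.DataFrame) -> dict[str, WholemountSample]:
    out = {}
    for fid, grp in df.groupby("female_id", sort=True):
        out[str(fid)] = WholemountSample(
            female_id=str(fid),
            diameters=grp["diameter_um"].to_numpy(dtype=float),
            n_images=int(grp["image_no"].nunique()),
        )
    return out


def read_histology_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"female_id": str})
    _require_columns(df, HITS_COLUMNS, "histology_hits.csv")
    if df.duplicated(["female_id", "structure"]).any():
        raise ValueError("histology_hits.csv: duplicate (female_id, structure) row")
    return df


def read_histology_axes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"female_id": str})
    _require_columns(df, AXES_COLUMNS, "histology_axes.csv")
    return df


def write_histology_hits(df: pd.DataFrame, path) -> None:
    _require_columns(df, HITS_COLUMNS, "histology_hits.csv")
    df.loc[:, HITS_COLUMNS].to_csv(path, index=False)


def write_histology_axes(df: pd.DataFrame, path) -> None:
    _require_columns(df, AXES_COLUMNS, "histology_axes.csv")
    df.loc[:, AXES_COLUMNS].to_csv(path, index=False)


def histology_samples(hits: pd.DataFrame, axes: pd.DataFrame) -> dict[str, HistologySample]:
    """Assemble per-female :class:`HistologySample` objects from the two tables."""
    samples: dict[str, HistologySample] = {}
    for fid, grp in hits.groupby("female_id", sort=True):
        totals = grp["total_points"].unique()
        if len(totals) != 1:
            raise ValueError(f"female {fid}: inconsistent total_points across rows")
        samples[str(fid)] = HistologySample(
            female_id=str(fid),
            grid_hits={str(r.structure): int(r.hits) for r in grp.itertuples(index=False)},
            total_grid_points=int(totals[0]),
            section_area_mm2=float(grp["section_area_mm2"].iloc[0]),
        )
    for fid, grp in axes.groupby("female_id", sort=True):
        fid = str(fid)
        if fid not in samples:
            samples[fid] = HistologySample(female_id=fid, grid_hits={})
        samples[fid].axis_measurements.extend(
            (str(r.phase), float(r.long_axis_um), float(r.short_axis_um))
            for r in grp.itertuples(index=False)
        )
    return samples
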