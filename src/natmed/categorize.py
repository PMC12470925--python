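"""Mediator classification and stratum aggregation for natality records.

Raw birth records carry a race group, a birthweight in grams, a length of
gestation in completed weeks, and an infant-death flag.  This module bins the
two mediators into the standard clinical categories (five-level or binary
normal/abnormal), drops records with missing mediators, and aggregates to the
race x birthweight x gestation stratum counts that the Bayesian model consumes.

Category boundaries follow the WHO/clinical convention: ELBW <1000 g,
VLBW 1000-1499 g, LBW 1500-2499 g, NBW 2500-4000 g (inclusive), MAC >4000 g;
gestation on completed weeks with EPTD <28, VPTD 28-31, PTD 32-36, TD 37-41,
PostTD >=42.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Race",
    "BWCategory",
    "LGCategory",
    "BirthRecord",
    "StrataCounts",
    "classify_birthweight",
    "classify_gestation",
    "binarize",
    "filter_missing",
    "aggregate",
    "read_records_csv",
    "write_records_csv",
    "read_strata_csv",
    "write_strata_csv",
]


class Race(enum.IntEnum):
    """Race group of the infant (mother's designation, binary collapse)."""

    NON_BLACK = 1
    BLACK = 2

    @property
    def axis(self) -> int:
        """Zero-based array index (non-Black first)."""
        return self.value - 1


class BWCategory(enum.IntEnum):
    """Five-level birthweight classification."""

    ELBW = 1  # extremely low, <1000 g
    VLBW = 2  # very low, 1000-1499 g
    LBW = 3   # low, 1500-2499 g
    NBW = 4   # normal, 2500-4000 g
    MAC = 5   # macrosomia, >4000 g


class LGCategory(enum.IntEnum):
    """Five-level length-of-gestation classification (completed weeks)."""

    EPTD = 1    # extremely preterm, <28 wk
    VPTD = 2    # very preterm, 28-31 wk
    PTD = 3     # preterm, 32-36 wk
    TD = 4      # term, 37-41 wk
    POSTTD = 5  # post-term, >=42 wk


#: Five-level reference cell: normal birthweight, term delivery (0-based).
REFERENCE_CELL_5 = (BWCategory.NBW - 1, LGCategory.TD - 1)
#: Binary-scheme indices: 0 = abnormal, 1 = normal; reference = (normal, normal).
BINARY_ABNORMAL, BINARY_NORMAL = 0, 1
REFERENCE_CELL_2 = (BINARY_NORMAL, BINARY_NORMAL)

_SCHEME_SIZE = {"binary": 2, "five_by_five": 5}


@dataclass(frozen=True)
class BirthRecord:
    """One infant: race group, mediators (possibly missing), death flag."""

    race: Race
    birthweight_g: Optional[int]
    gestation_wk: Optional[int]
    infant_death: bool

    def __post_init__(self) -> None:
        if self.birthweight_g is not None and self.birthweight_g <= 0:
            raise ValueError(f"birthweight must be positive, got {self.birthweight_g}")
        if self.gestation_wk is not None and self.gestation_wk <= 0:
            raise ValueError(f"gestation must be positive, got {self.gestation_wk}")


def classify_birthweight(birthweight_g: Optional[float]) -> Optional[BWCategory]:
    """Bin a birthweight in grams; ``None`` for missing/nonpositive input.

    Bins: [0,1000) ELBW, [1000,1500) VLBW, [1500,2500) LBW, [2500,4000] NBW,
    (4000, inf) MAC.  Exactly 4000 g counts as normal.
    """
    if birthweight_g is None or not np.isfinite(birthweight_g) or birthweight_g <= 0:
        return None
    if birthweight_g < 1000:
        return BWCategory.ELBW
    if birthweight_g < 1500:
        return BWCategory.VLBW
    if birthweight_g < 2500:
        return BWCategory.LBW
    if birthweight_g <= 4000:
        return BWCategory.NBW
    return BWCategory.MAC


def classify_gestation(gestation_wk: Optional[float]) -> Optional[LGCategory]:
    """Bin completed weeks of gestation; ``None`` for missing/nonpositive.

    Bins: <28 EPTD, 28-31 VPTD, 32-36 PTD, 37-41 TD, >=42 PostTD.
    """
    if gestation_wk is None or not np.isfinite(gestation_wk) or gestation_wk <= 0:
        return None
    if gestation_wk < 28:
        return LGCategory.EPTD
    if gestation_wk < 32:
        return LGCategory.VPTD
    if gestation_wk < 37:
        return LGCategory.PTD
    if gestation_wk < 42:
        return LGCategory.TD
    return LGCategory.POSTTD


def binarize(bw: BWCategory, lg: LGCategory) -> tuple[bool, bool]:
    """Collapse five-level categories to (bw_normal, lg_normal) booleans."""
    return bw is BWCategory.NBW, lg is LGCategory.TD


def filter_missing(
    records: Iterable[BirthRecord],
) -> tuple[list[BirthRecord], int, int]:
    """Drop records missing either mediator.

    Returns ``(kept, n_dropped_bw, n_dropped_lg)``.  A record missing both
    fields is counted once, under birthweight (deterministic precedence for
    the drop log).
    """
    kept: list[BirthRecord] = []
    n_bw = n_lg = 0
    for rec in records:
        if rec.birthweight_g is None:
            n_bw += 1
        elif rec.gestation_wk is None:
            n_lg += 1
        else:
            kept.append(rec)
    return kept, n_bw, n_lg


@dataclass
class StrataCounts:
    """Births and deaths per race x BW x LG stratum, plus race totals.

    Arrays are shaped ``(2, K, K)`` with axis order (race, BW, LG); race axis
    0 is non-Black, 1 is Black; ``K`` is 5 for the five-level scheme and 2 for
    the binary one (index 0 = abnormal, 1 = normal).  Unobserved strata carry
    zero births and deaths.  Race totals default to the cell sums but may be
    supplied explicitly, larger than the sums, when only a subset of strata is
    available (the totals then carry the unlisted cells' mass).
    """

    births: np.ndarray
    deaths: np.ndarray
    scheme: str = "five_by_five"
    race_births: np.ndarray = field(default=None)  # type: ignore[assignment]
    race_deaths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        k = _SCHEME_SIZE.get(self.scheme)
        if k is None:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.births = np.asarray(self.births, dtype=np.int64)
        self.deaths = np.asarray(self.deaths, dtype=np.int64)
        if self.births.shape != (2, k, k) or self.deaths.shape != (2, k, k):
            raise ValueError(f"expected (2,{k},{k}) count arrays, got "
                             f"{self.births.shape} and {self.deaths.shape}")
        if (self.deaths > self.births).any():
            raise ValueError("deaths exceed births in at least one stratum")
        if (self.births < 0).any() or (self.deaths < 0).any():
            raise ValueError("negative counts")
        if self.race_births is None:
            self.race_births = self.births.sum(axis=(1, 2))
        if self.race_deaths is None:
            self.race_deaths = self.deaths.sum(axis=(1, 2))
        self.race_births = np.asarray(self.race_births, dtype=np.int64)
        self.race_deaths = np.asarray(self.race_deaths, dtype=np.int64)
        if (self.race_births < self.births.sum(axis=(1, 2))).any():
            raise ValueError("race birth totals below the cell sums")
        if (self.race_deaths < self.deaths.sum(axis=(1, 2))).any():
            raise ValueError("race death totals below the cell sums")
        if (self.race_deaths > self.race_births).any():
            raise ValueError("race deaths exceed race births")

    @property
    def k(self) -> int:
        return self.births.shape[1]

    @property
    def reference_cell(self) -> tuple[int, int]:
        return REFERENCE_CELL_5 if self.scheme == "five_by_five" else REFERENCE_CELL_2

    def cell(self, race: Race, bw: int, lg: int) -> tuple[int, int]:
        """(births, deaths) for one stratum (0-based bw/lg indices)."""
        return int(self.births[race.axis, bw, lg]), int(self.deaths[race.axis, bw, lg])

    def observed(self) -> np.ndarray:
        """Boolean (K,K) mask of cells with births in at least one race."""
        return self.births.sum(axis=0) > 0

    def to_binary(self) -> "StrataCounts":
        """Collapse a five-level table to the binary normal/abnormal scheme."""
        if self.scheme != "five_by_five":
            raise ValueError("already binary")
        b = np.zeros((2, 2, 2), dtype=np.int64)
        d = np.zeros((2, 2, 2), dtype=np.int64)
        bw_norm = np.arange(5) == (BWCategory.NBW - 1)
        lg_norm = np.arange(5) == (LGCategory.TD - 1)
        for i, bn in enumerate(bw_norm):
            for j, ln in enumerate(lg_norm):
                b[:, int(bn), int(ln)] += self.births[:, i, j]
                d[:, int(bn), int(ln)] += self.deaths[:, i, j]
        return StrataCounts(b, d, scheme="binary",
                            race_births=self.race_births.copy(),
                            race_deaths=self.race_deaths.copy())


def aggregate(records: Sequence[BirthRecord], scheme: str = "five_by_five") -> StrataCounts:
    """Count births and deaths per stratum.

    Records missing either mediator must be removed beforehand (see
    :func:`filter_missing`); an empty input yields a valid all-zero table.
    """
    k = _SCHEME_SIZE[scheme]
    births = np.zeros((2, k, k), dtype=np.int64)
    deaths = np.zeros((2, k, k), dtype=np.int64)
    for rec in records:
        bw = classify_birthweight(rec.birthweight_g)
        lg = classify_gestation(rec.gestation_wk)
        if bw is None or lg is None:
            raise ValueError("record with missing mediator reached aggregate(); "
                             "run filter_missing first")
        if scheme == "binary":
            bn, ln = binarize(bw, lg)
            i, j = int(bn), int(ln)
        else:
            i, j = bw - 1, lg - 1
        births[rec.race.axis, i, j] += 1
        deaths[rec.race.axis, i, j] += int(rec.infant_death)
    return StrataCounts(births, deaths, scheme=scheme)


# ---------------------------------------------------------------------------
# delimited-text interfaces

_RACE_NAMES = {"Black": Race.BLACK, "nonBlack": Race.NON_BLACK}
_RACE_LABELS = {v: k for k, v in _RACE_NAMES.items()}
_BW_NAMES = {c.name: c for c in BWCategory}
_LG_NAMES = {"EPTD": LGCategory.EPTD, "VPTD": LGCategory.VPTD,
             "PTD": LGCategory.PTD, "TD": LGCategory.TD,
             "PostTD": LGCategory.POSTTD}
_LG_LABELS = {v: k for k, v in _LG_NAMES.items()}


def read_records_csv(path) -> list[BirthRecord]:
    """Read a record CSV: race_group,birthweight_g,gestation_wk,infant_death.

    Empty mediator cells are missing values.
    """
    df = pd.read_csv(path, dtype={"race_group": str})
    required = {"race_group", "birthweight_g", "gestation_wk", "infant_death"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"record CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        race = _RACE_NAMES.get(row.race_group)
        if race is None:
            raise ValueError(f"unknown race_group {row.race_group!r}")
        bw = None if pd.isna(row.birthweight_g) else int(row.birthweight_g)
        lg = None if pd.isna(row.gestation_wk) else int(row.gestation_wk)
        out.append(BirthRecord(race, bw, lg, bool(int(row.infant_death))))
    return out


def write_records_csv(records: Sequence[BirthRecord], path) -> None:
    df = pd.DataFrame(
        {
            "race_group": [_RACE_LABELS[r.race] for r in records],
            "birthweight_g": [r.birthweight_g for r in records],
            "gestation_wk": [r.gestation_wk for r in records],
            "infant_death": [int(r.infant_death) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_strata_csv(path, scheme: str = "five_by_five") -> StrataCounts:
    """Read a strata CSV: race_group,bw_cat,lg_cat,births,deaths.

    For the binary scheme, bw_cat/lg_cat take values ``normal``/``abnormal``.
    Cells not listed are zero.
    """
    df = pd.read_csv(path, dtype={"race_group": str, "bw_cat": str, "lg_cat": str})
    k = _SCHEME_SIZE[scheme]
    births = np.zeros((2, k, k), dtype=np.int64)
    deaths = np.zeros((2, k, k), dtype=np.int64)
    for t, row in enumerate(df.itertuples(index=False)):
        try:
            race = _RACE_NAMES[row.race_group]
            if scheme == "binary":
                i = BINARY_NORMAL if row.bw_cat == "normal" else BINARY_ABNORMAL
                j = BINARY_NORMAL if row.lg_cat == "normal" else BINARY_ABNORMAL
                if row.bw_cat not in ("normal", "abnormal") or row.lg_cat not in ("normal", "abnormal"):
                    raise KeyError(row.bw_cat)
            else:
                i = _BW_NAMES[row.bw_cat] - 1
                j = _LG_NAMES[row.lg_cat] - 1
            b, d = int(row.births), int(row.deaths)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"strata CSV row {t + 2}: bad value ({exc})") from exc
        if d > b:
            raise ValueError(f"strata CSV row {t + 2}: deaths {d} exceed births {b}")
        births[race.axis, i, j] += b
        deaths[race.axis, i, j] += d
    return StrataCounts(births, deaths, scheme=scheme)


def write_strata_csv(counts: StrataCounts, path) -> None:
    """Write all cells, including structural zeros, one row per stratum."""
    rows = []
    for race in Race:
        for i in range(counts.k):
            for j in range(counts.k):
                if counts.scheme == "binary":
                    bw_lab = "normal" if i == BINARY_NORMAL else "abnormal"
                    lg_lab = "normal" if j == BINARY_NORMAL else "abnormal"
                else:
                    bw_lab = BWCategory(i + 1).name
                    lg_lab = _LG_LABELS[LGCategory(j + 1)]
                rows.append(
                    (_RACE_LABELS[race], bw_lab, lg_lab,
                     int(counts.births[race.axis, i, j]),
                     int(counts.deaths[race.axis, i, j]))
                )
    pd.DataFrame(rows, columns=["race_group", "bw_cat", "lg_cat", "births", "deaths"]) \
        .to_csv(path, index=False)
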