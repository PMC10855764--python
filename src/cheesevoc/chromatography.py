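"""From raw GC-MS peak records to an analysis-ready feature table.

The processing chain mirrors standard volatolomics practice:

1. linear retention indices (LRI) of analytes against an n-alkane ladder
   (C7-C30) by piecewise-linear interpolation (van den Dool & Kratz);
2. identity assignment by nearest reference LRI within a tolerance;
3. normalization of every analyte area to the internal-standard area
   (3-octanol, quantifier m/z 59);
4. alignment of compounds across samples into a samples x VOC matrix,
   absent peaks filled with zero (undetected means absent here: several
   radiolytic hydrocarbons occur only in irradiated samples, so a zero is
   informative, not missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AmbiguousInternalStandardError,
    DataError,
    DegenerateInternalStandardError,
    MissingInternalStandardError,
    RetentionIndexRangeError,
)

#: Quantifier mass-to-charge of the 3-octanol internal standard.
DEFAULT_IS_MZ = 59

#: Default LRI tolerance for identity confirmation, in index units.
#: The typical inter-laboratory spread of linear retention indices on
#: apolar/mid-polar columns; configurable in :func:`annotate_by_lri`.
DEFAULT_LRI_TOLERANCE = 10.0

UNASSIGNED = "unassigned"

#: Columns of the on-disk peak-table CSV.
PEAK_CSV_COLUMNS = ["sample_id", "compound", "rt_min", "mz", "area"]

#: Leading metadata columns of the on-disk feature-table CSV.
META_CSV_COLUMNS = ["sample_id", "cheese", "dose_kgy"]


@dataclass(frozen=True)
class PeakRecord:
    """One integrated chromatographic peak.

    Parameters
    ----------
    sample_id : opaque sample identifier.
    compound : assigned compound name, or ``"unassigned"``.
    rt : retention time in minutes.
    mz : quantifier mass-to-charge (integer, >= 1).
    area : integrated ion-current area (arbitrary counts, >= 0).
    """

    sample_id: str
    compound: str
    rt: float
    mz: int
    area: float

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise DataError(f"retention time must be positive, got {self.rt}")
        if self.area < 0:
            raise DataError(f"peak area must be non-negative, got {self.area}")
        if self.mz < 1:
            raise DataError(f"m/z must be >= 1, got {self.mz}")


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times of the C7-C30 n-alkane standards.

    ``carbons`` and ``rts`` are parallel sequences; carbon numbers must lie
    in 7..30 and retention times must be strictly increasing.
    """

    carbons: tuple[int, ...]
    rts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.carbons) != len(self.rts):
            raise DataError("ladder carbons and retention times differ in length")
        if len(self.carbons) < 2:
            raise DataError("ladder needs at least two alkanes")
        if any(c < 7 or c > 30 for c in self.carbons):
            raise DataError("ladder carbon numbers must lie within 7..30")
        if any(b <= a for a, b in zip(self.carbons, self.carbons[1:])):
            raise DataError("ladder carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(self.rts, self.rts[1:])):
            raise DataError("ladder retention times must be strictly increasing")

    @classmethod
    def from_mapping(cls, entries: Mapping[int, float]) -> "AlkaneLadder":
        carbons = tuple(sorted(entries))
        return cls(carbons=carbons, rts=tuple(entries[c] for c in carbons))

    @classmethod
    def from_csv(cls, path) -> "AlkaneLadder":
        df = pd.read_csv(path)
        if not {"carbon", "rt_min"}.issubset(df.columns):
            raise DataError("ladder CSV must have columns carbon,rt_min")
        return cls.from_mapping(dict(zip(df["carbon"].astype(int), df["rt_min"])))

    def to_csv(self, path) -> None:
        pd.DataFrame({"carbon": self.carbons, "rt_min": self.rts}).to_csv(
            path, index=False
        )

    @property
    def span(self) -> tuple[float, float]:
        return self.rts[0], self.rts[-1]


@dataclass
class FeatureTable:
    """Aligned samples x VOC matrix of IS-normalized areas with metadata.

    Attributes
    ----------
    data : DataFrame, index = sample ids, columns = compound names, values
        are dimensionless IS-normalized areas (>= 0; absent peaks are 0).
    sample_meta : DataFrame indexed like ``data`` with columns ``cheese``
        and ``dose_kgy`` (dose in kilogray).
    compound_classes : optional Series mapping compound -> chemical class.
    markers : optional ground-truth list of discriminant compounds (set by
        the synthetic generator).
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    compound_classes: pd.Series | None = None
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.sample_meta.index):
            raise DataError("feature data and sample metadata indices differ")
        if (self.data.values < 0).any():
            raise DataError("feature table contains negative areas")
        if self.data.isna().any().any():
            raise DataError("feature table contains missing entries")

    @property
    def doses(self) -> pd.Series:
        return self.sample_meta["dose_kgy"]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path) -> None:
        out = pd.concat(
            [self.sample_meta[["cheese", "dose_kgy"]], self.data], axis=1
        )
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        missing = [c for c in ("cheese", "dose_kgy") if c not in df.columns]
        if missing:
            raise DataError(f"feature CSV lacks metadata columns {missing}")
        meta = df[["cheese", "dose_kgy"]].copy()
        data = df.drop(columns=["cheese", "dose_kgy"]).astype(float)
        return cls(data=data, sample_meta=meta)


def linear_retention_index(rt: float, ladder: AlkaneLadder) -> float:
    """Linear (van den Dool & Kratz) retention index of a peak.

    ``LRI = 100 * [n + (rt - t_n) / (t_next - t_n) * (c_next - n)]`` where
    ``n`` is the carbon number of the last ladder alkane eluting at or
    before ``rt``. Exactly ``100 * n`` at every alkane anchor; monotone
    non-decreasing in ``rt``. No extrapolation beyond the ladder span.
    """
    lo, hi = ladder.span
    if rt < lo or rt > hi:
        raise RetentionIndexRangeError(
            f"rt {rt} min outside ladder span [{lo}, {hi}]"
        )
    rts = np.asarray(ladder.rts)
    carbons = np.asarray(ladder.carbons)
    i = int(np.searchsorted(rts, rt, side="right")) - 1
    if i == len(rts) - 1:  # exactly at the last anchor
        return 100.0 * carbons[-1]
    frac = (rt - rts[i]) / (rts[i + 1] - rts[i])
    return 100.0 * (carbons[i] + frac * (carbons[i + 1] - carbons[i]))


def normalize_to_internal_standard(
    peaks: Sequence[PeakRecord], is_mz: int = DEFAULT_IS_MZ
) -> list[PeakRecord]:
    """Divide every analyte area in one sample by the IS area.

    The internal standard is identified by its quantifier m/z; exactly one
    such peak must be present with a positive area. The IS record itself is
    removed from the output.
    """
    is_peaks = [p for p in peaks if p.mz == is_mz]
    if not is_peaks:
        raise MissingInternalStandardError(f"no peak with m/z {is_mz}")
    if len(is_peaks) > 1:
        raise AmbiguousInternalStandardError(
            f"{len(is_peaks)} peaks with m/z {is_mz}"
        )
    is_area = is_peaks[0].area
    if is_area == 0:
        raise DegenerateInternalStandardError("internal standard area is zero")
    return [
        PeakRecord(p.sample_id, p.compound, p.rt, p.mz, p.area / is_area)
        for p in peaks
        if p.mz != is_mz
    ]


def annotate_by_lri(
    lri_e: float,
    reference: Mapping[str, float],
    tolerance: float = DEFAULT_LRI_TOLERANCE,
) -> str:
    """Assign a compound identity by nearest reference retention index.

    Returns the reference compound minimizing ``|LRI_E - LRI_R|`` when that
    minimum is within ``tolerance``, else ``"unassigned"``. Exact ties are
    broken by lexicographic compound name, with a warning.
    """
    if tolerance <= 0:
        raise DataError("tolerance must be positive")
    if not reference:
        raise DataError("empty reference index")
    best = min(reference, key=lambda c: (abs(lri_e - reference[c]), c))
    best_diff = abs(lri_e - reference[best])
    ties = [c for c in reference if abs(lri_e - reference[c]) == best_diff]
    if len(ties) > 1:
        warnings.warn(
            f"LRI {lri_e} equidistant from {sorted(ties)}; "
            f"keeping {min(ties)}",
            stacklevel=2,
        )
    return best if best_diff <= tolerance else UNASSIGNED


def build_feature_table(
    peaks_by_sample: Mapping[str, Sequence[PeakRecord]],
    sample_meta: pd.DataFrame,
    compound_classes: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Align normalized peaks across samples into a FeatureTable.

    The union of compounds across samples forms the columns; a sample
    missing a compound gets 0. Column order is deterministic: by chemical
    class then compound name when classes are given, else by name.
    """
    if not peaks_by_sample:
        raise DataError("no samples to align")
    for sid in peaks_by_sample:
        if sid not in sample_meta.index:
            raise DataError(f"sample {sid!r} has no metadata row")
    if "dose_kgy" not in sample_meta.columns:
        raise DataError("sample metadata lacks a dose_kgy column")

    rows: dict[str, dict[str, float]] = {}
    for sid, peaks in peaks_by_sample.items():
        row: dict[str, float] = {}
        for p in peaks:
            if p.compound in row:
                raise DataError(
                    f"duplicate (sample, compound) pair: ({sid!r}, {p.compound!r})"
                )
            row[p.compound] = p.area
        rows[sid] = row

    data = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    if compound_classes is not None:
        order = sorted(
            data.columns, key=lambda c: (compound_classes.get(c, ""), c)
        )
        classes: pd.Series | None = pd.Series(
            {c: compound_classes.get(c, "") for c in order}, name="class"
        )
    else:
        order = sorted(data.columns)
        classes = None
    data = data[order]
    data = data.loc[list(peaks_by_sample)]
    meta = sample_meta.loc[data.index]
    return FeatureTable(data=data, sample_meta=meta, compound_classes=classes)


def read_peak_csv(path) -> list[PeakRecord]:
    """Read a long-format peak table CSV (sample_id,compound,rt_min,mz,area)."""
    df = pd.read_csv(path)
    missing = [c for c in PEAK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"peak CSV lacks columns {missing}")
    df["compound"] = df["compound"].fillna(UNASSIGNED)
    return [
        PeakRecord(
            sample_id=str(r.sample_id),
            compound=str(r.compound),
            rt=float(r.rt_min),
            mz=int(r.mz),
            area=float(r.area),
        )
        for r in df.itertuples()
    ]


def write_peak_csv(peaks: Iterable[PeakRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "compound": p.compound,
                "rt_min": p.rt,
                "mz": p.mz,
                "area": p.area,
            }
            for p in peaks
        ]
    ).to_csv(path, index=False)
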