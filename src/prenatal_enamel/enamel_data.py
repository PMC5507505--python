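"""Domain types, validation and CSV I/O for enamel histomorphometry tables.

The measurement model follows standard dental-histology practice for
deciduous teeth: along single enamel prisms, segments (``PrismSegment``)
are traced from the enamel-dentine junction (EDJ) outwards and their
circadian cross-striations counted (one striation = one day of matrix
secretion); along the EDJ itself, intervals between biological landmarks
(``EDJInterval``) record the length of junction laid down in a known
number of days.  A ``ToothRecord`` bundles both for one deciduous central
incisor, together with arch and neonatal-line (NL) status.  When the NL is
absent the individual died at or very soon after birth, so all observable
enamel is treated as prenatal.

A reference table of per-individual growth parameters from the Imperial
Roman Velia series (18 deciduous central incisors) ships with the package
and is loaded by :func:`load_velia_table1`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PrismSegment",
    "EDJInterval",
    "ToothRecord",
    "Table1Row",
    "Finding",
    "SchemaError",
    "ReferentialError",
    "MeasurementValueError",
    "read_measurements",
    "write_measurements",
    "load_velia_table1",
    "validate_record",
]

# Canonical CSV schemas (column order is fixed for round-trip stability).
SEGMENTS_COLUMNS = ["tooth_id", "segment_index", "prism_length_um", "count_obs1", "count_obs2"]
EDJ_COLUMNS = [
    "tooth_id",
    "interval_index",
    "edj_length_um",
    "days",
    "cum_fraction_start",
    "cum_fraction_end",
]
TEETH_COLUMNS = ["tooth_id", "arch", "nl_present", "edj_total_um", "crown_area_mm2", "age_label"]

_FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ReferentialError(ValueError):
    """A child row references a tooth id absent from the metadata table."""


class MeasurementValueError(ValueError):
    """A measurement violates a value invariant (cites the offending row)."""


@dataclass(frozen=True)
class Finding:
    """A validation finding: severity ('error' | 'warning'), location, message."""

    severity: str
    location: str
    message: str


@dataclass
class PrismSegment:
    """One measured span along a single enamel prism.

    ``counts_by_observer`` holds the raw repeated cross-striation counts;
    ``count_days`` is their arithmetic mean (may be a half-integer — no
    rounding happens at segment level).
    """

    tooth_id: str
    index: int  # 1-based, from the dentine-horn end
    length_um: float
    counts_by_observer: list[float]
    count_days: float | None = None

    def __post_init__(self) -> None:
        if self.count_days is None:
            self.count_days = float(sum(self.counts_by_observer) / len(self.counts_by_observer))


@dataclass
class EDJInterval:
    """Length of EDJ between two biological landmarks and its formation days.

    Cumulative fractions locate the interval along the total prenatal EDJ,
    measured from the dentine horn toward the cervix.
    """

    tooth_id: str
    index: int
    length_um: float
    days: float
    cum_fraction_start: float
    cum_fraction_end: float

    @property
    def midpoint_fraction(self) -> float:
        return 0.5 * (self.cum_fraction_start + self.cum_fraction_end)


@dataclass
class ToothRecord:
    """One deciduous central incisor with its prism and EDJ measurements."""

    id: str
    arch: str  # 'upper' | 'lower'
    nl_present: bool
    segments: list[PrismSegment] = field(default_factory=list)
    edj_intervals: list[EDJInterval] = field(default_factory=list)
    edj_total_um: float | None = None
    crown_area_mm2: float | None = None
    age_label: str | None = None

    @property
    def total_prism_length_um(self) -> float:
        return float(sum(s.length_um for s in self.segments))


@dataclass(frozen=True)
class Table1Row:
    """Per-individual growth parameters of the Velia reference series."""

    id: str
    arch: str
    nl_present: bool
    pcft_direct_days: float
    pcft_regression_days: float
    deviation_days: float
    dsr_mean_um_day: float
    dsr_sd: float
    dsr_n: int
    cuspal_middle_eer_um_day: float
    eer_mean_um_day: float
    eer_sd: float
    eer_n: int


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_measurements(
    segments_path: str | Path, edj_path: str | Path, meta_path: str | Path
) -> list[ToothRecord]:
    """Read the three measurement tables and assemble validated tooth records.

    Raises :class:`SchemaError` for missing columns, :class:`ReferentialError`
    for orphan child rows, and :class:`MeasurementValueError` (citing the
    1-based data row) for non-positive lengths or counts.
    """
    seg_df = pd.read_csv(segments_path)
    edj_df = pd.read_csv(edj_path)
    meta_df = pd.read_csv(meta_path)

    _require_columns(seg_df, [c for c in SEGMENTS_COLUMNS if c != "count_obs2"], str(segments_path))
    _require_columns(edj_df, EDJ_COLUMNS, str(edj_path))
    _require_columns(meta_df, ["tooth_id", "arch", "nl_present"], str(meta_path))

    records: dict[str, ToothRecord] = {}
    for _, row in meta_df.iterrows():
        tid = str(row["tooth_id"])
        nl = row["nl_present"]
        if isinstance(nl, str):
            nl = nl.strip().lower() in ("true", "1", "yes")
        records[tid] = ToothRecord(
            id=tid,
            arch=str(row["arch"]),
            nl_present=bool(nl),
            edj_total_um=_opt_float(row.get("edj_total_um")),
            crown_area_mm2=_opt_float(row.get("crown_area_mm2")),
            age_label=_opt_str(row.get("age_label")),
        )

    for i, row in seg_df.iterrows():
        rownum = int(i) + 2  # 1-based including header
        tid = str(row["tooth_id"])
        if tid not in records:
            raise ReferentialError(
                f"{segments_path} row {rownum}: tooth id '{tid}' absent from metadata"
            )
        length = float(row["prism_length_um"])
        if not length > 0:
            raise MeasurementValueError(
                f"{segments_path} row {rownum}: prism_length_um must be > 0, got {length}"
            )
        counts = [float(row["count_obs1"])]
        obs2 = _opt_float(row.get("count_obs2"))
        if obs2 is not None:
            counts.append(obs2)
        for c in counts:
            if not c > 0:
                raise MeasurementValueError(
                    f"{segments_path} row {rownum}: counts must be > 0, got {c}"
                )
        records[tid].segments.append(
            PrismSegment(tooth_id=tid, index=int(row["segment_index"]), length_um=length,
                         counts_by_observer=counts)
        )

    for i, row in edj_df.iterrows():
        rownum = int(i) + 2
        tid = str(row["tooth_id"])
        if tid not in records:
            raise ReferentialError(f"{edj_path} row {rownum}: tooth id '{tid}' absent from metadata")
        length = float(row["edj_length_um"])
        days = float(row["days"])
        if not length > 0:
            raise MeasurementValueError(
                f"{edj_path} row {rownum}: edj_length_um must be > 0, got {length}"
            )
        if not days > 0:
            raise MeasurementValueError(f"{edj_path} row {rownum}: days must be > 0, got {days}")
        records[tid].edj_intervals.append(
            EDJInterval(
                tooth_id=tid,
                index=int(row["interval_index"]),
                length_um=length,
                days=days,
                cum_fraction_start=float(row["cum_fraction_start"]),
                cum_fraction_end=float(row["cum_fraction_end"]),
            )
        )

    out = list(records.values())
    for rec in out:
        rec.segments.sort(key=lambda s: s.index)
        rec.edj_intervals.sort(key=lambda iv: iv.index)
    return out


def write_measurements(
    records: Iterable[ToothRecord],
    segments_path: str | Path,
    edj_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write records back to the canonical three-table CSV layout.

    Column order and float formatting are fixed so that read → write → read
    round-trips bit-identically.
    """
    seg_rows, edj_rows, meta_rows = [], [], []
    for rec in records:
        meta_rows.append(
            {
                "tooth_id": rec.id,
                "arch": rec.arch,
                "nl_present": str(rec.nl_present).lower(),
                "edj_total_um": rec.edj_total_um,
                "crown_area_mm2": rec.crown_area_mm2,
                "age_label": rec.age_label,
            }
        )
        for s in rec.segments:
            seg_rows.append(
                {
                    "tooth_id": rec.id,
                    "segment_index": s.index,
                    "prism_length_um": s.length_um,
                    "count_obs1": s.counts_by_observer[0],
                    "count_obs2": s.counts_by_observer[1] if len(s.counts_by_observer) > 1 else None,
                }
            )
        for iv in rec.edj_intervals:
            edj_rows.append(
                {
                    "tooth_id": rec.id,
                    "interval_index": iv.index,
                    "edj_length_um": iv.length_um,
                    "days": iv.days,
                    "cum_fraction_start": iv.cum_fraction_start,
                    "cum_fraction_end": iv.cum_fraction_end,
                }
            )
    pd.DataFrame(seg_rows, columns=SEGMENTS_COLUMNS).to_csv(
        segments_path, index=False, float_format=_FLOAT_FORMAT
    )
    pd.DataFrame(edj_rows, columns=EDJ_COLUMNS).to_csv(
        edj_path, index=False, float_format=_FLOAT_FORMAT
    )
    pd.DataFrame(meta_rows, columns=TEETH_COLUMNS).to_csv(
        meta_path, index=False, float_format=_FLOAT_FORMAT
    )


def load_velia_table1() -> list[Table1Row]:
    """Load the packaged Velia reference table (18 individuals)."""
    with resources.files("prenatal_enamel.data").joinpath("velia_table1.csv").open() as fh:
        df = pd.read_csv(fh)
    rows = []
    for _, r in df.iterrows():
        rows.append(
            Table1Row(
                id=str(r["id"]),
                arch=str(r["arch"]),
                nl_present=str(r["nl_present"]).strip().lower() == "true",
                pcft_direct_days=float(r["pcft_direct_days"]),
                pcft_regression_days=float(r["pcft_regression_days"]),
                deviation_days=float(r["deviation_days"]),
                dsr_mean_um_day=float(r["dsr_mean_um_day"]),
                dsr_sd=float(r["dsr_sd"]),
                dsr_n=int(r["dsr_n"]),
                cuspal_middle_eer_um_day=float(r["cuspal_middle_eer_um_day"]),
                eer_mean_um_day=float(r["eer_mean_um_day"]),
                eer_sd=float(r["eer_sd"]),
                eer_n=int(r["eer_n"]),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_record(record: ToothRecord) -> list[Finding]:
    """Check all type invariants; returns findings instead of raising."""
    findings: list[Finding] = []

    def err(loc: str, msg: str) -> None:
        findings.append(Finding("error", loc, msg))

    if record.arch not in ("upper", "lower"):
        err(record.id, f"arch must be 'upper' or 'lower', got '{record.arch}'")

    for s in record.segments:
        loc = f"{record.id}/segment[{s.index}]"
        if s.tooth_id != record.id:
            err(loc, f"segment tooth_id '{s.tooth_id}' != record id '{record.id}'")
        if not s.length_um > 0:
            err(loc, f"length_um must be > 0, got {s.length_um}")
        if not s.count_days > 0:
            err(loc, f"count_days must be > 0, got {s.count_days}")
        if s.counts_by_observer:
            mean = sum(s.counts_by_observer) / len(s.counts_by_observer)
            if not math.isclose(s.count_days, mean, rel_tol=1e-9, abs_tol=1e-9):
                err(
                    loc,
                    f"count_days {s.count_days} is not the mean of observer counts "
                    f"{s.counts_by_observer} (expected {mean})",
                )

    prev: EDJInterval | None = None
    for iv in record.edj_intervals:
        loc = f"{record.id}/edj[{iv.index}]"
        if iv.tooth_id != record.id:
            err(loc, f"interval tooth_id '{iv.tooth_id}' != record id '{record.id}'")
        if not iv.length_um > 0:
            err(loc, f"length_um must be > 0, got {iv.length_um}")
        if not iv.days > 0:
            err(loc, f"days must be > 0, got {iv.days}")
        if not (0.0 <= iv.cum_fraction_start < iv.cum_fraction_end <= 1.0):
            err(
                loc,
                f"cumulative fractions must satisfy 0 <= start < end <= 1, got "
                f"({iv.cum_fraction_start}, {iv.cum_fraction_end})",
            )
        if prev is not None and iv.cum_fraction_start < prev.cum_fraction_end - 1e-12:
            err(
                f"{record.id}/edj[{prev.index},{iv.index}]",
                f"intervals {prev.index} and {iv.index} overlap in EDJ fraction",
            )
        prev = iv

    return findings


def _opt_float(value) -> float | None:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return str(value)
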