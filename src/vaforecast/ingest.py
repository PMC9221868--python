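"""Ingestion of per-visit OCT metadata, VA notations and the visit index.

The XML dialect mirrors what the Heidelberg Spectralis exports for the
ETDRS macular grid: global tags ``CentralThickness``,
``MinCentralThickness``, ``MaxCentralThickness``, ``TotalVolume`` and one
``Zone`` element per grid zone with ``Name``, ``AvgThickness``,
``Volume`` and ``ValidPixelPercentage`` children. Visual acuity arrives
in mixed notations (Snellen fraction, decimal, LogMAR, or a range) and
is normalised to the decimal scale in [0, 1].
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from lxml import etree

from .records import (
    ZONES,
    EyeSeries,
    VAConversionError,
    VisitRecord,
    XMLParseError,
)

__all__ = [
    "SnellenFraction",
    "parse_heidelberg_xml",
    "va_to_decimal",
    "assemble_series",
    "read_cohort",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnellenFraction:
    """A Snellen chart fraction: test distance over the healthy-eye distance."""

    test_distance: float
    denominator_d: float

    def __post_init__(self):
        if self.test_distance <= 0 or self.denominator_d <= 0:
            raise VAConversionError("Snellen fraction terms must be strictly positive")

    @property
    def decimal(self) -> float:
        return self.test_distance / self.denominator_d


def _float_or_error(elem, tag: str) -> float:
    text = (elem.text or "").strip()
    try:
        return float(text)
    except ValueError as exc:
        raise XMLParseError(f"malformed number {text!r} in tag <{tag}>") from exc


def parse_heidelberg_xml(path: str | Path) -> VisitRecord:
    """Parse one visit's OCT metadata file into a (partial) VisitRecord.

    Missing tags leave the corresponding field ``None`` (not fatal); a tag
    whose text is not a number raises :class:`XMLParseError` naming the tag.
    Zones are keyed by their ``Name`` child, so document order is irrelevant.
    The visit date, VA and treatment flag come from the index, not the XML;
    the returned record carries a placeholder date.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    rec = VisitRecord(visit_date=dt.date.min)
    for tag, attr in {
        "CentralThickness": "central_thickness",
        "MinCentralThickness": "min_central_thickness",
        "MaxCentralThickness": "max_central_thickness",
        "TotalVolume": "total_volume",
    }.items():
        elem = root.find(f".//{tag}")
        if elem is not None:
            setattr(rec, attr, _float_or_error(elem, tag))
    for zone in root.iter("Zone"):
        name_el = zone.find("Name")
        if name_el is None or (name_el.text or "").strip() not in ZONES:
            continue
        name = name_el.text.strip()
        th = zone.find("AvgThickness")
        vol = zone.find("Volume")
        vpp = zone.find("ValidPixelPercentage")
        if th is not None:
            rec.zone_avg_thickness[name] = _float_or_error(th, "AvgThickness")
        if vol is not None:
            rec.zone_volume[name] = _float_or_error(vol, "Volume")
        if vpp is not None:
            rec.valid_pixel_percentage[name] = _float_or_error(vpp, "ValidPixelPercentage")
    return rec


_RANGE_RE = re.compile(r"^\s*(\d*\.?\d+)\s*-\s*(\d*\.?\d+)\s*$")
_FRACTION_RE = re.compile(r"^\s*(\d*\.?\d+)\s*/\s*(\d*\.?\d+)\s*$")


def va_to_decimal(raw: str | float, logmar: bool = False) -> float:
    """Convert a visual-acuity notation to decimal in [0, 1].

    Accepts a Snellen fraction ("20/40", "6/60"), a decimal ("0.5"), a
    LogMAR value (``logmar=True`` or a "logmar 0.3"-style prefix), or a
    range ("0.3-0.5", converted to the mean of the endpoint decimals).
    Values above 1.0 decimal (e.g. "20/16") are clamped to 1.0, since the
    forecaster's output is sigmoid-bounded; clamping is logged.
    """
    if isinstance(raw, (int, float)):
        value = 10.0 ** (-float(raw)) if logmar else float(raw)
        return _clamp_va(value, str(raw))
    token = str(raw).strip()
    low = token.lower()
    if low.startswith("logmar"):
        return va_to_decimal(low.removeprefix("logmar").strip(), logmar=True)
    if not token:
        raise VAConversionError("empty visual-acuity token")
    m = _FRACTION_RE.match(token)
    if m:
        frac = SnellenFraction(float(m.group(1)), float(m.group(2)))
        return _clamp_va(frac.decimal, token)
    m = _RANGE_RE.match(token)
    if m and not logmar:
        lo, hi = float(m.group(1)), float(m.group(2))
        return _clamp_va((lo + hi) / 2.0, token)
    try:
        value = float(token)
    except ValueError as exc:
        raise VAConversionError(f"cannot interpret visual-acuity token {raw!r}") from exc
    if logmar:
        value = 10.0 ** (-value)
    return _clamp_va(value, token)


def _clamp_va(value: float, token: str) -> float:
    if value < 0:
        raise VAConversionError(f"negative visual acuity from token {token!r}")
    if value > 1.0:
        log.info("clamping VA %.3f from %r to 1.0", value, token)
        return 1.0
    return value


def assemble_series(
    index: pd.DataFrame,
    xml_records: dict[tuple[str, str, str], VisitRecord] | None = None,
    mode: str = "intersection",
) -> list[EyeSeries]:
    """Build per-eye series from the visit index and parsed XML records.

    ``index`` needs columns patient_id, eye, visit_date (ISO-8601), va_raw,
    treated. ``xml_records`` maps (patient_id, eye, visit_date) to the
    parsed OCT record. ``mode="intersection"`` keeps only visits present in
    both sources; ``mode="union"`` keeps index visits without OCT data,
    leaving their OCT fields missing. Eyes with fewer than two retained
    visits are excluded. Duplicate (eye, date) rows: the later row wins.
    """
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    xml_records = xml_records or {}
    by_eye: dict[tuple[str, str], dict[str, VisitRecord]] = {}
    for _, row in index.iterrows():
        pid, eye = str(row["patient_id"]), str(row["eye"])
        date_str = str(row["visit_date"])
        key = (pid, eye, date_str)
        oct_rec = xml_records.get(key)
        if oct_rec is None and mode == "intersection":
            continue
        visits = by_eye.setdefault((pid, eye), {})
        if date_str in visits:
            log.warning("duplicate visit %s for eye %s_%s: later record wins", date_str, pid, eye)
        rec = VisitRecord(visit_date=dt.date.fromisoformat(date_str))
        if oct_rec is not None:
            rec.zone_avg_thickness = dict(oct_rec.zone_avg_thickness)
            rec.zone_volume = dict(oct_rec.zone_volume)
            rec.central_thickness = oct_rec.central_thickness
            rec.min_central_thickness = oct_rec.min_central_thickness
            rec.max_central_thickness = oct_rec.max_central_thickness
            rec.total_volume = oct_rec.total_volume
            rec.valid_pixel_percentage = dict(oct_rec.valid_pixel_percentage)
            rec.image_path = oct_rec.image_path
        va_raw = row.get("va_raw")
        if va_raw is not None and str(va_raw).strip() not in ("", "nan"):
            rec.va = va_to_decimal(str(va_raw))
        rec.treated = bool(int(row["treated"])) if "treated" in row else False
        visits[date_str] = rec
    out = []
    for (pid, eye), visits in sorted(by_eye.items()):
        if len(visits) < 2:
            log.info("excluding eye %s_%s: fewer than 2 visits", pid, eye)
            continue
        series = EyeSeries(patient_id=pid, eye=eye, visits=list(visits.values())).sort()
        out.append(series)
    return out


def read_cohort(root: str | Path, mode: str = "intersection") -> list[EyeSeries]:
    """Read a cohort directory written by :func:`vaforecast.cohort.write_cohort`."""
    root = Path(root)
    index = pd.read_csv(root / "index.csv", dtype={"va_raw": str})
    records: dict[tuple[str, str, str], VisitRecord] = {}
    per_eye_counter: dict[str, int] = {}
    for _, row in index.iterrows():
        eye_id = f"{row['patient_id']}_{row['eye']}"
        n = per_eye_counter.get(eye_id, 0) + 1
        per_eye_counter[eye_id] = n
        xml_path = root / eye_id / f"visit_{n:02d}.xml"
        if xml_path.exists():
            rec = parse_heidelberg_xml(xml_path)
            png = xml_path.with_suffix(".png")
            if png.exists():
                rec.image_path = str(png)
            records[(str(row["patient_id"]), str(row["eye"]), str(row["visit_date"]))] = rec
    return assemble_series(index, records, mode=mode)
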