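"""Curation pipeline for literature egg-description records.

Turns raw tab-delimited entries — taxon fields, free-text measurements in mm
(``0.6 ± 0.05``, ``0.5–0.7``, ``1.2``), and optional image measurements in
pixels — into a final trait table: parse the text descriptors, derive
lengths/widths/volumes, merge text and image sources (text wins where both
exist; asymmetry and curvature only ever come from images), drop extreme
outliers (top 0.1 percentile of image-derived aspect ratio and asymmetry),
and apply the analysis transforms (log10 for strictly positive size traits,
square root for the zero-inflated shape traits).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import DerivedMeasurement, RawMeasurement, derive_measurement, ellipsoid_volume

__all__ = [
    "MeasurementDescriptor",
    "TextEggRecord",
    "TextDerived",
    "FinalEggRecord",
    "MeasurementParseError",
    "IncompleteRecordError",
    "parse_measurement",
    "representative_value",
    "derive_text",
    "merge",
    "exclusion_thresholds",
    "exclusion_filters",
    "transform",
    "read_raw_tsv",
    "process_raw",
    "write_final_tsv",
    "RAW_COLUMNS",
    "FINAL_COLUMNS",
]


class MeasurementParseError(ValueError):
    """Raised when a free-text measurement cannot be interpreted."""


class IncompleteRecordError(ValueError):
    """Raised when a record carries no usable measurement at all."""


# ---------------------------------------------------------------------------
# text measurement grammar

_NUM = r"(\d+(?:\.\d+)?)"
_AVG_DEV_RE = re.compile(rf"{_NUM}\s*(?:±|\+/-|\+-)\s*{_NUM}")
_RANGE_RE = re.compile(rf"{_NUM}\s*(?:–|—|−|-|\bto\b)\s*{_NUM}")
_SINGLE_RE = re.compile(_NUM)
_BAD_UNIT_RE = re.compile(r"(?:\bcm\b|µm|μm|\bum\b|micron|\binch(?:es)?\b|\bin\.)", re.IGNORECASE)


def _decimals(numeral: str) -> int:
    return len(numeral.split(".")[1]) if "." in numeral else 0


@dataclass(frozen=True)
class MeasurementDescriptor:
    """A parsed text measurement: average±deviation, range, or single value.

    ``decimal_places`` records the decimal count of the least precise numeral
    in the description, counted from the string as printed in mm (trailing
    zeros are significant).
    """

    kind: str                      # "avg_dev" | "range" | "single"
    primary_value: float           # mean / lower endpoint / the value, mm
    secondary_value: Optional[float]  # deviation / upper endpoint
    raw_text: str
    decimal_places: int

    def __post_init__(self) -> None:
        if self.kind not in ("avg_dev", "range", "single"):
            raise MeasurementParseError(f"unknown descriptor kind {self.kind!r}")
        if self.primary_value <= 0:
            raise MeasurementParseError("measurement values must be positive")
        if self.kind == "range" and self.secondary_value < self.primary_value:
            raise MeasurementParseError("range endpoints must be ordered")


def parse_measurement(raw: str) -> MeasurementDescriptor:
    """Parse a text measurement string (mm).

    Recognises ``a ± b`` (average and deviation), ``a–b``/``a-b``/``a to b``
    (range), and bare numbers, each with an optional ``mm`` suffix; when
    several forms are present, precedence is average±deviation > range >
    single value.  Strings carrying non-mm units are rejected rather than
    converted.
    """
    if not raw or not raw.strip():
        raise MeasurementParseError("empty measurement string")
    text = raw.strip()
    if _BAD_UNIT_RE.search(text):
        raise MeasurementParseError(f"only mm measurements are supported: {raw!r}")

    m = _AVG_DEV_RE.search(text)
    if m:
        mean, dev = float(m.group(1)), float(m.group(2))
        return MeasurementDescriptor(
            kind="avg_dev", primary_value=mean, secondary_value=dev, raw_text=raw,
            decimal_places=min(_decimals(m.group(1)), _decimals(m.group(2))),
        )
    m = _RANGE_RE.search(text)
    if m:
        lo, hi = sorted((float(m.group(1)), float(m.group(2))))
        return MeasurementDescriptor(
            kind="range", primary_value=lo, secondary_value=hi, raw_text=raw,
            decimal_places=min(_decimals(m.group(1)), _decimals(m.group(2))),
        )
    m = _SINGLE_RE.search(text)
    if m:
        return MeasurementDescriptor(
            kind="single", primary_value=float(m.group(1)), secondary_value=None,
            raw_text=raw, decimal_places=_decimals(m.group(1)),
        )
    raise MeasurementParseError(f"unparseable measurement: {raw!r}")


def representative_value(d: MeasurementDescriptor) -> float:
    """One number standing for a descriptor: the mean for average±deviation,
    the midpoint (median of the two endpoints) for a range, the value itself
    for a single measurement."""
    if d.kind == "avg_dev":
        return d.primary_value
    if d.kind == "range":
        return (d.primary_value + d.secondary_value) / 2.0
    return d.primary_value


# ---------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class TextEggRecord:
    """One literature entry: taxon strings plus text measurements in mm."""

    genus: str
    species: str = ""
    family: str = ""
    order: str = ""
    length: Optional[MeasurementDescriptor] = None
    width: Optional[MeasurementDescriptor] = None
    breadth: Optional[MeasurementDescriptor] = None
    volume_reported: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.genus:
            raise IncompleteRecordError("a genus name is required")
        if (self.length is None and self.width is None and self.breadth is None
                and self.volume_reported is None):
            raise IncompleteRecordError(
                "a record needs at least one measurement or a reported volume")


@dataclass(frozen=True)
class TextDerived:
    """Values derived from the text description alone (all mm / mm^3)."""

    length_mm: Optional[float] = None
    width_mm: Optional[float] = None
    breadth_mm: Optional[float] = None
    volume_mm3: Optional[float] = None
    aspect_ratio: Optional[float] = None
    volume_provenance: Optional[str] = None   # "text" (computed) | "reported"


def derive_text(rec: TextEggRecord) -> TextDerived:
    """Derive sizes from a text record.

    Width is the wider and breadth the narrower of the two transverse
    diameters; volume is the ellipsoid volume from l/w(/b), falling back to a
    reported volume only when it cannot be computed from linear dimensions.
    """
    l = representative_value(rec.length) if rec.length else None
    w = representative_value(rec.width) if rec.width else None
    b = representative_value(rec.breadth) if rec.breadth else None
    if w is not None and b is not None:
        w, b = max(w, b), min(w, b)

    volume = None
    vol_prov = None
    if l is not None and w is not None:
        volume = ellipsoid_volume(l, w, b)
        vol_prov = "text"
    elif rec.volume_reported is not None:
        volume = rec.volume_reported
        vol_prov = "reported"

    aspect = l / w if (l is not None and w is not None) else None
    if l is None and w is None and b is None and volume is None:
        raise IncompleteRecordError("record has no derivable values")
    return TextDerived(length_mm=l, width_mm=w, breadth_mm=b, volume_mm3=volume,
                       aspect_ratio=aspect, volume_provenance=vol_prov)


@dataclass(frozen=True)
class FinalEggRecord:
    """One curated dataset entry with per-field provenance and transforms.

    Size traits are in mm / mm^3; the angle of curvature is stored in
    radians.  ``image_aspect_ratio``/``image_asymmetry`` retain the
    image-derived values used by the extreme-shape exclusion filters even
    when the final value came from text.
    """

    length_mm: Optional[float] = None
    width_mm: Optional[float] = None
    breadth_mm: Optional[float] = None
    volume_mm3: Optional[float] = None
    aspect_ratio: Optional[float] = None
    asymmetry: Optional[float] = None
    curvature_rad: Optional[float] = None
    image_aspect_ratio: Optional[float] = None
    image_asymmetry: Optional[float] = None
    provenance: dict = field(default_factory=dict)
    # transforms, populated by transform()
    log10_length: Optional[float] = None
    log10_width: Optional[float] = None
    log10_breadth: Optional[float] = None
    log10_volume: Optional[float] = None
    log10_aspect_ratio: Optional[float] = None
    sqrt_asymmetry: Optional[float] = None
    sqrt_curvature: Optional[float] = None
    taxon: dict = field(default_factory=dict)
    source_id: str = ""


def merge(text_derived: Optional[TextDerived],
          image_derived: Optional[DerivedMeasurement],
          taxon: Optional[dict] = None, source_id: str = "") -> FinalEggRecord:
    """Merge text- and image-derived values into a final record.

    Text wins for every trait available from both sources; asymmetry and the
    angle of curvature are only ever taken from images.
    """
    if text_derived is None and image_derived is None:
        raise IncompleteRecordError("neither text nor image values present")

    def pick(text_val, image_val):
        if text_val is not None:
            return text_val, "text"
        if image_val is not None:
            return image_val, "image"
        return None, None

    t = text_derived or TextDerived()
    i = image_derived
    prov: dict = {}
    length, prov["length"] = pick(t.length_mm, i.length_mm if i else None)
    width, prov["width"] = pick(t.width_mm, i.width_mm if i else None)
    breadth, prov["breadth"] = pick(t.breadth_mm, None)
    volume, prov["volume"] = pick(t.volume_mm3, i.volume_mm3 if i else None)
    if prov["volume"] == "text" and t.volume_provenance == "reported":
        prov["volume"] = "reported"
    aspect, prov["aspect_ratio"] = pick(t.aspect_ratio, i.aspect_ratio if i else None)
    asym = i.asymmetry if i else None
    prov["asymmetry"] = "image" if asym is not None else None
    curv = i.curvature_rad if i else None
    prov["curvature"] = "image" if curv is not None else None

    return FinalEggRecord(
        length_mm=length, width_mm=width, breadth_mm=breadth, volume_mm3=volume,
        aspect_ratio=aspect, asymmetry=asym, curvature_rad=curv,
        image_aspect_ratio=i.aspect_ratio if i else None,
        image_asymmetry=i.asymmetry if i else None,
        provenance=prov, taxon=dict(taxon or {}), source_id=source_id,
    )


# ---------------------------------------------------------------------------
# exclusion filters and transforms

def exclusion_thresholds(records: Sequence[FinalEggRecord],
                         percentile: float = 99.9) -> Tuple[Optional[float], Optional[float]]:
    """The (aspect-ratio, asymmetry) cutoffs: the ``percentile``-th percentile
    (linear interpolation) of the nonmissing image-derived values."""
    ars = [r.image_aspect_ratio for r in records if r.image_aspect_ratio is not None]
    asyms = [r.image_asymmetry for r in records if r.image_asymmetry is not None]
    ar_thr = float(np.percentile(ars, percentile)) if ars else None
    asym_thr = float(np.percentile(asyms, percentile)) if asyms else None
    return ar_thr, asym_thr


def exclusion_filters(records: Sequence[FinalEggRecord],
                      thresholds: Optional[Tuple[Optional[float], Optional[float]]] = None,
                      percentile: float = 99.9) -> List[FinalEggRecord]:
    """Drop extreme-shape records and null out unreliable curvature.

    Records whose *image-derived* aspect ratio (resp. asymmetry) is strictly
    above the 99.9th percentile of the nonmissing values are removed — the
    top 0.1 percentile, where measurement variance blows up.  Curvature is
    nulled wherever the final aspect ratio is one or less.  Pass precomputed
    ``thresholds`` to re-apply frozen cutoffs.
    """
    if not records:
        return []
    if thresholds is None:
        thresholds = exclusion_thresholds(records, percentile)
    ar_thr, asym_thr = thresholds

    kept: List[FinalEggRecord] = []
    for r in records:
        if ar_thr is not None and r.image_aspect_ratio is not None and r.image_aspect_ratio > ar_thr:
            continue
        if asym_thr is not None and r.image_asymmetry is not None and r.image_asymmetry > asym_thr:
            continue
        if (r.curvature_rad is not None and r.aspect_ratio is not None
                and r.aspect_ratio <= 1.0):
            r = replace(r, curvature_rad=None,
                        provenance={**r.provenance, "curvature": None})
        kept.append(r)
    return kept


def transform(rec: FinalEggRecord) -> FinalEggRecord:
    """Apply the analysis transforms to one record.

    Strictly positive size traits (length, width, breadth, volume, aspect
    ratio) are log10 transformed; zero-inflated shape traits (asymmetry,
    curvature in radians) are square-root transformed.
    """
    def log10(v: Optional[float], name: str) -> Optional[float]:
        if v is None:
            return None
        if v <= 0:
            raise ValueError(f"log10 transform requires positive {name}, got {v}")
        return math.log10(v)

    def sqrt(v: Optional[float], name: str) -> Optional[float]:
        if v is None:
            return None
        if v < 0:
            raise ValueError(f"sqrt transform requires non-negative {name}, got {v}")
        return math.sqrt(v)

    return replace(
        rec,
        log10_length=log10(rec.length_mm, "length"),
        log10_width=log10(rec.width_mm, "width"),
        log10_breadth=log10(rec.breadth_mm, "breadth"),
        log10_volume=log10(rec.volume_mm3, "volume"),
        log10_aspect_ratio=log10(rec.aspect_ratio, "aspect ratio"),
        sqrt_asymmetry=sqrt(rec.asymmetry, "asymmetry"),
        sqrt_curvature=sqrt(rec.curvature_rad, "curvature"),
    )


# ---------------------------------------------------------------------------
# TSV dialects

RAW_COLUMNS = [
    "order", "family", "genus", "species", "source_id",
    "length_text", "width_text", "breadth_text", "volume_reported",
    "straight_length_px", "curved_length_px", "q1_px", "q2_px", "q3_px",
    "curvature_deg", "px_per_mm",
]

FINAL_COLUMNS = [
    "order", "family", "genus", "species", "source_id",
    "length", "width", "breadth", "volume", "aspect_ratio", "asymmetry",
    "angle_of_curvature",
    "log10_length", "log10_width", "log10_breadth", "log10_volume",
    "log10_aspect_ratio", "sqrt_asymmetry", "sqrt_angle_of_curvature",
    "provenance_length", "provenance_width", "provenance_volume",
    "provenance_aspect_ratio",
    # extra columns retained for downstream QC
    "length_text", "length_kind", "length_primary", "length_secondary",
    "length_decimal_places", "text_length", "image_length",
    "image_aspect_ratio", "image_asymmetry",
]


def read_raw_tsv(path) -> pd.DataFrame:
    """Read the raw-dataset dialect (UTF-8, tab-delimited, header required)."""
    df = pd.read_csv(path, sep="\t", dtype={c: "string" for c in
                                            ("order", "family", "genus", "species",
                                             "source_id", "length_text", "width_text",
                                             "breadth_text")})
    missing = [c for c in ("genus", "length_text") if c not in df.columns]
    if missing:
        raise ValueError(f"raw dataset missing columns: {missing}")
    return df


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def _opt_text(value) -> Optional[str]:
    if value is None or pd.isna(value) or str(value).strip() == "":
        return None
    return str(value)


def process_raw(df: pd.DataFrame, apply_filters: bool = True) -> pd.DataFrame:
    """Run the full curation pipeline on a raw-dialect DataFrame.

    Parses text descriptors, derives text and image values, merges with text
    precedence, optionally applies the extreme-shape exclusion filters, and
    appends the transformed columns.  Output row order follows the input
    (minus excluded records) and is byte-stable across runs.
    """
    records: List[FinalEggRecord] = []
    extras: List[dict] = []
    for _, row in df.iterrows():
        descriptors = {}
        for name in ("length", "width", "breadth"):
            raw = _opt_text(row.get(f"{name}_text"))
            descriptors[name] = parse_measurement(raw) if raw else None
        vol = _opt_float(row.get("volume_reported"))

        text_derived = None
        if any(descriptors.values()) or vol is not None:
            trec = TextEggRecord(
                genus=_opt_text(row.get("genus")) or "",
                species=_opt_text(row.get("species")) or "",
                family=_opt_text(row.get("family")) or "",
                order=_opt_text(row.get("order")) or "",
                length=descriptors["length"], width=descriptors["width"],
                breadth=descriptors["breadth"], volume_reported=vol,
                source_id=_opt_text(row.get("source_id")) or "",
            )
            text_derived = derive_text(trec)

        image_derived = None
        sl = _opt_float(row.get("straight_length_px"))
        if sl is not None:
            qs = {k: _opt_float(row.get(k)) for k in ("q1_px", "q2_px", "q3_px")}
            if any(v is None for v in qs.values()):
                raise ValueError("image measurements require q1_px, q2_px and q3_px")
            raw_m = RawMeasurement(
                straight_length_px=sl,
                curved_length_px=_opt_float(row.get("curved_length_px")) or sl,
                q1_px=qs["q1_px"], q2_px=qs["q2_px"], q3_px=qs["q3_px"],
                curvature_deg=_opt_float(row.get("curvature_deg")) or 0.0,
            )
            image_derived = derive_measurement(raw_m, px_per_mm=_opt_float(row.get("px_per_mm")))

        taxon = {k: _opt_text(row.get(k)) or "" for k in ("order", "family", "genus", "species")}
        rec = merge(text_derived, image_derived, taxon=taxon,
                    source_id=_opt_text(row.get("source_id")) or "")
        records.append(rec)
        ld = descriptors["length"]
        extras.append({
            "length_text": _opt_text(row.get("length_text")),
            "length_kind": ld.kind if ld else None,
            "length_primary": ld.primary_value if ld else None,
            "length_secondary": ld.secondary_value if ld else None,
            "length_decimal_places": ld.decimal_places if ld else None,
            "text_length": text_derived.length_mm if text_derived else None,
            "image_length": image_derived.length_mm if image_derived else None,
        })

    if apply_filters:
        # exclusion_filters may replace curvature-nulled records, so filter
        # positionally with frozen thresholds to keep extras paired
        thresholds = exclusion_thresholds(records)
        filtered = []
        for rec, extra in zip(records, extras):
            out = exclusion_filters([rec], thresholds=thresholds)
            if out:
                filtered.append((out[0], extra))
    else:
        filtered = list(zip(records, extras))

    rows = []
    for rec, extra in filtered:
        rec = transform(rec)
        rows.append({
            **{k: rec.taxon.get(k, "") for k in ("order", "family", "genus", "species")},
            "source_id": rec.source_id,
            "length": rec.length_mm, "width": rec.width_mm, "breadth": rec.breadth_mm,
            "volume": rec.volume_mm3, "aspect_ratio": rec.aspect_ratio,
            "asymmetry": rec.asymmetry, "angle_of_curvature": rec.curvature_rad,
            "log10_length": rec.log10_length, "log10_width": rec.log10_width,
            "log10_breadth": rec.log10_breadth, "log10_volume": rec.log10_volume,
            "log10_aspect_ratio": rec.log10_aspect_ratio,
            "sqrt_asymmetry": rec.sqrt_asymmetry,
            "sqrt_angle_of_curvature": rec.sqrt_curvature,
            "provenance_length": rec.provenance.get("length"),
            "provenance_width": rec.provenance.get("width"),
            "provenance_volume": rec.provenance.get("volume"),
            "provenance_aspect_ratio": rec.provenance.get("aspect_ratio"),
            **extra,
            "image_aspect_ratio": rec.image_aspect_ratio,
            "image_asymmetry": rec.image_asymmetry,
        })
    return pd.DataFrame(rows, columns=FINAL_COLUMNS)


def write_final_tsv(df: pd.DataFrame, path) -> None:
    """Write the final-dataset dialect (missing values as empty fields)."""
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.9g")
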