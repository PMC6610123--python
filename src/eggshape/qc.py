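"""Dataset quality control: intraspecific variation, precision, coverage.

Four intraspecific-variation metrics (percent difference within a
description, across publications, text vs image, triaxial vs rotationally
symmetric volume), two precision metrics (decimal places and relative
precision of the printed length), and the per-rank phylogenetic coverage
ratio (entries per 100 estimated species).
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import ellipsoid_volume
from .records import parse_measurement, representative_value

__all__ = [
    "VariationResult",
    "PrecisionResult",
    "CoverageRow",
    "VOLUME_INDEPENDENCE_THRESHOLD_MM3",
    "COVERAGE_STANDARD_PER_100",
    "pct_diff_range",
    "pct_diff_avgdev",
    "independent_observations",
    "across_publication_variation",
    "triaxial_vs_symmetric",
    "decimal_places",
    "relative_precision",
    "coverage",
    "variation_report",
    "precision_report",
    "histogram_table",
]

#: Two same-species entries whose calculated volumes differ by more than this
#: (mm^3) are treated as independent observations rather than repeats.
VOLUME_INDEPENDENCE_THRESHOLD_MM3 = 1.0e-5

#: The arbitrary sampling standard: one dataset entry per 100 estimated species.
COVERAGE_STANDARD_PER_100 = 1.0


@dataclass(frozen=True)
class VariationResult:
    species: str
    method: str  # within_description | across_publications | text_vs_image | triaxial_vs_symmetric
    pct_diff: float


@dataclass(frozen=True)
class PrecisionResult:
    entry_id: str
    decimal_places: int
    relative_precision_pct: float


@dataclass(frozen=True)
class CoverageRow:
    rank_name: str
    n_entries: int
    n_species_estimated: Optional[int]
    entries_per_100_species: Optional[float]
    below_standard: Optional[bool]


# ---------------------------------------------------------------------------
# percent-difference metrics

def pct_diff_range(values: Sequence[float]) -> float:
    """Percent difference of a set of lengths: 100 * (max - min) / median.

    The median of two values is their midpoint.
    """
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("pct_diff_range needs at least two values")
    if min(vals) <= 0:
        raise ValueError("values must be positive")
    return 100.0 * (max(vals) - min(vals)) / float(np.median(vals))


def pct_diff_avgdev(mean: float, deviation: float) -> float:
    """Percent difference of an average-and-deviation description:
    100 * (2 * deviation) / mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if deviation < 0:
        raise ValueError("deviation must be non-negative")
    return 100.0 * (2.0 * deviation) / mean


def triaxial_vs_symmetric(l: float, w: float, b: float) -> float:
    """Percent change in volume between the triaxial ellipsoid model
    (1/6)πlwb and the rotationally symmetric model (1/6)πlw²."""
    if w < b:
        raise ValueError("width must be >= breadth (normalise upstream)")
    v_tri = ellipsoid_volume(l, w, b)
    v_sym = ellipsoid_volume(l, w)
    return pct_diff_range([v_tri, v_sym])


# ---------------------------------------------------------------------------
# independent observations

def independent_observations(entries: Sequence[Tuple[str, float]]) -> Dict[str, List[List[int]]]:
    """Group same-species entries into independent observations.

    Within a species, entries whose calculated volumes differ by at most the
    independence threshold are chained together (single linkage) as repeats
    of one observation — e.g. a description re-printed in a later review.
    Returns, per species, lists of entry indices forming each observation,
    ordered by volume.  The grouping is invariant to input order.
    """
    by_species: Dict[str, List[Tuple[float, int]]] = defaultdict(list)
    for idx, (species, volume) in enumerate(entries):
        if volume is None or not math.isfinite(volume):
            continue
        by_species[species].append((float(volume), idx))

    out: Dict[str, List[List[int]]] = {}
    for species, items in by_species.items():
        items.sort()
        groups: List[List[int]] = []
        prev_vol = None
        for vol, idx in items:
            if prev_vol is not None and vol - prev_vol <= VOLUME_INDEPENDENCE_THRESHOLD_MM3:
                groups[-1].append(idx)
            else:
                groups.append([idx])
            prev_vol = vol
        out[species] = groups
    return out


def across_publication_variation(
    entries: Sequence[Tuple[str, float, float]],
) -> List[VariationResult]:
    """Across-publication intraspecific variation.

    ``entries`` are (species, length_mm, volume_mm3) triples.  Entries are
    grouped into independent observations by volume; for species with at
    least two observations the percent difference of the group representative
    lengths (the median length within each group) is reported.
    """
    groups = independent_observations([(sp, vol) for sp, _, vol in entries])
    lengths = [ln for _, ln, _ in entries]
    results = []
    for species in sorted(groups):
        gs = groups[species]
        if len(gs) < 2:
            continue
        reps = [float(np.median([lengths[i] for i in g])) for g in gs]
        results.append(VariationResult(species=species, method="across_publications",
                                       pct_diff=pct_diff_range(reps)))
    return results


# ---------------------------------------------------------------------------
# precision metrics

_NUMERAL_RE = re.compile(r"\d+(?:\.\d+)?")


def decimal_places(raw: str) -> int:
    """Decimal places of a printed measurement, base millimetres.

    Counted from the numeral as printed, so trailing zeros are significant:
    ``"1 mm"`` has 0 decimal places, ``"1.00 mm"`` has 2.
    """
    m = _NUMERAL_RE.search(raw or "")
    if not m:
        raise ValueError(f"no numeral found in {raw!r}")
    token = m.group(0)
    return len(token.split(".")[1]) if "." in token else 0


def relative_precision(raw: str) -> float:
    """Relative precision of a printed length: the smallest measurement unit
    as a percent of egg length, 100 * 10^(-decimal places) / length.

    An egg printed as ``"1.00 mm"`` was measured within 1% of its length.
    """
    m = _NUMERAL_RE.search(raw or "")
    if not m:
        raise ValueError(f"no numeral found in {raw!r}")
    length = float(m.group(0))
    if length <= 0:
        raise ValueError("length must be positive")
    unit = 10.0 ** (-decimal_places(raw))
    return 100.0 * unit / length


# ---------------------------------------------------------------------------
# phylogenetic coverage

def coverage(entry_counts: Mapping[str, int],
             species_counts: Mapping[str, int]) -> List[CoverageRow]:
    """Entries per 100 estimated species for each taxonomic rank.

    Ranks with no species estimate are reported with missing ratio rather
    than raising; ranks below one entry per 100 species are flagged.
    """
    rows = []
    for rank, n_entries in entry_counts.items():
        n_species = species_counts.get(rank)
        if n_species is None or n_species <= 0:
            rows.append(CoverageRow(rank, int(n_entries), None, None, None))
            continue
        ratio = 100.0 * n_entries / n_species
        rows.append(CoverageRow(rank, int(n_entries), int(n_species), ratio,
                                ratio < COVERAGE_STANDARD_PER_100))
    return rows


# ---------------------------------------------------------------------------
# dataset-level reports (operate on the final-dataset TSV dialect)

def variation_report(final_df: pd.DataFrame) -> pd.DataFrame:
    """All four intraspecific-variation metrics over a final dataset frame.

    Uses the descriptor columns carried through by the curation pipeline
    (``length_kind`` etc.) plus the text/image length pairs and l/w/b sizes.
    """
    results: List[VariationResult] = []
    species_of = (final_df["genus"].fillna("").astype(str) + " "
                  + final_df["species"].fillna("").astype(str)).str.strip()

    # method 1: variation recorded within one description
    for i, row in final_df.iterrows():
        kind = row.get("length_kind")
        if pd.isna(kind):
            continue
        if kind == "avg_dev":
            pct = pct_diff_avgdev(float(row["length_primary"]), float(row["length_secondary"]))
        elif kind == "range":
            pct = pct_diff_range([float(row["length_primary"]), float(row["length_secondary"])])
        else:
            continue
        results.append(VariationResult(species_of[i], "within_description", pct))

    # method 2: across independent observations of the same species
    mask = final_df["length"].notna() & final_df["volume"].notna()
    entries = [
        (species_of[i], float(final_df.at[i, "length"]), float(final_df.at[i, "volume"]))
        for i in final_df.index[mask]
    ]
    results.extend(across_publication_variation(entries))

    # method 3: reported text length vs re-measured image length
    both = final_df["text_length"].notna() & final_df["image_length"].notna()
    for i in final_df.index[both]:
        pct = pct_diff_range([float(final_df.at[i, "text_length"]),
                              float(final_df.at[i, "image_length"])])
        results.append(VariationResult(species_of[i], "text_vs_image", pct))

    # method 4: triaxial vs rotationally symmetric volume
    tri = final_df["length"].notna() & final_df["width"].notna() & final_df["breadth"].notna()
    for i in final_df.index[tri]:
        pct = triaxial_vs_symmetric(float(final_df.at[i, "length"]),
                                    float(final_df.at[i, "width"]),
                                    float(final_df.at[i, "breadth"]))
        results.append(VariationResult(species_of[i], "triaxial_vs_symmetric", pct))

    return pd.DataFrame([{"species": r.species, "method": r.method, "pct_diff": r.pct_diff}
                         for r in results], columns=["species", "method", "pct_diff"])


def precision_report(final_df: pd.DataFrame) -> pd.DataFrame:
    """Decimal places and relative precision for every entry with a printed
    text length."""
    rows = []
    for i in final_df.index[final_df["length_text"].notna()]:
        raw = str(final_df.at[i, "length_text"])
        try:
            desc = parse_measurement(raw)
        except Exception:
            continue
        dp = desc.decimal_places
        length = representative_value(desc)
        rows.append({
            "entry_id": str(final_df.at[i, "source_id"]) if "source_id" in final_df else str(i),
            "decimal_places": dp,
            "relative_precision_pct": 100.0 * 10.0 ** (-dp) / length,
        })
    return pd.DataFrame(rows, columns=["entry_id", "decimal_places", "relative_precision_pct"])


def histogram_table(values: Sequence[float], bins) -> pd.DataFrame:
    """Histogram bin table (bin_left, bin_right, count) for report output."""
    counts, edges = np.histogram(np.asarray(list(values), dtype=float), bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
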