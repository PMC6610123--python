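"""Synthetic literature-record generator.

Emits raw-dialect record tables with realistic structure for exercising the
curation pipeline and QC metrics end to end: lognormal egg sizes centred near
1 mm, the three text description styles (single value, range, average ±
deviation) in roughly the proportions seen in compiled egg datasets,
volume-only entries, and a subset of entries with image measurements (with
and without a scale bar) consistent with the text values up to ~10%
intraspecific scatter.

These records emulate the *format* and the broad size/shape distributions of
literature data; they carry none of the taxonomic signal, transcription
errors, or unit heterogeneity of real compilations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import RAW_COLUMNS

__all__ = ["synthetic_raw_records"]

_SYLLABLES = ["ba", "ce", "do", "fi", "gu", "la", "mo", "ni", "pa", "ru", "si", "to"]

#: Mix of text description styles (single, range, avg±dev), following the
#: rough proportions reported for compiled insect-egg data.
_TEXT_KIND_P = {"single": 0.575, "range": 0.285, "avg_dev": 0.14}


def _name(rng: np.random.Generator, n_syl: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syl))


def _format_mm(value: float, decimals: int) -> str:
    # widen the precision until the printed numeral is nonzero
    while float(f"{value:.{decimals}f}") == 0.0:
        decimals += 1
    return f"{value:.{decimals}f}"


def synthetic_raw_records(
    n: int = 500,
    seed: int = 0,
    p_volume_only: float = 0.13,
    p_image: float = 0.30,
    p_image_scale: float = 0.8,
    p_breadth: float = 0.10,
    intraspecific_cv: float = 0.05,
    n_species: int | None = None,
) -> pd.DataFrame:
    """Generate ``n`` raw-dialect records (see ``records.RAW_COLUMNS``).

    ``p_image`` of records carry image measurements (a fraction
    ``p_image_scale`` of those with a scale bar); ``p_volume_only`` carry a
    reported volume and no linear dimensions.  Species are drawn from a pool
    of ``n_species`` (default ``n // 3``) so that intraspecific repeats occur.
    """
    rng = np.random.default_rng(seed)
    if n_species is None:
        n_species = max(1, n // 3)
    pool = []
    for _ in range(n_species):
        genus = _name(rng, 3).capitalize()
        species = _name(rng, 3)
        # species-level true size: lognormal around 1 mm, AR around 1.8
        length = float(10 ** rng.normal(0.0, 0.3))
        aspect = float(np.exp(rng.normal(np.log(1.8), 0.25)))
        pool.append((genus, species, length, aspect))

    kinds = list(_TEXT_KIND_P)
    kind_p = np.array([_TEXT_KIND_P[k] for k in kinds])
    kind_p = kind_p / kind_p.sum()

    rows = []
    for i in range(n):
        genus, species, sp_length, sp_aspect = pool[rng.integers(0, n_species)]
        length = sp_length * float(np.exp(rng.normal(0.0, intraspecific_cv)))
        width = length / sp_aspect
        decimals = int(rng.integers(1, 4))
        row = {c: None for c in RAW_COLUMNS}
        row.update(order="", family=genus[:2].capitalize() + "idae",
                   genus=genus, species=species, source_id=f"src{i:05d}")

        if rng.random() < p_volume_only:
            row["volume_reported"] = float(np.pi / 6 * length * width ** 2)
        else:
            kind = rng.choice(kinds, p=kind_p)
            if kind == "single":
                row["length_text"] = _format_mm(length, decimals) + " mm"
            elif kind == "range":
                half = 0.05 * length
                row["length_text"] = (f"{_format_mm(length - half, decimals)}–"
                                      f"{_format_mm(length + half, decimals)} mm")
            else:
                dev = 0.05 * length
                row["length_text"] = (f"{_format_mm(length, decimals)} ± "
                                      f"{_format_mm(dev, max(decimals, 2))} mm")
            row["width_text"] = _format_mm(width, decimals) + " mm"
            if rng.random() < p_breadth:
                row["breadth_text"] = _format_mm(width * rng.uniform(0.6, 1.0), decimals) + " mm"

        if rng.random() < p_image:
            ppm = float(rng.uniform(50, 500))           # pixels per mm
            img_len = length * float(np.exp(rng.normal(0.0, intraspecific_cv))) * ppm
            asym = float(rng.exponential(0.08))
            q1 = width * ppm
            q2 = q1 * rng.uniform(0.95, 1.0)
            q3 = q1 / (1.0 + asym)
            curv = float(rng.exponential(8.0)) if img_len / q1 > 1 else 0.0
            row.update(
                straight_length_px=img_len,
                curved_length_px=img_len * (1 + 1e-3 * curv),
                q1_px=q1, q2_px=q2, q3_px=q3, curvature_deg=curv,
                px_per_mm=ppm if rng.random() < p_image_scale else None,
            )
        rows.append(row)

    df = pd.DataFrame(rows, columns=RAW_COLUMNS)
    # guarantee at least one usable measurement everywhere (a volume-only row
    # that also drew no image is fine; a no-text no-image no-volume row is not)
    assert (df["length_text"].notna() | df["volume_reported"].notna()
            | df["straight_length_px"].notna()).all()
    return df
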