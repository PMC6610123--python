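"""Curate raw literature-style records into a final trait table.

Generates a synthetic raw table (text descriptions in mm, image measurements
in pixels), runs the full pipeline — descriptor parsing, derivation, text-
over-image merging, extreme-shape exclusion, transforms — and prints what
happened.
"""

import pandas as pd

from eggshape import process_raw, synthetic_raw_records

raw = synthetic_raw_records(n=400, seed=7)
final = process_raw(raw, apply_filters=True)

print(f"raw records     : {len(raw)}")
print(f"final records   : {len(final)}   "
      f"({len(raw) - len(final)} removed by the top-0.1-percentile shape filters)")
print(f"text lengths    : {final['text_length'].notna().sum()}")
print(f"image lengths   : {final['image_length'].notna().sum()}")
both = final["text_length"].notna() & final["image_length"].notna()
print(f"both sources    : {both.sum()}  (text wins: "
      f"{(final.loc[both, 'provenance_length'] == 'text').all()})")

with pd.option_context("display.width", 120):
    cols = ["genus", "species", "length", "width", "volume", "aspect_ratio",
            "log10_volume", "provenance_length"]
    print("\nfirst rows of the final table:")
    print(final[cols].head(5).to_string(index=False))
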