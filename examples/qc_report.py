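"""Dataset QC: intraspecific variation, precision, phylogenetic coverage.

Runs the four percent-difference variation metrics and the two precision
metrics over a synthetic curated dataset, plus the entries-per-100-species
coverage ratio against a small species-count table.
"""

from eggshape import coverage, process_raw, synthetic_raw_records
from eggshape.qc import precision_report, variation_report

final = process_raw(synthetic_raw_records(n=400, seed=7), apply_filters=True)

variation = variation_report(final)
print("intraspecific variation (percent difference in egg size):")
for method, group in variation.groupby("method"):
    print(f"  {method:<22} n={len(group):4d}  median={group['pct_diff'].median():6.2f}%")

precision = precision_report(final)
print("\nmeasurement precision of printed lengths:")
print(f"  decimal places: median {precision['decimal_places'].median():.0f}")
print(f"  relative precision: median {precision['relative_precision_pct'].median():.2f}% "
      "of egg length")

rows = coverage({"Coleoptera": 55, "Zygentoma": 1}, {"Coleoptera": 2500, "Zygentoma": 550})
print("\nphylogenetic coverage (entries per 100 estimated species):")
for r in rows:
    flag = "  <-- below 1-per-100 standard" if r.below_standard else ""
    print(f"  {r.rank_name:<12} {r.n_entries:3d} entries / {r.n_species_estimated} species"
          f" = {r.entries_per_100_species:.2f}{flag}")
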