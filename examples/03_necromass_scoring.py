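"""Necromass scoring of the packaged 63-spring survey table.

The packaged score table carries, per assembly, the summed abundance of
cell-degrading (chitin + peptidoglycan) and photosynthate-degrading
(xylan + cellulose) secreted CAZymes. The necromass fraction
cell/(cell+photo) says how strongly each community leans on dead microbial
biomass; a study dominated by fractions > 0.5 points to chemolithoautotroph
necromass, not plant matter, feeding the heterotrophs.
"""

from thermenz.scoring import (
    load_printed_scores, necromass_fraction, round_fraction, threshold_counts,
)

scores = load_printed_scores()
frac = necromass_fraction(scores["cell"], scores["photosynthate"])

for sample in ("RS17S", "BJ19F", "KR21S"):
    row = scores.set_index("sample_id").loc[sample]
    f = round_fraction(necromass_fraction(float(row["cell"]),
                                          float(row["photosynthate"])))
    print(f"{sample}: cell {row['cell']:>9.2f}  photosynthate {row['photosynthate']:>8.2f}"
          f"  -> necromass fraction {f:.2f}")

counts = threshold_counts(scores)
print(f"\nassemblies: {len(scores)}")
print(f"grand totals: cell {scores['cell'].sum():.2f}, "
      f"photosynthate {scores['photosynthate'].sum():.2f}")
print(f"assemblies with fraction < 0.50: {counts['n_fraction_below']} "
      "(cell-degradation dominates nearly everywhere else)")
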