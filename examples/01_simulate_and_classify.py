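"""Generate a separable synthetic community and run the origin classifier.

Contaminant ASVs are verbatim copies of control sequences (no-template,
drilling-fluid, seawater) while indigenous ASVs stay below 97% identity to
every control, so a correct classifier must recover the planted contaminants
exactly. Prints the per-category ASV tally and the per-sample removed-read
fraction next to the planted truth.
"""

from collections import Counter

import lithoscreen as ls

params = ls.GeneratorParams(seed=7)
community = ls.make_community(params)
table = ls.sample_counts(community, params)

seqs = {a.id: a for a in community.asvs}
calls = ls.classify_table(
    table, seqs, community.controls, community.whitelist, community.environment
)

print("ASVs per origin category:")
for cat, n in sorted(Counter(c.category.value for c in calls).items()):
    print(f"  {cat:22s} {n}")

result = ls.filter_contaminants(table, calls)
print("\nsample  removed_fraction  planted  fully_excluded")
for _, row in result.report.iterrows():
    planted = community.truth.contaminant_fractions[row.sample_id]
    print(f"{row.sample_id:6s}  {row.fraction_removed:16.4f}  {planted:7.3f}"
          f"  {bool(row.fully_excluded)}")

print(
    "\nEach sample's removed-read fraction tracks the contaminant read mass"
    "\nplanted by the generator; the fully contaminated sample (S8) is"
    "\nexcluded outright, the fate of one real crustal sample in such screens."
)
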