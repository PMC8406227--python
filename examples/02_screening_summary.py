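"""Screening-success accounting over the packaged expedition metadata table.

The fixture transcribes the 29-sample metadata of a low-biomass subsurface
drilling survey: lithology, depth, cell density (with below-detection
sentinels), whether cell sorting found cells, whether PCR of the amplified
DNA succeeded, and whether amplicon sequencing succeeded.
"""

import json

import lithoscreen as ls

samples = ls.reference_sample_table()
summary = ls.summarize_screening(samples)
print(json.dumps(summary.to_dict(), indent=2))

print(
    "\nOf the 29 screened samples, cells were detected in"
    f" {summary.n_cells_detected}; {summary.n_sequenced} yielded 16S amplicon"
    f" sequence data ({summary.to_dict()['efficiency_percent_display']:.0f}%"
    " end-to-end efficiency), split"
    f" {summary.n_sequenced_sediment} sediment / {summary.n_sequenced_crust}"
    " crust by the lithology heuristic."
)
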