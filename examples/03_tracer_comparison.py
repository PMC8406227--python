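"""Compare indigenous read fraction against the drilling-fluid tracer.

The perfluorocarbon (PFC) tracer is added to drilling fluid; its concentration
in a core interior indexes drilling contamination. On a noise-free synthetic
cohort the tracer is monotone in the planted contaminant fraction, so the
indigenous (subsurface + possibly subsurface) read fraction anti-correlates
perfectly: rank correlation -1 with an exact permutation p-value.
"""

import json

import lithoscreen as ls
from lithoscreen.records import PcrStatus, SeqStatus, Sentinel

params = ls.GeneratorParams(seed=7)
community = ls.make_community(params)
table = ls.sample_counts(community, params)
tracer = ls.make_tracer(community.truth, noise_sd=0.0)

seqs = {a.id: a for a in community.asvs}
calls = ls.classify_table(
    table, seqs, community.controls, community.whitelist, community.environment
)
profiles = ls.category_abundance(table, calls)

samples = [
    ls.SampleRecord(
        sample_id=sid, lithology="serpentinized harzburgite", depth_mbsf=1.0,
        cell_density=100.0, pcr_status=PcrStatus.POSITIVE,
        seq_status=SeqStatus.SUCCESS,
        pfc_interior=tracer[sid], pfc_exterior=Sentinel("BDL"),
    )
    for sid in table.sample_ids
]

report = ls.tracer_comparison(profiles, samples)
print(json.dumps(report, indent=2))
print(
    "\nrank_correlation -1.0 means samples with more drilling tracer carry"
    "\nproportionally fewer indigenous reads, exactly as constructed."
)
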