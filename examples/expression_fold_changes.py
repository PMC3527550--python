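"""Probe-level expression data to signed fold changes and hit lists.

Two demonstrations:

1. the full synthetic pipeline — MAD outlier filter, probe averaging,
   quantile normalization, signed fold change — recovering a planted
   2-fold down-regulation;
2. re-applying the 1.8-fold filter to the bundled published hit table,
   reproducing its per-timepoint row counts.
"""

import numpy as np

from mirtraffic import expression as ex
from mirtraffic.reference import table1_records
from mirtraffic.synthgen import ExpressionSpec, make_expression_dataset

planted = {("TX0001", 24): 0.5, ("TX0002", 24): 0.5, ("TX0003", 24): 0.5}
spec = ExpressionSpec(n_transcripts=80, planted_fold_changes=planted, rng_seed=21)
probes, design, truth = make_expression_dataset(spec)
print(f"{len(probes)} probes x {len(design)} arrays (duplicates per condition/timepoint)")

summarized = ex.summarize_probes(probes)
records = ex.fold_changes(summarized, design)
at24 = {r.transcript_id: r for r in records if r.timepoint == 24}
print("recovered signed fold changes at 24 h (planted -2.0):")
for tid, _tp in planted:
    print(f"  {tid}: {at24[tid].fold_change:+.2f}")
hits = ex.select_regulated(records, threshold=1.5)
print(f"transcripts passing the 1.5-fold filter: {hits['union']}")

print("\npublished hit table re-filtered at 1.8-fold:")
table_hits = ex.select_regulated(table1_records(), threshold=1.8)
for tp, lists in sorted(table_hits["per_timepoint"].items()):
    print(f"  {tp:2d} h: {len(lists['down'])} down, {len(lists['up'])} up")
print(f"  union: {len(table_hits['union'])} unique transcripts")
print(
    "\nThe 12/24/48 h counts (4, 9, 18) and the deduplicated union match"
    " the published table; sign -2.0 means halved expression."
)
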