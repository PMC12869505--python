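"""Segment-free fiber morphometry on a synthetic muscle section.

Generates a ground-truthed three-channel section, applies the QC filter
and measures every retained fiber: minimum Feret diameter (orientation-
robust fiber size) and internal-nuclei count (degeneration marker).
"""

import numpy as np

from myophen.morphometry import fiber_table
from myophen.synth import SectionParams, make_section

image, truth = make_section(SectionParams(n_fibers=80, seed=1))
table = fiber_table(image, truth.label_mask)

print(f"fibers generated: {len(truth.table)}, retained after QC: {len(table)}")
print(f"median minimum Feret: {table.min_feret_um.median():.1f} um "
      f"(generator size law median: 40.0 um)")
dist = table.n_internal_nuclei.value_counts(normalize=True).sort_index()
print("internal-nuclei distribution (fraction of fibers):")
for k, frac in dist.items():
    print(f"  {k} nuclei: {100 * frac:.1f}%")
merged = table.merge(truth.table, on="fiber_id")
acc = (merged.n_internal_nuclei_x == merged.n_internal_nuclei_y).mean()
print(f"counts matching ground truth: {100 * acc:.1f}% of retained fibers")
# QC removes border-clipped and irregular fibers, so the retained count is
# below the generated count; the Feret median estimates the size law.
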