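"""Collagen-VI / perlecan basal-lamina ratio in a 2-um peripheral band.

Collagen-VI deficiency shows up as a reduced collagen-VI signal relative
to perlecan (a basement-membrane reference) around each fiber.  Two
sections are generated, one with full and one with 60% collagen-VI
amplitude, and the measured per-fiber ratio medians are compared.
"""

import numpy as np

from myophen.lamina import measure_section
from myophen.synth import SectionParams, make_section

for label, amp_ratio in (("wild-type-like", 1.0), ("mutant-like", 0.6)):
    image, truth = make_section(
        SectionParams(n_fibers=80, seed=2, col6_amplitude=6000.0 * amp_ratio)
    )
    measures = measure_section(image, truth.label_mask)
    median = np.nanmedian(measures["ratio"])
    print(f"{label:16s} true amplitude ratio {amp_ratio:.1f} -> "
          f"measured median per-fiber ratio {median:.3f} "
          f"({measures['ratio'].notna().sum()} fibers)")
# The measured medians recover the generated amplitude ratios; downstream,
# genotype groups are compared with the effect-size-gated rank tests.
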