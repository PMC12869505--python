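"""Percent fibrotic area on a synthetic Picro-Sirius-Red section.

The red-excess signal is thresholded per 500x500-px ROI with Li's
minimum-cross-entropy method; the percent of above-threshold pixels over
the whole ROI quantifies collagen deposition (fibrosis).
"""

from myophen.fibrosis import psr_signal, section_fibrosis, tile_rois
from myophen.synth import make_psr

for frac in (0.05, 0.10, 0.25):
    rgb, truth = make_psr(frac, canvas=(1500, 1500), seed=3)
    signal = psr_signal(rgb)
    table, summary = section_fibrosis(signal, tile_rois(signal.shape))
    print(f"true fraction {100 * truth:5.2f}% -> mean over "
          f"{summary['n_rois']} ROIs {summary['mean_percent']:5.2f}% "
          f"(median {summary['median_percent']:5.2f}%)")
# Per-ROI values (table.percent_area) feed violin plots and group tests.
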