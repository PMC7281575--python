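"""Select regions of interest and trim a run to a small synthetic spectrum.

The default strategy divides the m/z range into 4 bins, finds the
highest-intensity sliding window in each bin and a single best RT window,
and keeps only the centroids inside their intersections.  The trimmed run
is the small peak-rich surrogate the parameter optimizer works on.
"""

import metaboflow as mf
from examples_common import make_planted_peaks

peaks = make_planted_peaks(seed=2, n_peaks=25)
run = mf.simulate_run(
    peaks, mf.NoiseModel(60, 25, 12), rt_grid=(0, 240, 1), mz_jitter_ppm=3, seed=2
)

spec = mf.TrimSpec(rt_fraction=0.5)  # 4 m/z bins, RT window = 50% of the run
rois = mf.select_rois(run, spec)
for i, roi in enumerate(rois):
    print(
        f"ROI {i + 1}: m/z {roi.mz_lo:7.1f}-{roi.mz_hi:7.1f}  "
        f"RT {roi.rt_lo:5.0f}-{roi.rt_hi:5.0f} s  intensity sum {roi.score:.3e}"
    )

trimmed = mf.trim_run(run, spec, rois)
full = sum(s.intensity.sum() for s in run.scans)
kept = sum(s.intensity.sum() for s in trimmed.scans)
in_roi = sum(
    any(r.mz_lo <= p.mz <= r.mz_hi and r.rt_lo <= p.rt_apex <= r.rt_hi for r in rois)
    for p in peaks
)
print(f"\ntrimmed run: {len(trimmed)} of {len(run)} scans, "
      f"{100 * kept / full:.1f}% of total intensity")
print(f"planted peaks with apex inside an ROI: {in_roi}/{len(peaks)}")
# The ROIs concentrate most of the signal into a fraction of the run while
# still containing real (including low-intensity) peaks to optimize on.
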