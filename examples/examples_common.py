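"""Shared helper for the example scripts: a reproducible planted-peak set."""

import numpy as np

import metaboflow as mf


def make_planted_peaks(seed: int, n_peaks: int = 20):
    rng = np.random.default_rng(seed)
    mzs = rng.uniform(100, 900, n_peaks)
    return [
        mf.PlantedPeak(
            mz=float(mzs[i]),
            rt_apex=float(rng.uniform(30, 210)),
            rt_sigma=float(rng.uniform(3, 6)),
            height=float(10 ** rng.uniform(3.7, 5.7)),
            isotope_partner=bool(rng.random() < 0.7),
            isotope_abundance=float(rng.uniform(0.08, 0.3)),
        )
        for i in range(n_peaks)
    ]
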