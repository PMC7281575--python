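import numpy as np
import pytest

from metaboflow import NoiseModel, PickerParams, PlantedPeak, simulate_run


def make_peak_set(seed: int, n_peaks: int = 25, rt_range=(30.0, 210.0)):
    """Planted peaks with sigma in [3, 6] s and isotopologue partners."""
    rng = np.random.default_rng(seed)
    mzs = rng.uniform(100, 900, n_peaks)
    return [
        PlantedPeak(
            mz=float(mzs[i]),
            rt_apex=float(rng.uniform(*rt_range)),
            rt_sigma=float(rng.uniform(3.0, 6.0)),
            height=float(10 ** rng.uniform(3.7, 5.7)),
            isotope_partner=bool(rng.random() < 0.7),
            isotope_abundance=float(rng.uniform(0.08, 0.3)),
        )
        for i in range(n_peaks)
    ]


@pytest.fixture(scope="session")
def planted_peaks():
    return make_peak_set(seed=11)


@pytest.fixture(scope="session")
def noisy_run(planted_peaks):
    return simulate_run(
        planted_peaks,
        NoiseModel(baseline=60, sd=25, spike_rate=8),
        rt_grid=(0.0, 240.0, 1.0),
        mz_jitter_ppm=3.0,
        seed=1,
    )


@pytest.fixture
def permissive_params():
    return PickerParams(
        ppm=20,
        peakwidth_min=5,
        peakwidth_max=40,
        mzdiff=0.01,
        snthresh=3,
        noise=150,
        prefilter_k=3,
        prefilter_i=150,
        bw=5,
    )
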