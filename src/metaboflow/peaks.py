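"""CentWave-style chromatographic peak detection, grouping and annotation.

The detector chains centroids into m/z traces within a ppm tolerance, locates
apexes on smoothed extracted-ion chromatograms, delimits peak bounds at
valleys or baseline, filters on width and signal-to-noise, merges peaks
closer than ``mzdiff``, and scores each peak's Gaussian shape.  Peaks from
multiple samples are grouped by kernel density over retention time within
narrow m/z slices, aligned with a LOESS retention-time model, and annotated
with isotope flags.  The module exposes the exact parameter vector the
optimizer searches over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .simulate import C13_C12_DELTA
from .spectra import SpectraRun

__all__ = [
    "PickerParams",
    "ChromPeak",
    "Feature",
    "FeatureSet",
    "estimate_noise_and_ppm",
    "pick_peaks",
    "score_gaussian",
    "group_and_align",
    "detect_isotopes",
]

GAUSS_COR_CUTOFF = 0.9
GAUSS_P_CUTOFF = 0.05
LIP_PERCENTILE = 0.03  # lowest 3% of feature intensities define the LIP threshold


@dataclass(frozen=True)
class PickerParams:
    """The optimizable peak-picking parameter vector."""

    ppm: float = 20.0
    peakwidth_min: float = 5.0
    peakwidth_max: float = 40.0
    mzdiff: float = 0.01
    snthresh: float = 6.0
    noise: float = 100.0
    prefilter_k: int = 3
    prefilter_i: float = 100.0
    bw: float = 5.0
    minfrac: float = 0.5

    def __post_init__(self) -> None:
        if self.peakwidth_min >= self.peakwidth_max:
            raise ValueError("peakwidth_min must be < peakwidth_max")
        for name in ("ppm", "mzdiff", "bw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        """Plain-python mapping of field names to values (for YAML/JSON)."""
        out = {}
        for k, v in self.__dict__.items():
            out[k] = int(v) if k == "prefilter_k" else float(v)
        return out


@dataclass
class ChromPeak:
    """One detected chromatographic peak in one sample."""

    mz: float
    mzmin: float
    mzmax: float
    rt: float
    rtmin: float
    rtmax: float
    area: float
    apex_height: float
    sn: float
    sample: int = 0
    gauss_cor: float = 0.0
    gauss_p: float = 1.0


@dataclass
class Feature:
    """A cross-sample feature: one consensus (m/z, RT) with member peaks."""

    mz: float
    rt: float
    members: dict[int, ChromPeak] = field(default_factory=dict)
    has_isotope: bool = False
    low_intensity_isotope: bool = False
    had_duplicates: bool = False

    @property
    def mean_intensity(self) -> float:
        if not self.members:
            return 0.0
        return float(np.mean([p.area for p in self.members.values()]))

    @property
    def representative(self) -> ChromPeak:
        return max(self.members.values(), key=lambda p: p.apex_height)

    @property
    def gauss_cor(self) -> float:
        return self.representative.gauss_cor

    @property
    def gauss_p(self) -> float:
        return self.representative.gauss_p

    @property
    def is_gaussian(self) -> bool:
        return self.gauss_cor >= GAUSS_COR_CUTOFF and self.gauss_p <= GAUSS_P_CUTOFF

    def intensity_row(self, n_samples: int) -> np.ndarray:
        row = np.full(n_samples, np.nan)
        for s, p in self.members.items():
            row[s] = p.area
        return row


@dataclass
class FeatureSet:
    """Grouped features plus alignment/grouping quality scores."""

    features: list[Feature]
    n_samples: int
    rcs: float = 1.0  # retention-time correction score, 1/(1 + mean |residual|)
    gs: float = 0.0  # grouping score, good^2/(bad + 1)

    def intensity_matrix(self) -> np.ndarray:
        if not self.features:
            return np.empty((0, self.n_samples))
        return np.vstack([f.intensity_row(self.n_samples) for f in self.features])


# ---------------------------------------------------------------------------
# noise / ppm estimation (kernel-density split of the log-intensity mixture)
# ---------------------------------------------------------------------------

def estimate_noise_and_ppm(run: SpectraRun) -> tuple[float, int, float, float]:
    """Estimate (noise, prefilter_k, prefilter_i, ppm) from the run itself.

    The noise floor is placed at the first antimode of a kernel density
    estimate of log10 centroid intensities, separating the noise mode from
    the signal mode.  ``prefilter_k`` is the modal consecutive-scan length of
    above-noise m/z traces and ``ppm`` the 95th percentile of within-trace
    deviations from each trace's intensity-weighted mean m/z.
    """
    if not run.scans:
        raise ValueError("cannot estimate parameters from an empty run")
    _, mz, inten = run.flatten()
    pos = inten[inten > 0]
    if pos.size < 10:
        raise ValueError("too few centroids to estimate noise")
    logi = np.log10(pos)
    noise = None
    if np.ptp(logi) > 1e-9 and pos.size >= 30:
        kde = stats.gaussian_kde(logi)
        grid = np.linspace(logi.min(), logi.max(), 512)
        dens = kde(grid)
        interior = np.arange(1, grid.size - 1)
        maxima = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
        if maxima.size >= 2:
            # noise mode = the dominant mode; antimode = density minimum
            # between it and the highest mode above it
            noise_mode = maxima[int(np.argmax(dens[maxima]))]
            upper = maxima[(maxima > noise_mode) & (dens[maxima] >= 0.02 * dens[noise_mode])]
            if upper.size:
                signal_mode = upper[int(np.argmax(dens[upper]))]
                antimode = noise_mode + int(np.argmin(dens[noise_mode : signal_mode + 1]))
                if antimode not in (noise_mode, signal_mode):
                    noise = float(10 ** grid[antimode])
    if noise is None:
        warnings.warn("log-intensity density is unimodal; falling back to 3x median intensity")
        noise = float(3.0 * np.median(pos))

    # traces above noise: chain centroids by m/z proximity
    traces = _build_traces(run, ppm=30.0)
    run_lengths: list[int] = []
    ppm_devs: list[float] = []
    for tr in traces:
        t_int = tr["intensity"]
        above = t_int >= noise
        if not above.any():
            continue
        # longest run of consecutive above-noise scans
        best = cur = 0
        prev_scan = None
        for s, ok in zip(tr["scan"], above):
            if ok and prev_scan is not None and s == prev_scan + 1:
                cur += 1
            elif ok:
                cur = 1
            else:
                cur = 0
            best = max(best, cur)
            prev_scan = s
        if best >= 2:
            run_lengths.append(best)
        w = t_int / t_int.sum()
        center = float(np.sum(w * tr["mz"]))
        if center > 0 and tr["mz"].size >= 2:
            ppm_devs.extend(np.abs(tr["mz"] - center) / center * 1e6)
    if run_lengths:
        values, counts = np.unique(run_lengths, return_counts=True)
        prefilter_k = int(values[np.argmax(counts)])
    else:
        prefilter_k = 3
    prefilter_k = int(np.clip(prefilter_k, 2, 10))
    ppm = float(np.percentile(ppm_devs, 95)) if ppm_devs else 0.0
    ppm = max(ppm, 1.0)  # instrument floor
    return noise, prefilter_k, noise, ppm


# ---------------------------------------------------------------------------
# trace building and peak detection
# ---------------------------------------------------------------------------

def _build_traces(run: SpectraRun, ppm: float) -> list[dict]:
    """Chain centroids into m/z traces: split sorted m/z at gaps > ppm tolerance."""
    parts_mz, parts_int, parts_scan = [], [], []
    for i, scan in enumerate(run.scans):
        if scan.mz.size:
            parts_mz.append(scan.mz)
            parts_int.append(scan.intensity)
            parts_scan.append(np.full(scan.mz.size, i, dtype=np.int64))
    if not parts_mz:
        return []
    mz = np.concatenate(parts_mz)
    inten = np.concatenate(parts_int)
    scan_idx = np.concatenate(parts_scan)
    order = np.argsort(mz, kind="stable")
    mz, inten, scan_idx = mz[order], inten[order], scan_idx[order]
    gaps = np.diff(mz)
    tol = mz[:-1] * ppm * 1e-6
    breaks = np.flatnonzero(gaps > tol) + 1
    traces = []
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, mz.size]):
        traces.append({"mz": mz[lo:hi], "intensity": inten[lo:hi], "scan": scan_idx[lo:hi]})
    return traces


def _longest_consecutive_above(eic: np.ndarray, threshold: float) -> int:
    above = eic >= threshold
    best = cur = 0
    for ok in above:
        cur = cur + 1 if ok else 0
        best = max(best, cur)
    return best


def _delimit(eic_s: np.ndarray, apex: int, floor: float) -> tuple[int, int]:
    """Walk from a smoothed-EIC apex to the valleys or baseline on each side."""
    n = eic_s.size
    lo = apex
    while lo > 0 and eic_s[lo - 1] < eic_s[lo] and eic_s[lo - 1] > floor:
        lo -= 1
    while lo > 0 and eic_s[lo - 1] <= eic_s[lo] and eic_s[lo] > floor:
        lo -= 1
    hi = apex
    while hi < n - 1 and eic_s[hi + 1] < eic_s[hi] and eic_s[hi + 1] > floor:
        hi += 1
    while hi < n - 1 and eic_s[hi + 1] <= eic_s[hi] and eic_s[hi] > floor:
        hi += 1
    return lo, hi


def pick_peaks(run: SpectraRun, params: PickerParams) -> list[ChromPeak]:
    """Detect chromatographic peaks in a centroided MS1 run.

    Deterministic; an empty list is a valid result.
    """
    rts = run.rts
    if rts.size == 0:
        return []
    dt = float(np.median(np.diff(rts))) if rts.size > 1 else 1.0
    if dt <= 0:
        dt = 1.0
    peaks: list[ChromPeak] = []
    min_pts = max(int(np.ceil(params.peakwidth_min / dt)) // 2 + 1, 3)
    for tr in _build_traces(run, params.ppm):
        if tr["mz"].size < max(params.prefilter_k, min_pts):
            continue
        eic = np.zeros(rts.size)
        np.add.at(eic, tr["scan"], tr["intensity"])
        if eic.max() < params.noise:
            continue
        if _longest_consecutive_above(eic, params.prefilter_i) < params.prefilter_k:
            continue
        eic_s = gaussian_filter1d(eic, sigma=max(1.0, 1.5 / dt))
        apexes, _ = find_peaks(eic_s, height=max(params.noise, params.prefilter_i) * 0.5)
        for apex in apexes:
            # bounds at valleys or at 5% of apex height (~4.9 sigma full width
            # for an isolated Gaussian), whichever comes first
            floor = max(0.05 * eic_s[apex], 0.5 * params.noise)
            lo, hi = _delimit(eic_s, apex, floor)
            if hi - lo < 2:
                continue
            width = rts[hi] - rts[lo]
            if not (params.peakwidth_min <= width <= params.peakwidth_max):
                continue
            raw_apex = int(lo + np.argmax(eic[lo : hi + 1]))
            apex_height = float(eic[raw_apex])
            baseline = float(min(eic[lo], eic[hi]))
            off = np.r_[eic[:lo], eic[hi + 1 :]]
            off = off[off > 0]
            noise_local = float(np.median(off)) if off.size >= 3 else max(params.noise, 1.0)
            noise_local = max(noise_local, 1.0)
            sn = (apex_height - baseline) / noise_local
            if sn < params.snthresh:
                continue
            in_peak = (tr["scan"] >= lo) & (tr["scan"] <= hi)
            if not in_peak.any():
                continue
            w = tr["intensity"][in_peak]
            mzs = tr["mz"][in_peak]
            mz_mean = float(np.sum(w * mzs) / w.sum())
            area = float(np.trapezoid(eic[lo : hi + 1], rts[lo : hi + 1]))
            cor, p = score_gaussian(list(zip(rts[lo : hi + 1], eic[lo : hi + 1])))
            peaks.append(
                ChromPeak(
                    mz=mz_mean,
                    mzmin=float(mzs.min()),
                    mzmax=float(mzs.max()),
                    rt=float(rts[raw_apex]),
                    rtmin=float(rts[lo]),
                    rtmax=float(rts[hi]),
                    area=area,
                    apex_height=apex_height,
                    sn=float(sn),
                    gauss_cor=cor,
                    gauss_p=p,
                )
            )
    return _merge_close(peaks, params.mzdiff)


def _merge_close(peaks: list[ChromPeak], mzdiff: float) -> list[ChromPeak]:
    """Merge peaks closer than ``mzdiff`` in m/z with overlapping RT ranges."""
    if len(peaks) < 2:
        return peaks
    peaks = sorted(peaks, key=lambda p: (p.mz, p.rt))
    merged: list[ChromPeak] = []
    for p in peaks:
        target = None
        for q in reversed(merged):
            if p.mz - q.mz >= mzdiff:
                break
            if p.rtmin <= q.rtmax and q.rtmin <= p.rtmax:
                target = q
                break
        if target is None:
            merged.append(replace(p))
        else:
            total = target.area + p.area
            target.mz = (target.mz * target.area + p.mz * p.area) / total if total > 0 else target.mz
            target.mzmin = min(target.mzmin, p.mzmin)
            target.mzmax = max(target.mzmax, p.mzmax)
            target.rtmin = min(target.rtmin, p.rtmin)
            target.rtmax = max(target.rtmax, p.rtmax)
            if p.apex_height > target.apex_height:
                target.rt = p.rt
                target.apex_height = p.apex_height
                target.gauss_cor, target.gauss_p = p.gauss_cor, p.gauss_p
            target.area = total
            target.sn = max(target.sn, p.sn)
    return merged


def _gauss(t, h, mu, sigma):
    return h * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def score_gaussian(eic: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Fit a Gaussian to an EIC and report (Pearson cor, correlation-test p).

    Returns ``(0, 1)`` when the fit does not converge or the trace is
    degenerate.  Requires at least 4 points.
    """
    arr = np.asarray(eic, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 4:
        raise ValueError("score_gaussian needs at least 4 (rt, intensity) points")
    t, y = arr[:, 0], arr[:, 1]
    if np.ptp(y) <= 0:
        return 0.0, 1.0
    h0 = float(y.max())
    mu0 = float(t[np.argmax(y)])
    sigma0 = max(float(np.ptp(t)) / 4.0, 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss,
                t,
                y,
                p0=(h0, mu0, sigma0),
                maxfev=400,
            )
    except Exception:
        return 0.0, 1.0
    fitted = _gauss(t, *popt)
    if np.ptp(fitted) <= 1e-12 or not np.all(np.isfinite(fitted)):
        return 0.0, 1.0
    r = float(np.corrcoef(fitted, y)[0, 1])
    if not np.isfinite(r):
        return 0.0, 1.0
    n = t.size
    dof = n - 1
    r_clipped = min(abs(r), 1.0 - 1e-12)
    t_stat = r_clipped * np.sqrt(dof / (1.0 - r_clipped**2))
    p = float(2.0 * stats.t.sf(t_stat, dof))
    return r, p


# ---------------------------------------------------------------------------
# cross-sample grouping and alignment
# ---------------------------------------------------------------------------

def _density_maxima(rts: np.ndarray, bw: float) -> np.ndarray:
    """RT positions of local maxima of a Gaussian kernel density."""
    lo, hi = rts.min() - 3 * bw, rts.max() + 3 * bw
    grid = np.linspace(lo, hi, max(int((hi - lo) / (bw / 4)), 8) + 1)
    dens = np.exp(-((grid[:, None] - rts[None, :]) ** 2) / (2 * bw**2)).sum(axis=1)
    interior = np.arange(1, grid.size - 1)
    peaks = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if peaks.size == 0:
        return np.array([float(np.median(rts))])
    return grid[peaks]


def group_and_align(
    peaks_by_sample: Sequence[Sequence[ChromPeak]],
    params: PickerParams,
) -> FeatureSet:
    """Group peaks across samples into features and LOESS-align retention times.

    Within m/z slices of width ``max(mzdiff, 2*ppm*mz)`` a kernel density over
    RT (bandwidth ``bw``) defines feature centers; each center claims its
    nearest peaks, at most one per sample (most intense wins).  Well-behaved
    groups (>= ``minfrac`` of samples, one peak each) anchor a per-sample
    LOESS model of RT deviation; ``rcs`` summarises post-alignment residuals
    and ``gs = good^2 / (bad + 1)`` the grouping quality.
    """
    n_samples = len(peaks_by_sample)
    if n_samples < 1:
        raise ValueError("need at least one sample")
    tagged: list[ChromPeak] = []
    for s, plist in enumerate(peaks_by_sample):
        for p in plist:
            q = replace(p)
            q.sample = s
            tagged.append(q)
    if not tagged:
        return FeatureSet(features=[], n_samples=n_samples, rcs=1.0, gs=0.0)
    tagged.sort(key=lambda p: p.mz)
    mzs = np.array([p.mz for p in tagged])
    slice_breaks = [0]
    for i in range(1, len(tagged)):
        tol = max(params.mzdiff, 2 * params.ppm * 1e-6 * mzs[i - 1])
        if mzs[i] - mzs[i - 1] > tol:
            slice_breaks.append(i)
    slice_breaks.append(len(tagged))

    features: list[Feature] = []
    for lo, hi in zip(slice_breaks[:-1], slice_breaks[1:]):
        members = tagged[lo:hi]
        rts = np.array([p.rt for p in members])
        centers = _density_maxima(rts, params.bw)
        assignment = np.argmin(np.abs(rts[:, None] - centers[None, :]), axis=1)
        for ci in range(centers.size):
            claimed = [p for p, a in zip(members, assignment) if a == ci]
            if not claimed:
                continue
            by_sample: dict[int, ChromPeak] = {}
            dup = False
            for p in claimed:
                if p.sample in by_sample:
                    dup = True
                    if p.apex_height > by_sample[p.sample].apex_height:
                        by_sample[p.sample] = p
                else:
                    by_sample[p.sample] = p
            f = Feature(
                mz=float(np.median([p.mz for p in by_sample.values()])),
                rt=float(np.median([p.rt for p in by_sample.values()])),
                members=by_sample,
                had_duplicates=dup,
            )
            features.append(f)

    # a well-behaved group spans >= minfrac of samples (and, with several
    # samples, at least two — a singleton cannot inform alignment)
    min_members = max(params.minfrac * n_samples, 2 if n_samples > 1 else 1)
    good_features = [
        f
        for f in features
        if not f.had_duplicates and len(f.members) >= min_members
    ]
    good = len(good_features)
    bad = len(features) - good
    gs = good**2 / (bad + 1)

    # LOESS alignment per sample on well-behaved groups
    if good >= 1 and n_samples > 1:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        for s in range(n_samples):
            pts = [
                (f.rt, f.members[s].rt - f.rt)
                for f in good_features
                if s in f.members
            ]
            if not pts:
                continue
            pts.sort()
            x = np.array([p[0] for p in pts])
            d = np.array([p[1] for p in pts])
            if len(pts) >= 4 and np.ptp(x) > 0:
                fit = lowess(d, x, frac=2 / 3, return_sorted=True)
                xf, df_ = fit[:, 0], fit[:, 1]
            else:
                xf, df_ = x, np.full_like(x, float(np.median(d)))
            for f in features:
                if s in f.members:
                    shift = float(np.interp(f.members[s].rt, xf, df_))
                    f.members[s].rt -= shift
        for f in features:
            f.rt = float(np.median([p.rt for p in f.members.values()]))

    if good_features:
        residuals = [
            abs(p.rt - f.rt)
            for f in good_features
            for p in f.members.values()
        ]
        rcs = 1.0 / (1.0 + float(np.mean(residuals)))
    else:
        rcs = 1.0 if n_samples == 1 else 0.0
    return FeatureSet(features=features, n_samples=n_samples, rcs=rcs, gs=float(gs))


# ---------------------------------------------------------------------------
# isotope annotation
# ---------------------------------------------------------------------------

def lip_threshold(intensities) -> float:
    """Mean of the lowest 3% of feature intensities (low-intensity cutoff)."""
    arr = np.sort(np.asarray(intensities, dtype=np.float64))
    if arr.size == 0:
        raise ValueError("no intensities")
    n_low = max(int(np.ceil(LIP_PERCENTILE * arr.size)), 1)
    return float(arr[:n_low].mean())


def detect_isotopes(
    fs: FeatureSet,
    ppm: float = 20.0,
    rt_tol: float = 3.0,
    ratio_max: float = 0.6,
) -> FeatureSet:
    """Flag features with a detectable isotopologue partner (in place).

    Feature A has an isotope when another feature sits at
    ``A.mz + 1.003355/z`` (z in {1, 2}) within the ppm tolerance, co-elutes
    within ``rt_tol`` seconds, and has an intensity ratio in (0, ``ratio_max``].
    The partner is a low-intensity isotope when its mean intensity falls
    below the mean of the lowest 3% of all feature intensities.
    """
    feats = fs.features
    if not feats:
        return fs
    intensities = np.array([f.mean_intensity for f in feats])
    lip_cutoff = lip_threshold(intensities)
    order = np.argsort([f.mz for f in feats])
    mz_sorted = np.array([feats[i].mz for i in order])
    for f in feats:
        f.has_isotope = False
        f.low_intensity_isotope = False
        for z in (1, 2):
            target = f.mz + C13_C12_DELTA / z
            tol = target * ppm * 1e-6
            lo = int(np.searchsorted(mz_sorted, target - tol, side="left"))
            hi = int(np.searchsorted(mz_sorted, target + tol, side="right"))
            for j in order[lo:hi]:
                g = feats[j]
                if g is f or abs(g.rt - f.rt) > rt_tol:
                    continue
                base = f.mean_intensity
                if base <= 0:
                    continue
                ratio = g.mean_intensity / base
                if 0 < ratio <= ratio_max:
                    f.has_isotope = True
                    if g.mean_intensity < lip_cutoff:
                        f.low_intensity_isotope = True
                    break
            if f.has_isotope:
                break
    return fs
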