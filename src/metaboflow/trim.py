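"""Region-of-interest selection and spectra trimming.

The default "standards simulation" strategy (``ssm``) divides the m/z range
into equal bins, slides an m/z window within each bin to find the window with
the highest summed centroid intensity, slides a single RT window across the
whole run the same way, and intersects the two.  The resulting ROIs are
enriched for genuine chromatographic peaks and serve as a small synthetic
surrogate of the full run for parameter optimization.  Targeted modes extract
or remove points near user-specified m/z or RT values instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra import CentroidScan, EmptyRunError, SpectraRun

__all__ = ["ROIWindow", "TrimSpec", "select_rois", "trim_run"]

# sliding-window step as a fraction of the window width
_STEP_FRACTION = 0.1


@dataclass(frozen=True)
class ROIWindow:
    """An m/z x RT window with its summed signal intensity."""

    mz_lo: float
    mz_hi: float
    rt_lo: float
    rt_hi: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mz_lo < self.mz_hi and self.rt_lo < self.rt_hi):
            raise ValueError("window bounds must be ordered")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    def contains(self, mz: np.ndarray, rt: float) -> np.ndarray:
        inside_rt = self.rt_lo <= rt <= self.rt_hi
        if not inside_rt:
            return np.zeros(mz.shape, dtype=bool)
        return (mz >= self.mz_lo) & (mz <= self.mz_hi)


@dataclass
class TrimSpec:
    """Trimming strategy and its knobs.

    ``targets`` are (value, tolerance) pairs: tolerance in ppm for
    ``mz_specific`` and in seconds for ``rt_specific``.
    """

    strategy: str = "ssm"
    n_bins: int = 4
    mz_window_fraction: float = 0.25
    rt_fraction: float = 0.25
    targets: list[tuple[float, float]] = field(default_factory=list)
    keep: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in {"ssm", "mz_specific", "rt_specific"}:
            raise ValueError(f"unknown trimming strategy {self.strategy!r}")
        if not (0 < self.rt_fraction <= 1):
            raise ValueError("rt_fraction must be in (0, 1]")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not (0 < self.mz_window_fraction <= 1):
            raise ValueError("mz_window_fraction must be in (0, 1]")


def _best_window(
    sorted_pos: np.ndarray,
    sorted_weight: np.ndarray,
    lo: float,
    hi: float,
    width: float,
) -> tuple[float, float, float]:
    """Slide a window of ``width`` over [lo, hi]; return (start, end, best sum).

    Positions must be ascending.  The step is ``width / 10``; ties break
    toward the lower start (first maximum wins).
    """
    csum = np.concatenate([[0.0], np.cumsum(sorted_weight)])
    step = width * _STEP_FRACTION
    if hi - lo <= width:
        starts = np.array([lo])
    else:
        starts = np.arange(lo, hi - width + step / 2, step)
    left = np.searchsorted(sorted_pos, starts, side="left")
    right = np.searchsorted(sorted_pos, starts + width, side="right")
    sums = csum[right] - csum[left]
    best = int(np.argmax(sums))  # argmax returns the first maximum: low-side tie break
    return float(starts[best]), float(starts[best] + width), float(sums[best])


def select_rois(run: SpectraRun, spec: TrimSpec) -> list[ROIWindow]:
    """Select one maximal-intensity ROI per m/z bin (``ssm`` strategy)."""
    if spec.strategy != "ssm":
        raise ValueError("select_rois applies to the ssm strategy only")
    if not run.scans:
        raise EmptyRunError("cannot select ROIs from an empty run")
    rt, mz, inten = run.flatten()
    if mz.size == 0:
        raise EmptyRunError("run contains no centroids")

    # single global RT window with the highest summed intensity
    rt_lo_all, rt_hi_all = float(run.scans[0].rt), float(run.scans[-1].rt)
    rt_span = rt_hi_all - rt_lo_all
    rt_width = rt_span * spec.rt_fraction
    scan_rts = run.rts
    if rt_span <= 0 or np.sum((scan_rts >= rt_lo_all) & (scan_rts <= rt_lo_all + rt_width)) < 2:
        raise ValueError(
            "run is too short for the requested RT window; increase rt_fraction"
        )
    order_rt = np.argsort(rt, kind="stable")
    rt_lo, rt_hi, _ = _best_window(rt[order_rt], inten[order_rt], rt_lo_all, rt_hi_all, rt_width)

    # per-bin m/z windows
    order_mz = np.argsort(mz, kind="stable")
    mz_sorted, inten_by_mz, rt_by_mz = mz[order_mz], inten[order_mz], rt[order_mz]
    mz_min, mz_max = float(mz_sorted[0]), float(mz_sorted[-1])
    if mz_max <= mz_min:
        mz_max = mz_min + 1.0
    edges = np.linspace(mz_min, mz_max, spec.n_bins + 1)
    rois: list[ROIWindow] = []
    for b in range(spec.n_bins):
        lo_e, hi_e = float(edges[b]), float(edges[b + 1])
        width = (hi_e - lo_e) * spec.mz_window_fraction
        sel = slice(
            int(np.searchsorted(mz_sorted, lo_e, side="left")),
            int(np.searchsorted(mz_sorted, hi_e, side="right")),
        )
        w_lo, w_hi, _ = _best_window(mz_sorted[sel], inten_by_mz[sel], lo_e, hi_e, width)
        inside = (
            (mz_sorted >= w_lo)
            & (mz_sorted <= w_hi)
            & (rt_by_mz >= rt_lo)
            & (rt_by_mz <= rt_hi)
        )
        rois.append(
            ROIWindow(
                mz_lo=w_lo,
                mz_hi=w_hi,
                rt_lo=rt_lo,
                rt_hi=rt_hi,
                score=float(inten_by_mz[inside].sum()),
            )
        )
    return rois


def _target_regions(run: SpectraRun, spec: TrimSpec) -> list[ROIWindow]:
    if not spec.targets:
        raise ValueError(f"strategy {spec.strategy!r} requires non-empty targets")
    rt_lo, rt_hi = float(run.scans[0].rt), float(run.scans[-1].rt) + 1e-9
    _, mz, _ = run.flatten()
    mz_lo_all, mz_hi_all = float(mz.min()) - 1.0, float(mz.max()) + 1.0
    regions = []
    for value, tol in spec.targets:
        if spec.strategy == "mz_specific":
            delta = value * tol * 1e-6  # tolerance given in ppm
            regions.append(ROIWindow(value - delta, value + delta, rt_lo - 1e-9, rt_hi))
        else:  # rt_specific, tolerance in seconds
            regions.append(ROIWindow(mz_lo_all, mz_hi_all, value - tol, value + tol))
    return regions


def trim_run(
    run: SpectraRun,
    spec: TrimSpec,
    rois: Sequence[ROIWindow] | None = None,
) -> SpectraRun:
    """Keep (or remove) the centroids inside the union of regions.

    For ``ssm`` the regions are the ROIs from :func:`select_rois` and the
    output is the synthetic spectrum driving parameter optimization.  Empty
    scans are dropped; the surviving scans keep their original RTs.
    """
    if not run.scans:
        raise EmptyRunError("cannot trim an empty run")
    if spec.strategy == "ssm":
        regions = list(rois) if rois is not None else select_rois(run, spec)
    else:
        regions = _target_regions(run, spec)

    scans: list[CentroidScan] = []
    for scan in run.scans:
        inside = np.zeros(scan.mz.shape, dtype=bool)
        for region in regions:
            inside |= region.contains(scan.mz, scan.rt)
        mask = inside if spec.keep else ~inside
        if mask.any():
            scans.append(
                CentroidScan(
                    rt=scan.rt,
                    mz=scan.mz[mask],
                    intensity=scan.intensity[mask],
                    ms_level=scan.ms_level,
                    polarity=scan.polarity,
                )
            )
    if not scans:
        raise EmptyRunError("trimming removed every centroid")
    meta = dict(run.meta)
    meta["trimmed"] = {"strategy": spec.strategy, "keep": spec.keep, "n_regions": len(regions)}
    return SpectraRun(scans=scans, sample_id=run.sample_id, meta=meta)
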