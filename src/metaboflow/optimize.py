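"""Box–Behnken design optimization of peak-picking parameters.

The response variable is the Quality Score

    QS = RP^1.5 / (all_peaks - LIP) * GR^2 * QcoE

where RP counts features with a detectable isotope (reliable peaks), LIP the
reliable peaks whose isotope intensity is below the mean of the lowest 3% of
feature intensities, GR the fraction of features with Gaussian peak shape
(cor >= 0.9, p <= 0.05), and QcoE a weighted, min–max-normalized combination
of the retention-time correction score, the grouping score, and the inverted
coefficient of variation (weights 0.4 / 0.4 / 0.2).  The exponent 1.5 damps
sensitivity to raw peak counts (noise inflation); the exponent 2 emphasises
peak shape.

Noise, prefilter and ppm are fixed up front from the data by the
kernel-density estimator; the remaining five factors (peak width min/max,
mzdiff, s/n threshold, grouping bandwidth) are searched with a Box–Behnken
design whose fitted quadratic response surface recenters each round.
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .peaks import (
    FeatureSet,
    PickerParams,
    detect_isotopes,
    estimate_noise_and_ppm,
    group_and_align,
    pick_peaks,
)
from .spectra import SpectraRun

__all__ = [
    "OptimizationScore",
    "DoEDesign",
    "OptimizationResult",
    "qcoe_weighted",
    "compute_quality_score",
    "score_round",
    "build_bbd_design",
    "fit_response_surface",
    "optimize_params",
    "platform_defaults",
    "PLATFORM_REGISTRY",
]

RP_EXPONENT = 1.5
GR_EXPONENT = 2.0
QCOE_WEIGHTS = (0.4, 0.4, 0.2)  # RCS, GS, inverted CV

DOE_FACTORS = ("peakwidth_min", "peakwidth_max", "mzdiff", "snthresh", "bw")


@dataclass
class OptimizationScore:
    """All components of one Quality Score evaluation."""

    qs: float
    rp: int
    lip: int
    all_peaks: int
    gr: float
    qcoe: float
    rcs_raw: float
    gs_raw: float
    cv_raw: float


@dataclass
class DoEDesign:
    factors: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    coded: np.ndarray  # runs x k in {-1, 0, +1}
    natural: list[dict[str, float]]
    notes: list[str] = field(default_factory=list)


@dataclass
class OptimizationResult:
    best_params: PickerParams
    best_score: OptimizationScore
    history: list[dict]
    converged: bool


def qcoe_weighted(norm_rcs: float, norm_gs: float, norm_inv_cv: float) -> float:
    """The weighted three-component combination inside QcoE (0.4/0.4/0.2)."""
    w_rcs, w_gs, w_cv = QCOE_WEIGHTS
    return w_rcs * norm_rcs + w_gs * norm_gs + w_cv * norm_inv_cv


def _unit_norm(value: float, bounds: tuple[float, float] | None) -> float:
    """Min–max normalization; a degenerate span contributes a neutral 0.5."""
    if bounds is None:
        return 0.5
    lo, hi = bounds
    if not np.isfinite(lo) or not np.isfinite(hi) or hi - lo <= 1e-12:
        return 0.5
    return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))


def median_feature_cv(
    fs: FeatureSet, replicate_groups: Sequence[str] | None = None
) -> float:
    """Median across features of the mean within-replicate-group CV."""
    mat = fs.intensity_matrix()
    if mat.size == 0:
        return 0.0
    if replicate_groups is None:
        replicate_groups = ["all"] * fs.n_samples
    groups = {}
    for idx, g in enumerate(replicate_groups):
        groups.setdefault(g, []).append(idx)
    cvs = []
    for row in mat:
        per_group = []
        for cols in groups.values():
            vals = row[cols]
            vals = vals[np.isfinite(vals)]
            if vals.size >= 2 and vals.mean() > 0:
                per_group.append(vals.std(ddof=1) / vals.mean())
        if per_group:
            cvs.append(np.mean(per_group))
    return float(np.median(cvs)) if cvs else 0.0


def compute_quality_score(
    fs: FeatureSet,
    replicate_groups: Sequence[str] | None = None,
    norm_context: Mapping[str, tuple[float, float]] | None = None,
) -> OptimizationScore:
    """Score one picking run.

    ``norm_context`` supplies the (min, max) of the raw RCS, GS and inverted
    CV across the cohort being compared (a design round); a missing or
    degenerate entry makes that component contribute neutrally (0.5).
    """
    all_peaks = len(fs.features)
    rp = sum(f.has_isotope for f in fs.features)
    lip = sum(f.low_intensity_isotope for f in fs.features)
    gaussian = sum(f.is_gaussian for f in fs.features)
    gr = gaussian / all_peaks if all_peaks else 0.0
    cv_raw = median_feature_cv(fs, replicate_groups)
    ctx = norm_context or {}
    n_rcs = _unit_norm(fs.rcs, ctx.get("rcs"))
    n_gs = _unit_norm(fs.gs, ctx.get("gs"))
    n_inv_cv = _unit_norm(1.0 - cv_raw, ctx.get("inv_cv"))
    qcoe = qcoe_weighted(n_rcs, n_gs, n_inv_cv)
    if all_peaks == 0 or all_peaks <= lip:
        qs = 0.0
    else:
        qs = rp**RP_EXPONENT / (all_peaks - lip) * gr**GR_EXPONENT * qcoe
    return OptimizationScore(
        qs=float(qs),
        rp=rp,
        lip=lip,
        all_peaks=all_peaks,
        gr=gr,
        qcoe=qcoe,
        rcs_raw=fs.rcs,
        gs_raw=fs.gs,
        cv_raw=cv_raw,
    )


def score_round(
    feature_sets: Sequence[FeatureSet],
    replicate_groups: Sequence[str] | None = None,
) -> list[OptimizationScore]:
    """Score a cohort of evaluations with round-level normalization.

    RCS, GS and inverted CV are min–max normalized over the round, and the
    weighted QcoE is itself rescaled to [0, 1] over the round before entering
    the Quality Score.
    """
    raw = [
        (fs.rcs, fs.gs, 1.0 - median_feature_cv(fs, replicate_groups))
        for fs in feature_sets
    ]
    arr = np.asarray(raw)
    ctx = {
        "rcs": (float(arr[:, 0].min()), float(arr[:, 0].max())),
        "gs": (float(arr[:, 1].min()), float(arr[:, 1].max())),
        "inv_cv": (float(arr[:, 2].min()), float(arr[:, 2].max())),
    }
    scores = [
        compute_quality_score(fs, replicate_groups, norm_context=ctx)
        for fs in feature_sets
    ]
    qcoes = np.array([s.qcoe for s in scores])
    span = qcoes.max() - qcoes.min()
    for s in scores:
        rescaled = (s.qcoe - qcoes.min()) / span if span > 1e-12 else 0.5
        s.qcoe = float(rescaled)
        if s.all_peaks == 0 or s.all_peaks <= s.lip:
            s.qs = 0.0
        else:
            s.qs = float(
                s.rp**RP_EXPONENT / (s.all_peaks - s.lip) * s.gr**GR_EXPONENT * s.qcoe
            )
    return scores


# ---------------------------------------------------------------------------
# Box–Behnken design
# ---------------------------------------------------------------------------

def build_bbd_design(
    ranges: Mapping[str, tuple[float, float]],
    n_center: int = 6,
) -> DoEDesign:
    """Standard Box–Behnken design for the five DoE factors.

    For k = 5 this yields the 40 edge runs (every factor pair at the four
    (+-1, +-1) combinations, all other factors at 0) plus ``n_center``
    center replicates.  Decoded rows where peakwidth_min >= peakwidth_max
    are repaired by swapping, with a note.
    """
    factors = tuple(DOE_FACTORS)
    if set(ranges) != set(factors):
        raise ValueError(f"ranges must cover exactly {factors}")
    for name, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
    k = len(factors)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        for a, b in itertools.product((-1.0, 1.0), repeat=2):
            row = np.zeros(k)
            row[i], row[j] = a, b
            rows.append(row)
    rows.extend(np.zeros(k) for _ in range(n_center))
    coded = np.vstack(rows)
    mids = {f: (ranges[f][0] + ranges[f][1]) / 2 for f in factors}
    halfs = {f: (ranges[f][1] - ranges[f][0]) / 2 for f in factors}
    natural = []
    notes: list[str] = []
    for r, row in enumerate(coded):
        point = {f: mids[f] + row[i] * halfs[f] for i, f in enumerate(factors)}
        if point["peakwidth_min"] >= point["peakwidth_max"]:
            point["peakwidth_min"], point["peakwidth_max"] = (
                point["peakwidth_max"],
                point["peakwidth_min"],
            )
            if point["peakwidth_min"] >= point["peakwidth_max"]:
                point["peakwidth_max"] = point["peakwidth_min"] * 1.5 + 1.0
            notes.append(f"run {r}: repaired peakwidth ordering by swap")
        natural.append(point)
    return DoEDesign(factors=factors, ranges=dict(ranges), coded=coded, natural=natural, notes=notes)


def _quad_terms(x: np.ndarray) -> np.ndarray:
    """Full quadratic model terms for coded points (n x k)."""
    n, k = x.shape
    cols = [np.ones(n)]
    cols.extend(x[:, i] for i in range(k))
    cols.extend(x[:, i] * x[:, j] for i, j in itertools.combinations(range(k), 2))
    cols.extend(x[:, i] ** 2 for i in range(k))
    return np.column_stack(cols)


def fit_response_surface(
    design: DoEDesign, responses: Sequence[float]
) -> tuple[np.ndarray, dict[str, float], dict[str, bool]]:
    """Fit the quadratic surface and locate its maximum on the coded cube.

    Returns ``(coefficients, optimum in natural units, on_boundary flags)``.
    All-equal responses yield the center point flagged non-informative on no
    factor.
    """
    y = np.asarray(responses, dtype=np.float64)
    if y.shape[0] != design.coded.shape[0]:
        raise ValueError("one response per design run required")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    k = design.coded.shape[1]
    if np.ptp(y) <= 1e-15:
        coded_opt = np.zeros(k)
        coef = np.zeros(1 + k + k * (k - 1) // 2 + k)
        coef[0] = y[0]
    else:
        X = _quad_terms(design.coded)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)

        def neg_surface(x: np.ndarray) -> float:
            return -float((_quad_terms(x[None, :]) @ coef)[0])

        # coarse deterministic grid on {-1, 0, 1}^k, then local polish;
        # ties broken toward the center so flat factors stay put
        grid = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=k)))
        vals = _quad_terms(grid) @ coef
        near = np.flatnonzero(vals >= vals.max() - 1e-9 * max(abs(vals.max()), 1.0))
        x0 = grid[near[int(np.argmin(np.linalg.norm(grid[near], axis=1)))]]
        res = minimize(
            neg_surface,
            x0,
            method="L-BFGS-B",
            bounds=[(-1.0, 1.0)] * k,
        )
        coded_opt = res.x if res.success else x0
    mids = {f: (design.ranges[f][0] + design.ranges[f][1]) / 2 for f in design.factors}
    halfs = {f: (design.ranges[f][1] - design.ranges[f][0]) / 2 for f in design.factors}
    optimum = {
        f: mids[f] + coded_opt[i] * halfs[f] for i, f in enumerate(design.factors)
    }
    on_boundary = {
        f: bool(abs(coded_opt[i]) > 0.95) for i, f in enumerate(design.factors)
    }
    return coef, optimum, on_boundary


# ---------------------------------------------------------------------------
# the optimization loop
# ---------------------------------------------------------------------------

def _initial_ranges(init: PickerParams) -> dict[str, tuple[float, float]]:
    r = {
        "peakwidth_min": (max(0.5 * init.peakwidth_min, 1.0), 1.8 * init.peakwidth_min),
        "peakwidth_max": (0.6 * init.peakwidth_max, 1.5 * init.peakwidth_max),
        "mzdiff": (0.3 * init.mzdiff, 2.0 * init.mzdiff),
        "snthresh": (max(0.3 * init.snthresh, 1.0), 2.0 * init.snthresh),
        "bw": (max(0.3 * init.bw, 0.5), 2.0 * init.bw),
    }
    return r


def _evaluate(
    runs: Sequence[SpectraRun], params: PickerParams
) -> FeatureSet:
    peaks_by_sample = [pick_peaks(run, params) for run in runs]
    fs = group_and_align(peaks_by_sample, params)
    detect_isotopes(fs, ppm=max(params.ppm, 5.0))
    return fs


def optimize_params(
    trimmed_runs: Sequence[SpectraRun],
    init: PickerParams | None = None,
    max_rounds: int = 6,
    rel_tol: float = 0.05,
    replicate_groups: Sequence[str] | None = None,
) -> OptimizationResult:
    """DoE optimization of the five chromatographic parameters.

    Each round evaluates the Quality Score at every Box–Behnken design point
    (evaluations are independent), fits the quadratic response surface, and
    recenters on its maximum; a factor whose optimum sits on the coded
    boundary has its range shifted/expanded by 50% for the next round.  The
    loop stops when the relative QS improvement falls below ``rel_tol`` or
    after ``max_rounds``; the returned parameters are the best *evaluated*
    point, not the surface prediction.
    """
    if not trimmed_runs:
        raise ValueError("need at least one trimmed run")
    init = init or platform_defaults("generic")

    # fix data-driven parameters first: pooled median across runs
    estimates = [estimate_noise_and_ppm(run) for run in trimmed_runs]
    noise = float(np.median([e[0] for e in estimates]))
    prefilter_k = int(np.clip(round(np.median([e[1] for e in estimates])), 2, 10))
    prefilter_i = float(np.median([e[2] for e in estimates]))
    ppm = float(np.median([e[3] for e in estimates]))
    base = replace(init, noise=noise, prefilter_k=prefilter_k, prefilter_i=prefilter_i, ppm=ppm)

    ranges = _initial_ranges(base)
    best_params = base
    best_score: OptimizationScore | None = None
    history: list[dict] = []
    converged = False
    prev_best_qs = None
    for round_idx in range(max_rounds):
        design = build_bbd_design(ranges)
        extra_points = []
        if round_idx == 0:
            # evaluate the starting point itself so the returned best can
            # never fall below the initial parameters within a round cohort
            extra_points.append(
                {
                    "peakwidth_min": base.peakwidth_min,
                    "peakwidth_max": base.peakwidth_max,
                    "mzdiff": base.mzdiff,
                    "snthresh": base.snthresh,
                    "bw": base.bw,
                }
            )
        fsets, cand_params = [], []
        for point in list(design.natural) + extra_points:
            p = replace(
                base,
                peakwidth_min=point["peakwidth_min"],
                peakwidth_max=point["peakwidth_max"],
                mzdiff=point["mzdiff"],
                snthresh=point["snthresh"],
                bw=point["bw"],
            )
            cand_params.append(p)
            fsets.append(_evaluate(trimmed_runs, p))
        scores = score_round(fsets, replicate_groups)
        qs = np.array([s.qs for s in scores])
        best_idx = int(np.argmax(qs))
        round_best = scores[best_idx]
        if best_score is None or round_best.qs > best_score.qs:
            best_score = round_best
            best_params = cand_params[best_idx]
        design_qs = qs[: len(design.natural)]
        try:
            _, optimum, on_boundary = fit_response_surface(design, design_qs)
        except ValueError:
            optimum = design.natural[int(np.argmax(design_qs))]
            on_boundary = {f: False for f in design.factors}
        history.append(
            {
                "round": round_idx,
                "ranges": dict(ranges),
                "responses": qs.tolist(),
                "best_qs": round_best.qs,
                "surface_optimum": dict(optimum),
                "on_boundary": dict(on_boundary),
                "notes": list(design.notes),
            }
        )
        if prev_best_qs is not None and prev_best_qs > 0:
            rel_improvement = (best_score.qs - prev_best_qs) / prev_best_qs
            if rel_improvement < rel_tol:
                converged = True
                break
        prev_best_qs = best_score.qs
        # recenter ranges on the surface optimum; expand boundary factors by 50%
        new_ranges = {}
        for f in design.factors:
            lo, hi = ranges[f]
            half = (hi - lo) / 2
            center = optimum[f]
            if on_boundary[f]:
                half *= 1.5
            new_lo, new_hi = center - half, center + half
            floor = 0.5 if f.startswith("peakwidth") else 1e-4
            new_lo = max(new_lo, floor)
            if new_hi <= new_lo:
                new_hi = new_lo * 2 + floor
            new_ranges[f] = (new_lo, new_hi)
        ranges = new_ranges
    if best_score is None or best_score.qs <= 0:
        raise ValueError(
            "every design point scored QS = 0; enlarge the ROIs or loosen the "
            "initial parameters"
        )
    return OptimizationResult(
        best_params=best_params,
        best_score=best_score,
        history=history,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# platform starting points
# ---------------------------------------------------------------------------

def _pp(ppm, pwmin, pwmax, mzdiff, sn, noise, pk, pi, bw) -> PickerParams:
    return PickerParams(
        ppm=ppm,
        peakwidth_min=pwmin,
        peakwidth_max=pwmax,
        mzdiff=mzdiff,
        snthresh=sn,
        noise=noise,
        prefilter_k=pk,
        prefilter_i=pi,
        bw=bw,
    )


#: Documented starting parameters per LC-MS platform class.  Orbitraps get
#: tight ppm, TOFs intermediate, ion traps loose; UPLC peaks are narrower
#: than HPLC peaks.  These are starting points for the optimizer, not tuned
#: endpoints.
PLATFORM_REGISTRY: dict[str, PickerParams] = {
    "UPLC-Q/E": _pp(5, 4, 25, 0.01, 6, 1000, 3, 1000, 3),
    "UPLC-Q/TOF": _pp(15, 4, 25, 0.01, 6, 300, 3, 300, 3),
    "UPLC-T/TOF": _pp(15, 4, 25, 0.01, 6, 300, 3, 300, 3),
    "UPLC-Ion_trap": _pp(50, 4, 30, 0.02, 5, 100, 3, 100, 4),
    "UPLC-G2-S": _pp(15, 4, 25, 0.01, 6, 300, 3, 300, 3),
    "HPLC-Q/TOF": _pp(15, 10, 60, 0.01, 6, 300, 3, 300, 6),
    "HPLC-Ion_trap": _pp(50, 10, 60, 0.02, 5, 100, 3, 100, 8),
    "HPLC-Orbitrap": _pp(5, 10, 60, 0.01, 6, 1000, 3, 1000, 6),
    "HPLC-S/Q": _pp(100, 10, 60, 0.05, 5, 100, 3, 100, 8),
    "generic": _pp(25, 5, 50, 0.01, 10, 100, 3, 100, 10),
}


def platform_defaults(name: str) -> PickerParams:
    """Documented starting :class:`PickerParams` for a named platform."""
    try:
        return PLATFORM_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown platform {name!r}; available: {sorted(PLATFORM_REGISTRY)}"
        ) from None
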