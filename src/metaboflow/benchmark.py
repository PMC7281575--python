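"""Evaluation metrics for picked peak tables.

True-peak matching against a reference compound list, consensus
quantification between two groups, dilution-series linearity counting, and
the Gaussian-peak ratio.  These mirror the standard benchmark computations
for comparing peak-picking configurations on ground-truthed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReferenceCompound",
    "match_true_peaks",
    "consensus_quantified",
    "count_linear_peaks",
    "gaussian_peak_ratio",
]

DEFAULT_PPM_TOL = 10.0
DEFAULT_RT_TOL = 18.0  # seconds (0.3 min)
LINEARITY_ALPHA = 0.001


@dataclass(frozen=True)
class ReferenceCompound:
    """A targeted-assay reference with known m/z, RT and group ratio."""

    id: str
    mz: float
    rt: float
    expected_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.rt < 0:
            raise ValueError("mz must be positive and rt non-negative")


def match_true_peaks(
    features: Sequence[tuple[float, float]],
    reference: Sequence[ReferenceCompound],
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
) -> tuple[dict[str, int], list[str]]:
    """One-to-one greedy matching of features to reference compounds.

    Candidate pairs within ``ppm_tol`` (m/z) and ``rt_tol`` (RT, seconds)
    are assigned greedily in order of ppm distance then RT distance, one
    feature per reference.  Returns ``(matched: ref id -> feature index,
    unmatched reference ids)``.
    """
    if not len(features) or not len(reference):
        raise ValueError("features and reference must be non-empty")
    feat = np.asarray([(f[0], f[1]) for f in features], dtype=np.float64)
    pairs = []
    for ri, ref in enumerate(reference):
        dppm = np.abs(feat[:, 0] - ref.mz) / ref.mz * 1e6
        drt = np.abs(feat[:, 1] - ref.rt)
        ok = (dppm < ppm_tol) & (drt < rt_tol)
        for fi in np.flatnonzero(ok):
            pairs.append((float(dppm[fi]), float(drt[fi]), ri, int(fi)))
    pairs.sort()
    matched: dict[str, int] = {}
    used_refs: set[int] = set()
    used_feats: set[int] = set()
    for _, _, ri, fi in pairs:
        if ri in used_refs or fi in used_feats:
            continue
        used_refs.add(ri)
        used_feats.add(fi)
        matched[reference[ri].id] = fi
    unmatched = [r.id for i, r in enumerate(reference) if i not in used_refs]
    return matched, unmatched


def consensus_quantified(
    matched: Mapping[str, int],
    reference: Sequence[ReferenceCompound],
    group_a: Mapping[int, float] | Sequence[float],
    group_b: Mapping[int, float] | Sequence[float],
    rel_err_tol: float = 0.5,
) -> int:
    """Count matched references whose observed A/B intensity ratio agrees.

    The observed ratio (mean group A / mean group B feature intensity) must
    be within ``rel_err_tol`` relative error of the reference's expected
    ratio.  Features with zero group-B mean are skipped with a warning.
    """
    ref_by_id = {r.id: r for r in reference}
    count = 0
    skipped = 0
    for rid, fi in matched.items():
        ref = ref_by_id.get(rid)
        if ref is None or ref.expected_ratio is None:
            continue
        a = group_a[fi]
        b = group_b[fi]
        if b == 0:
            skipped += 1
            continue
        observed = a / b
        if abs(observed / ref.expected_ratio - 1.0) < rel_err_tol:
            count += 1
    if skipped:
        warnings.warn(f"skipped {skipped} features with zero group-B intensity")
    return count


def count_linear_peaks(
    table: np.ndarray,
    factors: Sequence[float],
    alpha: float = LINEARITY_ALPHA,
) -> tuple[int, float]:
    """Count features whose intensity is linear in the dilution factor.

    Ordinary least squares of intensity on factor per feature; a feature is
    counted when the slope test gives p < ``alpha`` with a positive slope.
    Requires at least 3 distinct factors; constant features are not counted.
    Returns ``(n_linear, fraction of features)``.
    """
    table = np.asarray(table, dtype=np.float64)
    factors = np.asarray(factors, dtype=np.float64)
    if table.ndim != 2 or table.shape[1] != factors.size:
        raise ValueError("table must be features x runs with one factor per run")
    if len(set(factors.tolist())) < 3:
        raise ValueError("need at least 3 distinct dilution factors")
    n_linear = 0
    for row in table:
        finite = np.isfinite(row)
        if finite.sum() < 3 or np.ptp(row[finite]) <= 0:
            continue
        res = stats.linregress(factors[finite], row[finite])
        if np.isfinite(res.pvalue) and res.pvalue < alpha and res.slope > 0:
            n_linear += 1
    return n_linear, n_linear / table.shape[0]


def gaussian_peak_ratio(
    features: Sequence,
    cor_cutoff: float = 0.9,
    p_cutoff: float = 0.05,
) -> float:
    """Fraction of features whose EIC shape is Gaussian (cor >= 0.9, p <= 0.05)."""
    feats = list(features)
    if not feats:
        raise ValueError("no features to rate")
    n_gauss = sum(
        1 for f in feats if f.gauss_cor >= cor_cutoff and f.gauss_p <= p_cutoff
    )
    return n_gauss / len(feats)
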