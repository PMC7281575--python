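"""Retention-time-aware pathway activity prediction (empirical compounds).

m/z features are matched to candidate compounds over a table of adduct and
isotope ion forms; per compound, co-eluting matches are clustered into
empirical compounds (ECs) within a retention-time window (by default 2% of
the maximum RT); ECs sharing an identical (m/z, ion form) member at the same
RT are merged; ECs lacking a primary ion are dropped.  Pathway libraries are
converted from compound space to EC space and enrichment of the significant
ECs is tested per pathway with a one-sided Fisher/hypergeometric test with
EASE correction, smoothed by a Gamma null fitted to permutation scores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IonForm",
    "MummichogParams",
    "EmpiricalCompound",
    "ECStages",
    "EnrichmentRow",
    "ion_forms",
    "normalize_ion_name",
    "match_mz",
    "build_empirical_compounds",
    "convert_library",
    "enrich_mummichog",
]

PROTON = 1.00727646677
_H2O = 18.0105646863
_NA = 22.98976928
_K = 38.9637064864
_NH4 = 18.0338254
_CL = 34.96885268
_HCOO = 44.9982029
_E = 0.00054857990


@dataclass(frozen=True)
class IonForm:
    """An adduct/ion species: m/z = (multiplier * M + mass_shift) / |charge|."""

    name: str
    mass_shift: float
    charge: int
    mode: str
    multiplier: int = 1
    is_primary: bool = False

    def theoretical_mz(self, mass: float) -> float:
        return (self.multiplier * mass + self.mass_shift) / abs(self.charge)


_POSITIVE_FORMS = (
    IonForm("M+H[1+]", PROTON, 1, "positive", is_primary=True),
    IonForm("M+Na[1+]", _NA - _E, 1, "positive", is_primary=True),
    IonForm("M-H2O+H[1+]", PROTON - _H2O, 1, "positive", is_primary=True),
    IonForm("M+K[1+]", _K - _E, 1, "positive"),
    IonForm("M+NH4[1+]", _NH4 - _E, 1, "positive"),
    IonForm("M+2H[2+]", 2 * PROTON, 2, "positive"),
    IonForm("2M+H[1+]", PROTON, 1, "positive", multiplier=2),
)
_NEGATIVE_FORMS = (
    IonForm("M-H[-]", -PROTON, -1, "negative", is_primary=True),
    IonForm("M-2H[2-]", -2 * PROTON, -2, "negative", is_primary=True),
    IonForm("M-H2O-H[-]", -PROTON - _H2O, -1, "negative", is_primary=True),
    IonForm("M+Cl[-]", _CL + _E, -1, "negative"),
    IonForm("M+HCOO[-]", _HCOO + _E, -1, "negative"),
    IonForm("2M-H[-]", -PROTON, -1, "negative", multiplier=2),
)

# alias spellings (whitespace variants, unicode minus, [1-] vs [-]) map to
# one canonical name each
_ALIASES = {
    "M-H[1-]": "M-H[-]",
    "M-H2O-H[1-]": "M-H2O-H[-]",
}


def normalize_ion_name(name: str) -> str:
    """Canonicalise an ion-form name (strip spaces, unify minus signs)."""
    cleaned = re.sub(r"\s+", "", name).replace("−", "-").replace("–", "-")
    return _ALIASES.get(cleaned, cleaned)


def ion_forms(mode: str) -> tuple[IonForm, ...]:
    """The ion-form table for an acquisition mode."""
    if mode == "positive":
        return _POSITIVE_FORMS
    if mode == "negative":
        return _NEGATIVE_FORMS
    raise ValueError(f"mode must be positive or negative, got {mode!r}")


@dataclass
class MummichogParams:
    """Tolerance and algorithm settings for EC-based enrichment."""

    ppm: float = 10.0
    mode: str = "positive"
    rt_frac: float = 0.02
    rt_tol: float | None = None  # seconds; overrides rt_frac when set
    force_primary_ion: bool = True
    p_cutoff: float = 0.05
    n_perm: int = 100
    seed: int = 42
    # EC significance rule: "any" member feature significant, or "primary"
    ec_significance: str = "any"

    def window(self, max_rt: float) -> float:
        """The retention-time window in seconds for EC construction."""
        if self.rt_tol is not None:
            return float(self.rt_tol)
        return float(max_rt) * self.rt_frac


@dataclass
class EmpiricalCompound:
    """A group of co-eluting features putatively explaining one metabolite."""

    ec_id: str
    compound_ids: set[str]
    members: list[tuple[int, float, float, str]]  # (feature idx, mz, rt, form name)

    @property
    def rt_span(self) -> tuple[float, float]:
        rts = [m[2] for m in self.members]
        return (min(rts), max(rts))

    @property
    def has_primary(self) -> bool:
        primary = _primary_names()
        return any(normalize_ion_name(m[3]) in primary for m in self.members)

    @property
    def feature_indices(self) -> set[int]:
        return {m[0] for m in self.members}


def _primary_names() -> frozenset:
    return frozenset(
        f.name for f in _POSITIVE_FORMS + _NEGATIVE_FORMS if f.is_primary
    )


@dataclass
class ECStages:
    """The three EC construction stages, kept for inspection."""

    initial: list[EmpiricalCompound]
    merged: list[EmpiricalCompound]
    final: list[EmpiricalCompound]
    window: float


@dataclass
class EnrichmentRow:
    pathway: str
    total_ecs: int
    hits_sig: int
    p_raw: float
    p_gamma: float


# ---------------------------------------------------------------------------
# m/z matching
# ---------------------------------------------------------------------------

def match_mz(
    features: Sequence[tuple[float, float]] | pd.DataFrame,
    compounds: Sequence[tuple[str, float]] | pd.DataFrame,
    params: MummichogParams,
) -> list[tuple[int, str, IonForm]]:
    """Match observed (mz, rt) features against compound monoisotopic masses.

    A feature matches a (compound, form) pair when the relative deviation of
    its m/z from the form's theoretical m/z is within ``params.ppm``; one
    feature may match many pairs.
    """
    if isinstance(features, pd.DataFrame):
        feat_mz = features["mz"].to_numpy(dtype=np.float64)
    else:
        feat_mz = np.array([f[0] for f in features], dtype=np.float64)
    if isinstance(compounds, pd.DataFrame):
        comp_ids = list(compounds["id"].astype(str))
        masses = compounds["mass"].to_numpy(dtype=np.float64)
    else:
        comp_ids = [c[0] for c in compounds]
        masses = np.array([c[1] for c in compounds], dtype=np.float64)
    if not comp_ids:
        return []
    matches: list[tuple[int, str, IonForm]] = []
    order = np.argsort(feat_mz)
    sorted_mz = feat_mz[order]
    tol_factor = params.ppm * 1e-6
    for form in ion_forms(params.mode):
        theo = form.theoretical_mz(masses)
        lo = np.searchsorted(sorted_mz, theo * (1 - tol_factor), side="left")
        hi = np.searchsorted(sorted_mz, theo * (1 + tol_factor), side="right")
        for ci, (a, b) in enumerate(zip(lo, hi)):
            for fi in order[a:b]:
                if abs(feat_mz[fi] - theo[ci]) / theo[ci] <= tol_factor:
                    matches.append((int(fi), comp_ids[ci], form))
    matches.sort(key=lambda m: (m[0], m[1], m[2].name))
    return matches


# ---------------------------------------------------------------------------
# empirical-compound construction
# ---------------------------------------------------------------------------

def build_empirical_compounds(
    matches: Sequence[tuple[int, str, IonForm]],
    features: pd.DataFrame,
    params: MummichogParams,
) -> ECStages:
    """Build the initial, merged and final empirical-compound lists.

    Stage 1 splits each compound's matches into co-eluting clusters by
    single-linkage over RT with the window as threshold; stage 2 merges ECs
    sharing an identical (m/z, form) member at the same RT (both within
    tolerance); stage 3 keeps only ECs containing a primary ion when
    ``force_primary_ion`` is set.
    """
    if "rt" not in features.columns or features["rt"].isna().all():
        raise ValueError(
            "features carry no retention time; RT-free enrichment is not supported"
        )
    feat_mz = features["mz"].to_numpy(dtype=np.float64)
    feat_rt = features["rt"].to_numpy(dtype=np.float64)
    window = params.window(float(feat_rt.max()))

    by_compound: dict[str, list[tuple[int, str]]] = {}
    for fi, cid, form in matches:
        by_compound.setdefault(cid, []).append((fi, form.name))

    initial: list[EmpiricalCompound] = []
    for cid in sorted(by_compound):
        members = by_compound[cid]
        members = sorted(members, key=lambda m: (feat_rt[m[0]], feat_mz[m[0]], m[1]))
        cluster: list[tuple[int, str]] = []
        prev_rt = None
        clusters: list[list[tuple[int, str]]] = []
        for fi, form_name in members:
            rt = feat_rt[fi]
            if prev_rt is not None and rt - prev_rt > window:
                clusters.append(cluster)
                cluster = []
            cluster.append((fi, form_name))
            prev_rt = rt
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            initial.append(
                EmpiricalCompound(
                    ec_id=f"EC{len(initial) + 1}",
                    compound_ids={cid},
                    members=[(fi, float(feat_mz[fi]), float(feat_rt[fi]), fn) for fi, fn in cl],
                )
            )

    # stage 2: union-find merge on shared (m/z, form) members at the same RT
    parent = list(range(len(initial)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    tol_factor = params.ppm * 1e-6
    # index members by form for pair search
    entries = []  # (mz, rt, form, ec index)
    for idx, ec in enumerate(initial):
        for _, mz, rt, fn in ec.members:
            entries.append((mz, rt, normalize_ion_name(fn), idx))
    entries.sort()
    for a in range(len(entries)):
        mz_a, rt_a, form_a, ec_a = entries[a]
        for b in range(a + 1, len(entries)):
            mz_b, rt_b, form_b, ec_b = entries[b]
            if mz_b - mz_a > mz_a * tol_factor:
                break
            if ec_a == ec_b or form_a != form_b:
                continue
            if abs(rt_b - rt_a) <= window:
                union(ec_a, ec_b)

    groups: dict[int, list[int]] = {}
    for idx in range(len(initial)):
        groups.setdefault(find(idx), []).append(idx)
    merged: list[EmpiricalCompound] = []
    for root in sorted(groups):
        idxs = groups[root]
        compound_ids: set[str] = set()
        members: list[tuple[int, float, float, str]] = []
        seen = set()
        for i in idxs:
            compound_ids |= initial[i].compound_ids
            for m in initial[i].members:
                key = (m[0], normalize_ion_name(m[3]))
                if key not in seen:
                    seen.add(key)
                    members.append(m)
        merged.append(
            EmpiricalCompound(
                ec_id=f"EC{len(merged) + 1}",
                compound_ids=compound_ids,
                members=sorted(members),
            )
        )

    if params.force_primary_ion:
        final = [ec for ec in merged if ec.has_primary]
    else:
        final = list(merged)
    final = [replace(ec, ec_id=f"EC{i + 1}") for i, ec in enumerate(final)]
    return ECStages(initial=initial, merged=merged, final=final, window=window)


def convert_library(
    library: Mapping[str, set[str]],
    final_ecs: Sequence[EmpiricalCompound],
) -> dict[str, set[str]]:
    """Convert a pathway -> compound library to pathway -> EC ids.

    An EC belongs to a pathway when its compound ids intersect the pathway's
    compounds; pathways with no ECs are dropped from testing.
    """
    out: dict[str, set[str]] = {}
    for pathway, comps in library.items():
        ecs = {ec.ec_id for ec in final_ecs if ec.compound_ids & set(comps)}
        if ecs:
            out[pathway] = ecs
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _ease_p(hits: np.ndarray, universe: int, pathway_size: np.ndarray, n_sig: int) -> np.ndarray:
    """One-sided hypergeometric tail with EASE correction (hits - 1)."""
    hits = np.asarray(hits, dtype=np.int64)
    p = np.ones(hits.shape, dtype=np.float64)
    pos = hits >= 1
    if pos.any():
        p[pos] = stats.hypergeom.sf(
            hits[pos] - 2, universe, np.asarray(pathway_size)[pos], n_sig
        )
    return np.clip(p, 0.0, 1.0)


def enrich_mummichog(
    feature_table: pd.DataFrame,
    library: Mapping[str, set[str]],
    compounds: pd.DataFrame,
    params: MummichogParams | None = None,
) -> list[EnrichmentRow]:
    """Pathway activity prediction from an (mz, rt, p) peak list.

    Features at ``p <= p_cutoff`` form the significant set; an EC is
    significant when any member feature is (or, with
    ``ec_significance='primary'``, any primary-ion member).  Raw pathway
    p-values come from the EASE-corrected hypergeometric tail on the EC
    2x2 table; the permutation null redraws the significant feature set,
    pools -ln(p) across pathways and permutations, fits a Gamma
    distribution, and reports its upper tail at each observed score.
    """
    params = params or MummichogParams()
    matches = match_mz(feature_table, compounds, params)
    stages = build_empirical_compounds(matches, feature_table, params)
    ec_list = stages.final
    ec_lib = convert_library(library, ec_list)
    pvals = feature_table["p"].to_numpy(dtype=np.float64)
    n_features = pvals.size
    sig_mask = pvals <= params.p_cutoff
    if not sig_mask.any():
        raise ValueError("no significant features at the requested cutoff")
    if sig_mask.all():
        raise ValueError("all features significant: the 2x2 table is degenerate")
    n_sig_features = int(sig_mask.sum())

    primary = _primary_names()
    ec_feature_sets = []
    for ec in ec_list:
        if params.ec_significance == "primary":
            ec_feature_sets.append(
                {m[0] for m in ec.members if normalize_ion_name(m[3]) in primary}
            )
        else:
            ec_feature_sets.append(ec.feature_indices)
    universe = len(ec_list)
    pathways = sorted(ec_lib)
    ec_index = {ec.ec_id: i for i, ec in enumerate(ec_list)}
    membership = np.zeros((len(pathways), universe), dtype=bool)
    for pi, pw in enumerate(pathways):
        for ec_id in ec_lib[pw]:
            membership[pi, ec_index[ec_id]] = True
    pathway_size = membership.sum(axis=1)

    def sig_ec_vector(sig_feature_idx: set[int]) -> np.ndarray:
        return np.array(
            [bool(fs & sig_feature_idx) for fs in ec_feature_sets], dtype=bool
        )

    membership_int = membership.astype(np.int64)
    observed_sig = sig_ec_vector(set(np.flatnonzero(sig_mask)))
    n_sig_ecs = int(observed_sig.sum())
    obs_hits = membership_int @ observed_sig.astype(np.int64)
    p_raw = _ease_p(obs_hits, universe, pathway_size, n_sig_ecs)

    rng = np.random.default_rng(params.seed)
    null_scores: list[np.ndarray] = []
    for _ in range(params.n_perm):
        drawn = set(rng.choice(n_features, size=n_sig_features, replace=False).tolist())
        sig_vec = sig_ec_vector(drawn)
        hits = membership_int @ sig_vec.astype(np.int64)
        p_perm = _ease_p(hits, universe, pathway_size, int(sig_vec.sum()))
        null_scores.append(-np.log(np.clip(p_perm, 1e-300, 1.0)))
    null = np.concatenate(null_scores)
    positive = null[null > 1e-12]
    obs_scores = -np.log(np.clip(p_raw, 1e-300, 1.0))
    if positive.size >= 10 and np.ptp(positive) > 1e-12:
        # the null is a mixture: an atom at score 0 (p_raw = 1) plus a
        # continuous part approximated by a Gamma; calibrate against the
        # mixture so that the exceedance probability is honest
        frac_pos = positive.size / null.size
        shape, loc, scale = stats.gamma.fit(positive, floc=0)
        p_gamma = np.where(
            obs_scores <= 1e-12,
            1.0,
            frac_pos * stats.gamma.sf(obs_scores, shape, loc=loc, scale=scale),
        )
        p_gamma = np.clip(p_gamma, 0.0, 1.0)
    else:
        p_gamma = p_raw.copy()
    rows = [
        EnrichmentRow(
            pathway=pw,
            total_ecs=int(pathway_size[pi]),
            hits_sig=int(obs_hits[pi]),
            p_raw=float(p_raw[pi]),
            p_gamma=float(p_gamma[pi]),
        )
        for pi, pw in enumerate(pathways)
    ]
    rows.sort(key=lambda r: (r.p_gamma, r.p_raw, r.pathway))
    return rows
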