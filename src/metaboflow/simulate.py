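"""Ground-truthed synthetic data for every stage of the workflow.

Generators are pure functions of their arguments and a seed: chromatographic
runs with planted Gaussian peaks, dilution series, batch-affected feature
tables with pooled-QC samples, and pathway libraries with planted enrichment.
Ground truth (planted peaks, the clean matrix, truth labels) is always
returned next to the data so recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .batch import BatchDesign
from .spectra import CentroidScan, SpectraRun

__all__ = [
    "PlantedPeak",
    "NoiseModel",
    "simulate_run",
    "simulate_dilution_series",
    "simulate_batched_table",
    "simulate_pathway_data",
]

C13_C12_DELTA = 1.003355  # Th per charge between isotopologue traces


@dataclass(frozen=True)
class PlantedPeak:
    """A Gaussian-in-time chromatographic peak planted at a fixed m/z."""

    mz: float
    rt_apex: float
    rt_sigma: float
    height: float
    isotope_partner: bool = False
    isotope_abundance: float | None = None  # relative to height; drawn if None
    charge: int = 1

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Uniform-in-m/z spike noise on top of an intensity baseline."""

    baseline: float = 0.0
    sd: float = 0.0
    spike_rate: float = 0.0  # expected random noise points per scan

    def __post_init__(self) -> None:
        if min(self.baseline, self.sd, self.spike_rate) < 0:
            raise ValueError("noise parameters must be >= 0")


def _expand_isotopes(peaks: Sequence[PlantedPeak], rng: np.random.Generator) -> list[PlantedPeak]:
    """Materialise isotope partner traces as additional planted peaks."""
    out: list[PlantedPeak] = []
    for p in peaks:
        out.append(p)
        if p.isotope_partner:
            abundance = p.isotope_abundance
            if abundance is None:
                abundance = float(rng.uniform(0.05, 0.3))
            out.append(
                replace(
                    p,
                    mz=p.mz + C13_C12_DELTA / max(p.charge, 1),
                    height=p.height * abundance,
                    isotope_partner=False,
                    isotope_abundance=None,
                )
            )
    return out


def simulate_run(
    peaks: Sequence[PlantedPeak],
    noise: NoiseModel | None = None,
    rt_grid: tuple[float, float, float] = (0.0, 300.0, 1.0),
    mz_jitter_ppm: float = 0.0,
    seed: int = 0,
    mz_range: tuple[float, float] = (50.0, 1000.0),
    sample_id: str = "synthetic",
    min_intensity: float = 1.0,
) -> SpectraRun:
    """Simulate a centroided MS1 run with planted Gaussian peaks.

    Each planted peak contributes ``height * exp(-(t - apex)^2 / (2 sigma^2))``
    on the RT grid; its m/z is jittered per scan by ``N(0, ppm)``.  Isotope
    partners are added at the charge-appropriate spacing.  Noise points are
    uniform in m/z (the sparse background of LC-HRMS spectra).  Centroids
    below ``min_intensity`` are not recorded, emulating the instrument's
    detection floor.
    """
    start, end, step = rt_grid
    if not (end > start and step > 0):
        raise ValueError("rt_grid must satisfy end > start and step > 0")
    noise = noise or NoiseModel()
    seen: set[tuple[float, float]] = set()
    for p in peaks:
        key = (round(p.mz, 6), round(p.rt_apex, 6))
        if key in seen:
            raise ValueError(f"duplicate planted (mz, rt) pair {key}: ambiguous ground truth")
        seen.add(key)
    rng = np.random.default_rng(seed)
    all_peaks = _expand_isotopes(peaks, rng)
    rts = np.arange(start, end + step / 2, step)
    scans: list[CentroidScan] = []
    scan_totals: list[float] = []
    for rt in rts:
        mzs: list[float] = []
        intens: list[float] = []
        for p in all_peaks:
            dt = rt - p.rt_apex
            if abs(dt) > 5 * p.rt_sigma:
                continue
            inten = p.height * np.exp(-(dt**2) / (2 * p.rt_sigma**2))
            if inten < min_intensity:
                continue
            mz = p.mz
            if mz_jitter_ppm > 0:
                mz *= 1.0 + rng.normal(0.0, mz_jitter_ppm * 1e-6)
            mzs.append(mz)
            intens.append(inten)
        if noise.spike_rate > 0:
            n_spikes = rng.poisson(noise.spike_rate)
            for _ in range(n_spikes):
                mzs.append(float(rng.uniform(*mz_range)))
                intens.append(
                    max(float(noise.baseline + rng.normal(0.0, noise.sd)), min_intensity)
                )
        if mzs:
            mz_arr = np.asarray(mzs)
            in_arr = np.asarray(intens)
            order = np.argsort(mz_arr, kind="stable")
            mz_arr, in_arr = mz_arr[order], in_arr[order]
            if mz_arr.size > 1 and np.any(np.diff(mz_arr) == 0):
                uniq, inverse = np.unique(mz_arr, return_inverse=True)
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, in_arr)
                mz_arr, in_arr = uniq, summed
        else:
            mz_arr = np.empty(0)
            in_arr = np.empty(0)
        scan_totals.append(float(in_arr.sum()))
        scans.append(CentroidScan(rt=float(rt), mz=mz_arr, intensity=in_arr, ms_level=1))
    meta = {"seed": seed, "scan_totals": scan_totals, "n_planted": len(peaks)}
    return SpectraRun(scans=scans, sample_id=sample_id, meta=meta)


def simulate_dilution_series(
    peaks: Sequence[PlantedPeak],
    factors: Sequence[float],
    replicates: int = 1,
    noise: NoiseModel | None = None,
    rt_grid: tuple[float, float, float] = (0.0, 300.0, 1.0),
    mz_jitter_ppm: float = 0.0,
    seed: int = 0,
) -> list[SpectraRun]:
    """Simulate a dilution series: peak heights scale with the factor, noise does not."""
    if len(factors) == 0:
        raise ValueError("factors must be non-empty")
    if any(f <= 0 for f in factors):
        raise ValueError("dilution factors must be positive")
    runs: list[SpectraRun] = []
    sub_seed = seed
    for rep in range(replicates):
        for factor in factors:
            scaled = [replace(p, height=p.height * factor) for p in peaks]
            sub_seed += 1
            run = simulate_run(
                scaled,
                noise=noise,
                rt_grid=rt_grid,
                mz_jitter_ppm=mz_jitter_ppm,
                seed=sub_seed,
                sample_id=f"dilution_{factor}_rep{rep}",
            )
            run.meta.update({"dilution_factor": factor, "replicate": rep})
            runs.append(run)
    return runs


def simulate_batched_table(
    n_features: int = 200,
    n_samples: int = 48,
    batches: int = 2,
    batch_shift: Sequence[float] | None = None,
    drift: float = 0.0,
    qc_every: int = 0,
    group_effect: float = 0.5,
    group_effect_fraction: float = 0.1,
    bio_sd: float = 0.3,
    noise_sd: float = 0.05,
    batch_shift_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, BatchDesign, pd.DataFrame]:
    """Simulate a features x samples intensity table with batch structure.

    Returns ``(table, design, clean)`` where ``clean`` is the same table
    without batch shifts or injection-order drift (the correction target).
    QC samples, inserted every ``qc_every`` injections, are the all-sample
    mean profile plus technical noise only — a pooled mixture of all
    samples.  Study samples additionally carry per-sample biological
    variability (``bio_sd``, log scale), which is why QCs cluster tightly
    relative to study samples on clean data.

    ``batch_shift`` gives one nominal multiplicative factor per batch
    (default 1.0 for the first batch and 2.0 for subsequent ones when
    ``batches >= 2``); the realised factor is feature-specific, drawn
    log-normally around the nominal value with spread ``batch_shift_sd``
    (instrument response drifts differently per compound — a uniform
    scaling would be mere normalization, not a batch effect).  ``drift`` is
    the total fractional monotone intensity change across the injection
    sequence.
    """
    if batches < 1:
        raise ValueError("need at least one batch")
    rng = np.random.default_rng(seed)
    if batch_shift is None:
        batch_shift = [1.0] + [2.0] * (batches - 1)
    if len(batch_shift) != batches:
        raise ValueError("batch_shift must have one entry per batch")

    base = rng.lognormal(mean=np.log(1e5), sigma=1.0, size=n_features)
    # biological groups on study samples, alternating A/B
    qc_positions: set[int] = set()
    if qc_every > 0:
        qc_positions = set(range(qc_every - 1, n_samples, qc_every))
    sample_ids, groups, is_qc = [], [], []
    study_counter = 0
    for i in range(n_samples):
        if i in qc_positions:
            sample_ids.append(f"QC_{i + 1}")
            groups.append("QC")
            is_qc.append(True)
        else:
            sample_ids.append(f"S_{i + 1}")
            groups.append("A" if study_counter % 2 == 0 else "B")
            is_qc.append(False)
            study_counter += 1
    batch_labels = [f"B{(i * batches) // n_samples + 1}" for i in range(n_samples)]
    injection_order = np.arange(1, n_samples + 1)

    affected = rng.random(n_features) < group_effect_fraction
    clean = np.empty((n_features, n_samples))
    for j in range(n_samples):
        mult = np.ones(n_features)
        if groups[j] == "B":
            mult = np.where(affected, 1.0 + group_effect, 1.0)
        profile = base * mult
        clean[:, j] = profile * rng.lognormal(0.0, bio_sd, size=n_features) * rng.lognormal(
            0.0, noise_sd, size=n_features
        )
    # QC columns: pooled mean profile of the study samples + noise
    study_cols = [j for j in range(n_samples) if not is_qc[j]]
    if study_cols:
        pooled = clean[:, study_cols].mean(axis=1)
        for j in range(n_samples):
            if is_qc[j]:
                clean[:, j] = pooled * rng.lognormal(0.0, noise_sd, size=n_features)

    dirty = clean.copy()
    unique_batches = sorted(set(batch_labels), key=batch_labels.index)
    shifts = [float(s) for s in batch_shift]
    no_effect = all(s == 1.0 for s in shifts)
    shift_by_batch = {}
    for bi, (b, nominal) in enumerate(zip(unique_batches, shifts)):
        if no_effect or bi == 0:
            # the first batch is the reference; all-ones means no batch effect
            shift_by_batch[b] = np.full(n_features, nominal)
        else:
            shift_by_batch[b] = nominal * rng.lognormal(0.0, batch_shift_sd, n_features)
    for j in range(n_samples):
        factor = shift_by_batch[batch_labels[j]]
        if drift != 0.0 and n_samples > 1:
            factor = factor * (1.0 + drift * (injection_order[j] - 1) / (n_samples - 1))
        dirty[:, j] *= factor

    feature_ids = [f"F{i + 1}" for i in range(n_features)]
    table = pd.DataFrame(dirty, index=feature_ids, columns=sample_ids)
    clean_df = pd.DataFrame(clean, index=feature_ids, columns=sample_ids)
    design = BatchDesign(
        sample_ids=sample_ids,
        batch=batch_labels,
        group=groups,
        is_qc=is_qc,
        injection_order=list(injection_order),
    )
    return table, design, clean_df


def simulate_pathway_data(
    n_compounds: int = 120,
    n_pathways: int = 25,
    enriched_pathway_size: int = 10,
    mode: str = "positive",
    effect: float = 0.0,
    sig_fraction: float = 0.1,
    pathway_size_range: tuple[int, int] = (4, 12),
    rt_max: float = 600.0,
    p_primary: float = 0.9,
    mz_jitter_ppm: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]], pd.DataFrame, dict]:
    """Simulate an annotated peak list plus pathway library with known truth.

    Each compound emits 1–4 ion-form features at form-consistent m/z that
    co-elute within a shared narrow RT window; the primary ion is present
    with probability ``p_primary``.  Under ``effect > 0``, that fraction of
    the designated pathway's compounds is made significant (all their
    features get small p-values); everything else gets uniform p-values with
    a random ``sig_fraction`` background significant at p < 0.05.

    Returns ``(features, library, compounds, truth)``.
    """
    from .mummichog import ion_forms  # local import to avoid a cycle

    if enriched_pathway_size > n_compounds:
        raise ValueError("enriched pathway cannot exceed the compound universe")
    rng = np.random.default_rng(seed)
    forms = ion_forms(mode)
    primary_forms = [f for f in forms if f.is_primary]
    other_forms = [f for f in forms if not f.is_primary]

    comp_ids = [f"C{i + 1}" for i in range(n_compounds)]
    masses = rng.uniform(100.0, 800.0, size=n_compounds)
    compounds = pd.DataFrame({"id": comp_ids, "mass": masses})

    # library: pathway P1 is the designated (possibly enriched) pathway
    library: dict[str, set[str]] = {}
    library["P1"] = set(rng.choice(comp_ids, size=enriched_pathway_size, replace=False))
    lo_sz, hi_sz = pathway_size_range
    for k in range(2, n_pathways + 1):
        size = int(rng.integers(lo_sz, hi_sz + 1))
        library[f"P{k}"] = set(rng.choice(comp_ids, size=min(size, n_compounds), replace=False))

    perturbed = {cid: False for cid in comp_ids}
    if effect > 0:
        enriched = sorted(library["P1"])
        chosen = rng.random(len(enriched)) < effect
        for cid, hit in zip(enriched, chosen):
            perturbed[cid] = bool(hit)
        if effect >= 1.0:
            for cid in enriched:
                perturbed[cid] = True

    rows = []
    for cid, mass in zip(comp_ids, masses):
        emitted: list = []
        if rng.random() < p_primary:
            emitted.append(primary_forms[int(rng.integers(len(primary_forms)))])
        n_extra = int(rng.integers(0, 4 - len(emitted)))
        for _ in range(n_extra):
            pool = other_forms or primary_forms
            emitted.append(pool[int(rng.integers(len(pool)))])
        if not emitted:
            continue
        rt_center = float(rng.uniform(30.0, rt_max))
        for form in emitted:
            mz = form.theoretical_mz(mass)
            mz *= 1.0 + rng.normal(0.0, mz_jitter_ppm * 1e-6)
            rt = min(max(rt_center + rng.uniform(-2.5, 2.5), 0.0), rt_max)
            if perturbed[cid]:
                p = float(rng.uniform(0.0, 1e-4))
            elif rng.random() < sig_fraction:
                p = float(rng.uniform(0.0, 0.05))
            else:
                p = float(rng.uniform(0.05, 1.0))
            stat = float(rng.normal(0.0, 1.0) + (4.0 if perturbed[cid] else 0.0))
            rows.append((mz, rt, p, stat, cid, form.name))
    features = pd.DataFrame(rows, columns=["mz", "rt", "p", "statistic", "true_compound", "true_form"])
    truth = {
        "enriched_pathway": "P1" if effect > 0 else None,
        "perturbed_compounds": {c for c, v in perturbed.items() if v},
    }
    return features, library, compounds, truth
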