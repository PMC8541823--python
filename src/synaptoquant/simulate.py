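"""Synthetic data generators with recorded ground truth.

Every analysis stage in this package has a matching generator that produces
inputs with the statistical structure the stage assumes, together with the
generating parameters ("truth"), so each stage can be validated by recovery
tests without any external data.

* mEPSP events: quantal content from a (truncated) binomial, amplitude from a
  Gaussian around integer multiples of the quantal size, optional baseline
  noise, Poisson-process event times.
* Larval crawl: a quasi-periodic area oscillation (one cycle per peristaltic
  wave) with measurement noise, a centroid advancing one stride per wave
  along a smoothly turning heading, and near-constant body dimensions.
* NMJ image pairs: 2-D Gaussian puncta on a dark noisy background, split into
  membrane-visible and vesicle-visible populations so that quench and
  pH-collapse scans have closed-form expected area-fraction ratios.
* FM-dye pairs: punctate loaded image plus a mask; the unloaded image scales
  the signal by (1 - released fraction).
* Co-IP peptide tables: protein abundances with a wide log-scale dynamic
  range, per-peptide ionisation efficiencies, replicate noise, bait-group
  fold changes for spiked proteins, and detection-limit (left-censored)
  missingness — the dominant missingness mechanism in label-free MS.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import ImageScan
from .locomotion import LarvaTrack
from .quantal import EventSeries, QuantalParams

__all__ = [
    "simulate_mepsp_events",
    "simulate_crawl",
    "simulate_nmj_pair",
    "simulate_fm_pair",
    "simulate_coip",
]


# ---------------------------------------------------------------------------
# mEPSP events


def simulate_mepsp_events(
    model: QuantalParams,
    n_events: int,
    noise_sd: float = 0.0,
    rate_hz: float = 2.0,
    seed: int = 0,
    cell_id: str = "sim",
) -> tuple[EventSeries, dict]:
    """Draw mEPSP amplitudes from the binomial x Gaussian generative model.

    Each event draws a quantal content i from the model's (optionally
    truncated) binomial, then an amplitude from N(i*q, sigma_i), plus optional
    Gaussian baseline noise; non-positive amplitudes are redrawn (the model
    describes positive potentials).  Event times follow a homogeneous Poisson
    process at ``rate_hz``: the duration is set to n_events / rate and times
    are uniform on it.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    i_support = np.arange(0, model.n + 1)
    from .quantal import quantal_content_pmf

    weights = np.array([quantal_content_pmf(model, int(i)) for i in i_support])
    contents = rng.choice(i_support, size=n_events, p=weights / weights.sum())
    sig = np.where(contents > 0, contents ** model.peak_sd_exponent * model.sigma0, 0.0)
    amps = contents * model.q + rng.normal(0.0, 1.0, n_events) * sig
    if noise_sd > 0:
        amps = amps + rng.normal(0.0, noise_sd, n_events)
    for _ in range(100):
        bad = amps <= 0
        if not bad.any():
            break
        k = int(bad.sum())
        c = contents[bad]
        redraw = c * model.q + rng.normal(0.0, 1.0, k) * np.where(
            c > 0, c ** model.peak_sd_exponent * model.sigma0, 0.0
        )
        if noise_sd > 0:
            redraw = redraw + rng.normal(0.0, noise_sd, k)
        amps[bad] = redraw
    amps = np.maximum(amps, 1e-6)
    duration = n_events / rate_hz
    times = np.sort(rng.uniform(0.0, duration, n_events))
    events = EventSeries(amplitudes=amps, duration=duration, times=times, cell_id=cell_id)
    truth = {
        "q": model.q,
        "sigma0": model.sigma0,
        "n": model.n,
        "p": model.p,
        "peak_sd_exponent": model.peak_sd_exponent,
        "truncated": model.truncated,
        "noise_sd": noise_sd,
        "rate_hz": rate_hz,
        "n_events": n_events,
        "seed": seed,
    }
    return events, truth


# ---------------------------------------------------------------------------
# larval crawl


def simulate_crawl(
    n_waves: int,
    stride_mm: float = 1.5,
    fps: float = 12.5,
    duration: float = 120.0,
    noise: float = 0.05,
    baseline_area: float = 4.0,
    oscillation_amplitude: float | None = None,
    body_length: float = 4.0,
    body_width: float = 1.0,
    seed: int = 0,
    larva_id: str = "sim",
) -> tuple[LarvaTrack, dict]:
    """Synthetic crawling track with ``n_waves`` programmed peristaltic waves.

    The projected area completes one full oscillation cycle per wave (noise is
    Gaussian with SD ``noise`` times the oscillation amplitude); the centroid
    moves at constant speed ``n_waves * stride_mm / duration`` along a slowly
    wandering heading, so total path length is n_waves * stride_mm up to the
    last-frame truncation; body dimensions are constant plus 1% jitter.
    """
    if n_waves < 0:
        raise ValueError("n_waves must be >= 0")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * fps))
    t = np.arange(n_frames) / fps
    amp = 0.12 * baseline_area if oscillation_amplitude is None else oscillation_amplitude
    if n_waves > 0:
        area = baseline_area - amp * np.cos(2.0 * math.pi * n_waves * t / duration)
    else:
        area = np.full(n_frames, baseline_area)
    area = area + rng.normal(0.0, noise * amp, n_frames)
    area = np.maximum(area, 0.05 * baseline_area)

    speed = n_waves * stride_mm / duration
    heading = np.cumsum(rng.normal(0.0, 0.05, n_frames))  # slow random turning
    steps = speed / fps * np.column_stack([np.cos(heading), np.sin(heading)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps[:-1], axis=0)])

    spine = body_length * (1.0 + rng.normal(0.0, 0.01, n_frames))
    width = body_width * (1.0 + rng.normal(0.0, 0.01, n_frames))
    track = LarvaTrack(
        frame_times=t,
        centroid_xy=xy,
        area=area,
        spine_length=spine,
        width=width,
        larva_id=larva_id,
    )
    truth = {
        "n_waves": n_waves,
        "stride_mm": stride_mm,
        "fps": fps,
        "duration": duration,
        "noise": noise,
        "baseline_area": baseline_area,
        "oscillation_amplitude": amp,
        "distance_mm": speed * (n_frames - 1) / fps,
        "seed": seed,
    }
    return track, truth


# ---------------------------------------------------------------------------
# imaging


def _puncta_image(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
    background_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cy, cx), a in zip(centers, amplitudes):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        local = r2 < (6 * sigma_px) ** 2
        img[local] += a * np.exp(-0.5 * r2[local] / sigma_px**2)
    img += rng.normal(0.0, background_sd, shape)
    return np.maximum(img, 0.0)


def _grid_positions(
    shape: tuple[int, int], n: int, cell: int, rng: np.random.Generator
) -> np.ndarray:
    """Non-overlapping punctum centres: one per randomly chosen grid cell."""
    ny, nx = shape[0] // cell, shape[1] // cell
    if n > ny * nx:
        raise ValueError(f"cannot place {n} puncta on a {ny}x{nx} grid")
    cells = rng.permutation(ny * nx)[:n]
    cy = cells // nx * cell + cell // 2 + rng.integers(-2, 3, n)
    cx = cells % nx * cell + cell // 2 + rng.integers(-2, 3, n)
    return np.column_stack([cy, cx]).astype(float)


def simulate_nmj_pair(
    vesicular_fraction: float,
    condition: str = "quench",
    puncta_count: int = 100,
    shape: tuple[int, int] = (256, 256),
    vesicle_membrane_ratio: float = 2.0,
    amplitude: float = 1000.0,
    sigma_px: float = 1.5,
    background_sd: float = 5.0,
    seed: int = 0,
) -> tuple[ImageScan, ImageScan, dict]:
    """Paired before/after scans of punctate pH-probe fluorescence.

    ``vesicular_fraction`` v is the fraction of the probe signal residing in
    deacidified (hence fluorescent) synaptic vesicles rather than on the
    presynaptic membrane.

    * quench: scan 1 shows all ``puncta_count`` fluorescent puncta; the acidic
      second scan quenches surface signal, leaving the round(v * count)
      vesicle-visible puncta.  Expected area-fraction ratio: v.
    * collapse: ``puncta_count`` total puncta split into membrane and
      vesicular populations in the mass ratio ``vesicle_membrane_ratio`` r.
      Scan 1 shows membrane plus the already-visible fraction v of vesicular
      puncta; the NH4Cl second scan reveals all.  Expected ratio:
      (1 + r) / (1 + v*r) (3-fold for v=0, r=2).

    The recorded threshold (3 x background SD) separates puncta from
    background; puncta are placed on a jittered grid so their footprints do
    not overlap and area fractions superpose linearly.
    """
    if not 0.0 <= vesicular_fraction <= 1.0:
        raise ValueError("vesicular_fraction must lie in [0, 1]")
    if condition not in ("quench", "collapse"):
        raise ValueError("condition must be 'quench' or 'collapse'")
    rng = np.random.default_rng(seed)
    threshold = 3.0 * background_sd
    v = vesicular_fraction

    if condition == "quench":
        centers = _grid_positions(shape, puncta_count, 16, rng)
        amps = amplitude * np.exp(rng.normal(0.0, 0.1, puncta_count))
        n_ves = int(round(v * puncta_count))
        ves_idx = rng.permutation(puncta_count)[:n_ves]
        first = _puncta_image(shape, centers, amps, sigma_px, background_sd, rng)
        second = _puncta_image(
            shape, centers[ves_idx], amps[ves_idx], sigma_px, background_sd, rng
        )
        expected_ratio = n_ves / puncta_count if puncta_count else float("nan")
    else:
        n_mem = max(int(round(puncta_count / (1.0 + vesicle_membrane_ratio))), 1)
        n_ves = puncta_count - n_mem
        centers = _grid_positions(shape, n_mem + n_ves, 16, rng)
        amps = amplitude * np.exp(rng.normal(0.0, 0.1, n_mem + n_ves))
        mem_c, ves_c = centers[:n_mem], centers[n_mem:]
        mem_a, ves_a = amps[:n_mem], amps[n_mem:]
        n_vis = int(round(v * n_ves))
        vis = rng.permutation(n_ves)[:n_vis]
        first = _puncta_image(
            shape,
            np.vstack([mem_c, ves_c[vis]]),
            np.concatenate([mem_a, ves_a[vis]]),
            sigma_px,
            background_sd,
            rng,
        )
        second = _puncta_image(shape, centers, amps, sigma_px, background_sd, rng)
        expected_ratio = (n_mem + n_ves) / (n_mem + n_vis)

    truth = {
        "vesicular_fraction": v,
        "condition": condition,
        "threshold": threshold,
        "expected_ratio": expected_ratio,
        "puncta_count": puncta_count,
        "vesicle_membrane_ratio": vesicle_membrane_ratio,
        "seed": seed,
    }
    return (
        ImageScan(pixels=first, condition="HL3"),
        ImageScan(
            pixels=second,
            condition="HL3-pH5.5" if condition == "quench" else "HL3-NH4Cl",
        ),
        truth,
    )


def simulate_fm_pair(
    released_fraction: float,
    puncta_count: int = 60,
    shape: tuple[int, int] = (256, 256),
    amplitude: float = 1000.0,
    sigma_px: float = 1.5,
    background_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ImageScan, ImageScan, np.ndarray, dict]:
    """Loaded/unloaded FM-dye scans plus a membrane-marker mask.

    The unloaded image carries ``(1 - released_fraction)`` of the loaded
    punctate signal (plus background noise); the mask is the union of punctum
    footprints, mimicking a GFP-restricted synaptic region.
    """
    if not 0.0 <= released_fraction <= 1.0:
        raise ValueError("released_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    centers = _grid_positions(shape, puncta_count, 16, rng)
    amps = amplitude * np.exp(rng.normal(0.0, 0.1, puncta_count))
    signal = _puncta_image(shape, centers, amps, sigma_px, 0.0, rng)
    loaded = np.maximum(signal + rng.normal(0.0, background_sd, shape), 0.0)
    unloaded = np.maximum(
        (1.0 - released_fraction) * signal + rng.normal(0.0, background_sd, shape), 0.0
    )
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 < (3 * sigma_px) ** 2
    truth = {
        "released_fraction": released_fraction,
        "puncta_count": puncta_count,
        "seed": seed,
    }
    return (
        ImageScan(pixels=loaded, condition="loaded"),
        ImageScan(pixels=unloaded, condition="unloaded"),
        mask,
        truth,
    )


# ---------------------------------------------------------------------------
# co-IP peptide tables


def simulate_coip(
    n_proteins: int = 300,
    spiked: dict[str, float] | None = None,
    n_experiments: int = 3,
    detection_quantile: float = 0.1,
    missing_rate: float = 1.0,
    rep_sd_log2: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Peptide intensity table for a bait-vs-control pull-down series.

    Protein log2 abundances are uniform on [16, 24] (a wide, bounded dynamic
    range); each protein yields 1-8 peptides with bounded per-peptide
    ionisation efficiencies (uniform +/-0.5 in log2, shared across experiments
    and groups) and replicate noise of ``rep_sd_log2``.  ``spiked`` maps
    protein ids (``"P0001"``...) to a fold change applied to the bait group in
    every experiment (a scalar fold, or a sequence of per-experiment folds).
    Missingness is intensity-dependent left-censoring at the identification
    level: a protein whose abundance in a given (experiment, group) run falls
    below the detection limit (the ``detection_quantile`` quantile of the
    baseline abundance distribution) is not identified in that run — all its
    peptides there are missing together — with probability ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    spiked = dict(spiked or {})
    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    unknown = set(spiked) - set(ids)
    if unknown:
        raise ValueError(f"spiked ids not in the protein universe: {sorted(unknown)}")
    base_log2 = rng.uniform(16.0, 24.0, n_proteins)
    # detection limit in closed form from the uniform baseline distribution
    limit_log2 = 16.0 + detection_quantile * 8.0
    n_pep = rng.integers(1, 9, n_proteins)
    rows = []
    for pi, pid in enumerate(ids):
        pep_eff = rng.uniform(-0.5, 0.5, n_pep[pi])
        folds = spiked.get(pid, 1.0)
        if np.isscalar(folds):
            folds = [float(folds)] * n_experiments
        if any(f <= 0 for f in folds):
            raise ValueError("spiked folds must be > 0")
        for exp in range(1, n_experiments + 1):
            for grp in ("bait", "control"):
                shift = math.log2(folds[exp - 1]) if grp == "bait" else 0.0
                cell_log2 = base_log2[pi] + shift
                identified = cell_log2 >= limit_log2 or rng.uniform() >= missing_rate
                vals = (
                    cell_log2
                    + pep_eff
                    + rng.normal(0.0, rep_sd_log2, n_pep[pi])
                )
                for k in range(n_pep[pi]):
                    intensity = 2.0 ** vals[k] if identified else np.nan
                    rows.append((pid, f"{pid}_pep{k + 1}", exp, grp, intensity))
    table = pd.DataFrame(
        rows, columns=["protein_id", "peptide_id", "experiment", "group", "intensity"]
    )
    table["gene_symbol"] = table["protein_id"]
    truth = {
        "spiked": {k: v for k, v in spiked.items()},
        "n_proteins": n_proteins,
        "n_experiments": n_experiments,
        "detection_quantile": detection_quantile,
        "missing_rate": missing_rate,
        "rep_sd_log2": rep_sd_log2,
        "seed": seed,
    }
    return table, truth
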