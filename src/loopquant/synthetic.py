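"""Synthetic single-allele FISH data with known ground truth.

Emulates the tabular output of a high-content imaging pipeline — one row per
segmented nucleus and one row per detected FISH spot — under a controlled
generative model:

* each cell carries ``ploidy`` alleles; each allele is either *looped* or
  *free*;
* the cross-channel separation of the two labeled loci of an allele is drawn
  from a half-normal law when looped and a Rayleigh law when free (the
  Rayleigh being the 2D-projected distance of an isotropic displacement);
* allele loop states within a cell are exchangeable with an intra-class
  correlation set by ``allele_coupling`` (a beta-binomial hierarchy: the
  cell-level loop probability is Beta-distributed with mean ``p_loop``,
  degenerate when the coupling is zero);
* log fusion-protein expression can shift the loop log-odds linearly
  (``expression_effect``);
* an allele shows an active transcription site with probability
  ``rna_p_on * (1 - repression_effect * contact)`` where *contact* means the
  true pair distance is below the contact threshold;
* detection is imperfect: true spots drop out independently with probability
  ``1 - spot_detection_prob`` and spurious spots appear per nucleus and
  channel at rate ``false_spot_rate``.

All randomness flows from ``config.seed`` through independent child streams
of one :class:`numpy.random.Generator`; identical configs give byte-identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .cluster import KineticTrace
from .config import SimulationConfig

DEFAULT_CONTACT_THRESHOLD = 0.27
_NUCLEUS_GRID_SPACING = 40.0  # um between nucleus centers in the synthetic field
_CELLS_PER_FIELD = 200


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of one generated dataset: one row per allele.

    ``alleles`` columns: nucleus_id, allele_id, looped, true_distance_um,
    contact, rna_active, expression, p_cell.
    """

    alleles: pd.DataFrame
    contact_threshold: float

    @property
    def realized_p_c(self) -> float:
        """Fraction of generated alleles whose true distance is a contact."""
        return float(self.alleles["contact"].mean())


def _cell_loop_probabilities(cfg: SimulationConfig, log_expr: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Per-cell loop probability: expression-shifted mean, Beta dispersion."""
    if cfg.p_loop in (0.0, 1.0) or cfg.expression_effect == 0.0:
        mean = np.full(log_expr.shape, cfg.p_loop)
    else:
        logit = math.log(cfg.p_loop / (1.0 - cfg.p_loop))
        shifted = logit + cfg.expression_effect * (log_expr - cfg.expression_params[0])
        mean = 1.0 / (1.0 + np.exp(-shifted))
    rho = cfg.allele_coupling
    if rho == 0.0:
        return mean
    # beta-binomial hierarchy: Beta(a, b) with mean m and ICC rho
    with np.errstate(divide="ignore", invalid="ignore"):
        a = mean * (1.0 - rho) / rho
        b = (1.0 - mean) * (1.0 - rho) / rho
    p = np.where((mean > 0) & (mean < 1), rng.beta(np.maximum(a, 1e-12),
                                                   np.maximum(b, 1e-12)), mean)
    return p


def _uniform_in_disk(n: int, radius: np.ndarray | float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(radius) * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return r * np.cos(theta), r * np.sin(theta)


def generate_fish_dataset(
    config: SimulationConfig,
    condition: str = "synthetic",
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate nucleus and spot tables plus ground truth.

    Returns
    -------
    nuclei : DataFrame with columns nucleus_id, field_id, condition,
        area_um2, solidity, gfp_mean.
    spots : DataFrame with columns nucleus_id, channel (dna_a/dna_b/rna),
        x_um, y_um, intensity.
    truth : TruthTable
    """
    cfg = config
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(6)
    rng_cell, rng_state, rng_geom, rng_detect, rng_false, rng_rna = streams

    n = cfg.n_cells
    ploidy = cfg.ploidy

    area = np.maximum(rng_cell.normal(*cfg.nucleus_area_params, size=n), 10.0)
    solidity = rng_cell.beta(*cfg.nucleus_solidity_params, size=n)
    log_expr = rng_cell.normal(*cfg.expression_params, size=n)
    expression = np.exp(log_expr)

    p_cell = _cell_loop_probabilities(cfg, log_expr, rng_state)
    looped = rng_state.uniform(size=(n, ploidy)) < p_cell[:, None]

    radius = np.sqrt(area / np.pi)
    # nucleus centers on a grid so coordinates resemble a real field of view
    col = np.arange(n) % 50
    row = np.arange(n) // 50
    cx = col * _NUCLEUS_GRID_SPACING
    cy = row * _NUCLEUS_GRID_SPACING

    n_alleles = n * ploidy
    rad_rep = np.repeat(radius, ploidy)
    ax, ay = _uniform_in_disk(n_alleles, rad_rep, rng_geom)
    ax += np.repeat(cx, ploidy)
    ay += np.repeat(cy, ploidy)

    looped_flat = looped.ravel()
    loc, hscale = cfg.looped_distance_params
    rscale = cfg.free_distance_params[0]
    dist = np.where(
        looped_flat,
        loc + hscale * np.abs(rng_geom.standard_normal(n_alleles)),
        rng_geom.rayleigh(rscale, size=n_alleles),
    )
    theta = rng_geom.uniform(0.0, 2.0 * np.pi, size=n_alleles)
    bx = ax + dist * np.cos(theta)
    by = ay + dist * np.sin(theta)

    contact = dist < contact_threshold
    p_on = cfg.rna_p_on * (1.0 - cfg.repression_effect * contact)
    rna_active = rng_rna.uniform(size=n_alleles) < p_on
    ts_intensity = rng_rna.lognormal(*cfg.ts_intensity_params, size=n_alleles)

    nucleus_ids = np.arange(n)
    allele_nucleus = np.repeat(nucleus_ids, ploidy)
    truth = pd.DataFrame({
        "nucleus_id": allele_nucleus,
        "allele_id": np.tile(np.arange(ploidy), n),
        "looped": looped_flat,
        "true_distance_um": dist,
        "contact": contact,
        "rna_active": rna_active,
        "expression": np.repeat(expression, ploidy),
        "p_cell": np.repeat(p_cell, ploidy),
    })

    nuclei = pd.DataFrame({
        "nucleus_id": nucleus_ids,
        "field_id": [f"F{i // _CELLS_PER_FIELD}" for i in nucleus_ids],
        "condition": condition,
        "area_um2": area,
        "solidity": solidity,
        "gfp_mean": expression,
    })

    spot_frames = []
    dna_int = rng_detect.lognormal(6.0, 0.3, size=2 * n_alleles)
    for k, (xs, ys, inten) in enumerate([
        (ax, ay, dna_int[:n_alleles]),
        (bx, by, dna_int[n_alleles:]),
    ]):
        keep = rng_detect.uniform(size=n_alleles) < cfg.spot_detection_prob
        spot_frames.append(pd.DataFrame({
            "nucleus_id": allele_nucleus[keep],
            "channel": "dna_a" if k == 0 else "dna_b",
            "x_um": xs[keep],
            "y_um": ys[keep],
            "intensity": inten[keep],
        }))
    keep_rna = rna_active & (rng_detect.uniform(size=n_alleles)
                             < cfg.spot_detection_prob)
    spot_frames.append(pd.DataFrame({
        "nucleus_id": allele_nucleus[keep_rna],
        "channel": "rna",
        "x_um": ax[keep_rna],
        "y_um": ay[keep_rna],
        "intensity": ts_intensity[keep_rna],
    }))

    if cfg.false_spot_rate > 0:
        for channel in ("dna_a", "dna_b", "rna"):
            counts = rng_false.poisson(cfg.false_spot_rate, size=n)
            total = int(counts.sum())
            if total == 0:
                continue
            nid = np.repeat(nucleus_ids, counts)
            fx, fy = _uniform_in_disk(total, np.repeat(radius, counts), rng_false)
            spot_frames.append(pd.DataFrame({
                "nucleus_id": nid,
                "channel": channel,
                "x_um": fx + np.repeat(cx, counts),
                "y_um": fy + np.repeat(cy, counts),
                "intensity": rng_false.lognormal(6.0, 0.3, size=total),
            }))

    spots = pd.concat(spot_frames, ignore_index=True)
    spots = spots.sort_values(["nucleus_id", "channel"],
                              kind="stable").reset_index(drop=True)
    return nuclei, spots, TruthTable(alleles=truth,
                                     contact_threshold=contact_threshold)


def implied_contact_probability(
    config: SimulationConfig,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    conditional_on: float | None = None,
) -> float:
    """Probability that a generated pair distance falls below ``threshold``.

    Numerically integrates the configured half-normal/Rayleigh mixture
    density. With ``conditional_on`` set (typically the 2 um matching cap),
    returns the probability conditional on the distance being below that cap,
    which is what the pipeline's contact fraction estimates since longer
    pairs are discarded. Exact only when ``expression_effect`` is zero (the
    marginal loop probability then equals ``p_loop``).
    """
    loc, hscale = config.looped_distance_params
    rscale = config.free_distance_params[0]

    def density(x: float) -> float:
        return (config.p_loop * stats.halfnorm.pdf(x, loc=loc, scale=hscale)
                + (1 - config.p_loop) * stats.rayleigh.pdf(x, scale=rscale))

    below, _ = integrate.quad(density, 0.0, threshold)
    if conditional_on is None:
        return below
    denom, _ = integrate.quad(density, 0.0, conditional_on)
    return below / denom


@dataclass(frozen=True)
class GeneratedKineticTrace:
    """A simulated clustering time course with its analytic ground truth."""

    trace: KineticTrace
    tc_true_s: float
    td_true_s: float
    t_peak_s: float
    cv_peak: float


def _kinetic_curve(t_min: np.ndarray, cv0: float, cv_max: float,
                   rise: float, decay: float, t_peak: float) -> np.ndarray:
    t = np.asarray(t_min, dtype=float)
    rise_part = 1.0 - np.exp(-rise * t)
    decay_part = np.exp(-decay * np.maximum(0.0, t - t_peak))
    return cv0 + (cv_max - cv0) * rise_part * decay_part


def generate_kinetic_trace(
    cv0: float,
    cv_max: float,
    rise_rate: float,
    decay_rate: float,
    frame_interval: float = 30.0,
    duration: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GeneratedKineticTrace:
    """Simulate a CV(t) clustering/declustering time course.

    ``rise_rate`` and ``decay_rate`` in 1/min, ``frame_interval`` in seconds,
    ``duration`` in minutes. The noiseless curve rises saturatingly toward
    ``cv_max`` and, past its peak, relaxes exponentially back toward the
    rising envelope's baseline. The peak time is placed where the one-sided
    decay continues the rise with zero slope, giving a smooth interior
    maximum; this requires ``decay_rate < rise_rate``.

    Ground-truth half-times (time to half-maximal clustering on the way up,
    and from the peak on the way down) are computed by root-finding on the
    noiseless curve and stored on the returned object.
    """
    if not (cv_max > cv0 > 0):
        raise ValueError("require cv_max > cv0 > 0")
    if decay_rate >= rise_rate:
        raise ValueError(
            "decay_rate >= rise_rate yields no interior maximum; "
            "choose decay_rate < rise_rate"
        )
    if decay_rate <= 0 or frame_interval <= 0 or duration <= 0:
        raise ValueError("rates, frame_interval and duration must be positive")

    from scipy.optimize import brentq

    t_peak = math.log(1.0 + rise_rate / decay_rate) / rise_rate  # minutes

    def curve(t: float) -> float:
        return float(_kinetic_curve(np.array([t]), cv0, cv_max,
                                    rise_rate, decay_rate, t_peak)[0])

    cv_peak = curve(t_peak)
    half = cv0 + (cv_peak - cv0) / 2.0
    tc_min = brentq(lambda t: curve(t) - half, 1e-12, t_peak)
    t_hi = t_peak + 1.0
    while curve(t_hi) > half:
        t_hi += 1.0
        if t_hi > t_peak + 1e4:  # pragma: no cover - decay_rate>0 guarantees exit
            raise RuntimeError("declustering never returns to half-maximum")
    td_min = brentq(lambda t: curve(t) - half, t_peak, t_hi) - t_peak

    times_s = np.arange(0.0, duration * 60.0 + 1e-9, frame_interval)
    values = _kinetic_curve(times_s / 60.0, cv0, cv_max,
                            rise_rate, decay_rate, t_peak)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.maximum(values, 0.0)

    trace = KineticTrace(times=times_s, cv_values=values, activation_index=0)
    return GeneratedKineticTrace(
        trace=trace,
        tc_true_s=tc_min * 60.0,
        td_true_s=td_min * 60.0,
        t_peak_s=t_peak * 60.0,
        cv_peak=cv_peak,
    )


def generate_cluster_image(
    nucleus_radius_px: int,
    n_clusters: int,
    cluster_amplitude: float,
    cluster_sigma_px: float,
    background: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic nucleus image: uniform background plus Gaussian clusters.

    Returns (image, mask): the mask is a filled circle; the image is zero
    outside the mask and ``background`` plus ``n_clusters`` Gaussian peaks of
    the given amplitude and sigma inside it.
    """
    if nucleus_radius_px < 1:
        raise ValueError("nucleus_radius_px must be >= 1")
    rng = np.random.default_rng(seed)
    size = 2 * nucleus_radius_px + 5
    c = size / 2.0 - 0.5
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (xx - c) ** 2 + (yy - c) ** 2 <= nucleus_radius_px ** 2
    image = np.where(mask, float(background), 0.0)
    if n_clusters > 0 and cluster_amplitude != 0:
        px, py = _uniform_in_disk(n_clusters, float(nucleus_radius_px), rng)
        for x0, y0 in zip(px + c, py + c):
            peak = cluster_amplitude * np.exp(
                -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * cluster_sigma_px ** 2)
            )
            image += np.where(mask, peak, 0.0)
    return image, mask


def generate_image_pair(
    image: np.ndarray, shift_px: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``image`` and a cyclic translation of it by ``(dx, dy)`` pixels.

    ``dx`` moves content along the x (column) axis, ``dy`` along y (rows);
    :func:`loopquant.registration.phase_correlation` recovers exactly this
    shift for any integer translation.
    """
    dx, dy = shift_px
    shifted = np.roll(np.asarray(image), shift=(int(dy), int(dx)), axis=(0, 1))
    return np.asarray(image), shifted
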