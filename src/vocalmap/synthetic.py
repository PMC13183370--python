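"""Synthetic cohort, audio and striatal-section generators.

This module emulates the full data structure of a double-label (activity-tagged
tdTomato reporter + acute c-Fos) whole-brain mapping experiment of courtship
ultrasonic vocalization (USV): per-mouse USV counts, per-section cell-detection
tables for both channels inside hemisphere ROI polygons, bregma bookkeeping
(30-um sections collected in 12 series, 360 um within-series spacing), ultrasonic
audio with ground-truth call events, and striatal sections with striosome blob
masks. Every stage carries a ground-truth ledger so downstream operations can be
tested against known effects with no external data.

All randomness flows from one master seed through per-purpose child seeds, so a
given configuration reproduces byte-identical fixtures.

USV-coupling mechanism
----------------------
A region couples to vocal output through a log-linear model: for exposed mouse *i*
with standardized USV count z_i, the latent density is
``baseline * exposure_multiplier * exp(beta * z_i + eps_i)`` with
``eps_i ~ N(0, sigma^2)`` (between-animal biological noise, default sigma = 0.10).
``beta`` is solved numerically so the *expected sample Pearson correlation* between
measured density and USV count equals the requested ``usv_coupling``, accounting for
the lognormal noise and the Poisson counting noise at the region's expected cell
yield. Negative couplings use the same mechanism with beta < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from . import striatum as _striatum
from .roi import CHANNEL_CFOS, CHANNEL_TDTOMATO, RoiAnnotation, empty_cell_table

GROUP_EXPOSED = "female-exposure"
GROUP_CONTROL = "no-exposure"

CATEGORY_BY_EFFECT = {
    "usv_positive": "usv-positive",
    "usv_negative": "usv-negative",
    "social": "social-interaction-related",
    "unrelated": "unrelated",
}


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """Ground-truth description of one region (or bregma-limited subregion).

    ``name`` is the anatomical parent used for ROI labels (e.g. ``"CPu"``); ``label``
    is the ledger key (e.g. ``"rCPu"``), defaulting to ``name``. ``usv_coupling`` is
    the target sample Pearson correlation between measured density and USV count
    among exposed mice; ``coupling_span_mm`` optionally confines the coupling to a
    bregma sub-interval (sections outside it get uncoupled mouse-level noise only).
    ``reactivation_prob`` is the probability that a tagged (tdTomato) cell is
    re-labeled with c-Fos in the second session. ``roi_area_mm2`` is the pooled
    two-hemisphere ROI area per section.
    """

    name: str
    bregma_span_mm: tuple[float, float]
    baseline_density: float
    exposure_multiplier: float = 1.0
    usv_coupling: float = 0.0
    reactivation_prob: float = 0.25
    roi_area_mm2: float = 1.0
    label: str = ""
    coupling_span_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.baseline_density < 0:
            raise ValueError(f"{self.name}: baseline_density must be >= 0")
        if self.roi_area_mm2 <= 0:
            raise ValueError(f"{self.name}: roi_area_mm2 must be positive")
        if self.exposure_multiplier < 0:
            raise ValueError(f"{self.name}: exposure_multiplier must be >= 0")
        if abs(self.usv_coupling) > 1:
            raise ValueError(f"{self.name}: |usv_coupling| must be <= 1")
        if not 0 <= self.reactivation_prob <= 1:
            raise ValueError(f"{self.name}: reactivation_prob must be in [0, 1]")
        if self.bregma_span_mm[0] >= self.bregma_span_mm[1]:
            raise ValueError(f"{self.name}: bregma span must be (low, high) with low < high")
        if not self.label:
            object.__setattr__(self, "label", self.name)

    @property
    def effect_type(self) -> str:
        if self.usv_coupling > 0:
            return "usv_positive"
        if self.usv_coupling < 0:
            return "usv_negative"
        if self.exposure_multiplier != 1.0:
            return "social"
        return "unrelated"


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the mapping study's design: 30-um coronal sections collected in
    12 series (360 um within-series spacing) and overdispersed per-mouse USV counts
    (negative binomial, mean 120, dispersion 2) for exposed mice; controls emit none.
    """

    n_exposed: int
    n_control: int
    regions: tuple[RegionSpec, ...]
    section_thickness_um: float = 30.0
    n_series: int = 12
    usv_mean: float = 120.0
    usv_dispersion: float = 2.0
    between_animal_sigma: float = 0.10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exposed < 3 or self.n_control < 3:
            raise ValueError("need at least 3 mice per group")
        if not self.regions:
            raise ValueError("need at least one region")

    @property
    def section_spacing_mm(self) -> float:
        """Within-series spacing: thickness x number of series."""
        return self.section_thickness_um * self.n_series / 1000.0


@dataclass(frozen=True)
class SectionRecord:
    """One region on one synthetic section: hemisphere ROIs plus its cell table."""

    mouse_id: str
    section_id: str
    region: str
    bregma_mm: float
    rois: tuple[RoiAnnotation, ...]
    cells: pd.DataFrame


@dataclass(frozen=True)
class SyntheticExperiment:
    mice: pd.DataFrame  # mouse_id, group, usv_count
    sections: tuple[SectionRecord, ...]
    truth: dict
    config: CohortConfig


# ---------------------------------------------------------------------------
# coupling solver
# ---------------------------------------------------------------------------

def _expected_sample_r(beta: float, z: np.ndarray, sigma: float, nbar: float) -> float:
    """Moment approximation of the expected sample Pearson correlation between the
    measured density and the (standardized) USV count, at log-effect ``beta``,
    lognormal noise ``sigma`` and expected per-mouse cell yield ``nbar``."""
    n = len(z)
    m = np.exp(beta * z + sigma**2 / 2)
    var = np.exp(2 * beta * z) * (np.exp(2 * sigma**2) - np.exp(sigma**2)) + m / max(nbar, 1e-9)
    zc = z - z.mean()
    num = float(np.sum(m * zc))
    den_y = float(np.sum((m - m.mean()) ** 2) + (1 - 1 / n) * np.sum(var))
    den = np.sqrt(den_y * float(np.sum(zc**2)))
    return num / den if den > 0 else 0.0


def solve_coupling_beta(
    target_r: float, z: np.ndarray, sigma: float, nbar: float, beta_max: float = 6.0
) -> float:
    """Solve for beta so the expected sample correlation equals ``target_r``.

    Uses the realized standardized USV counts of the cohort, so skewness of the
    count distribution is accounted for. If the target is beyond the maximum
    achievable correlation at this noise level, the argmax beta is returned.
    """
    from scipy.optimize import brentq

    if target_r == 0 or np.ptp(z) == 0:
        return 0.0
    sign = 1.0 if target_r > 0 else -1.0
    target = abs(target_r)
    bs = np.linspace(0, beta_max, 241)
    rs = np.array([sign * _expected_sample_r(sign * b, z, sigma, nbar) for b in bs])
    k_max = int(np.argmax(rs))
    if rs[k_max] <= target:
        return sign * bs[k_max]
    # smallest beta whose expected correlation reaches the target
    k = int(np.argmax(rs >= target))
    lo, hi = bs[max(k - 1, 0)], bs[k]
    if lo == hi:
        return sign * hi
    f = lambda b: sign * _expected_sample_r(sign * b, z, sigma, nbar) - target
    try:
        return sign * brentq(f, lo, hi, xtol=1e-6)
    except ValueError:
        return sign * hi


# ---------------------------------------------------------------------------
# cell placement
# ---------------------------------------------------------------------------

def _uniform_points_in_polygon(polygon: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform points inside a polygon by bounding-box rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    if polygon.area <= 0:
        raise ValueError("degenerate polygon (zero area)")
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    got = 0
    import shapely as _sh

    while got < n:
        m = max(32, int((n - got) * 2.5))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = _sh.contains_xy(polygon, xs, ys)
        take = min(n - got, int(ok.sum()))
        out[got : got + take] = np.c_[xs[ok], ys[ok]][:take]
        got += take
    return out


def place_cells(
    polygon: Polygon,
    density_td: float,
    rng: np.random.Generator,
    reactivation_prob: float = 0.25,
    density_fos: float | None = None,
    coloc_jitter_um: float = 0.7,
) -> pd.DataFrame:
    """Place tdTomato and c-Fos cells in one ROI polygon.

    tdTomato count is Poisson with mean ``density_td * area``; centroids are uniform
    in the polygon. A Binomial(``reactivation_prob``) fraction of tdTomato cells get
    a co-located c-Fos partner (Gaussian jitter clipped inside 2 um, well inside the
    8 um matching tolerance so the truth is unambiguous); independent c-Fos cells
    are added at ``density_fos * (1 - reactivation_prob)`` to keep the channel
    totals comparable. ``density_fos`` defaults to ``density_td``.
    """
    if density_td < 0 or (density_fos is not None and density_fos < 0):
        raise ValueError("densities must be >= 0")
    if polygon.area <= 0:
        raise ValueError("degenerate polygon (zero area)")
    if density_fos is None:
        density_fos = density_td
    area_mm2 = polygon.area / 1e6
    n_td = rng.poisson(density_td * area_mm2)
    td_xy = _uniform_points_in_polygon(polygon, n_td, rng)
    n_react = rng.binomial(n_td, reactivation_prob) if n_td else 0
    react_idx = rng.choice(n_td, size=n_react, replace=False) if n_react else np.array([], int)
    jitter = rng.normal(0.0, coloc_jitter_um, size=(n_react, 2))
    norms = np.linalg.norm(jitter, axis=1)
    too_far = norms > 1.99
    if too_far.any():
        jitter[too_far] *= (1.99 / norms[too_far])[:, None]
    fos_partner_xy = td_xy[react_idx] + jitter
    n_fos_ind = rng.poisson(density_fos * (1 - reactivation_prob) * area_mm2)
    fos_ind_xy = _uniform_points_in_polygon(polygon, n_fos_ind, rng)
    fos_xy = np.vstack([fos_partner_xy, fos_ind_xy])

    def _table(xy: np.ndarray, channel: str, mean_intensity: float) -> pd.DataFrame:
        k = len(xy)
        return pd.DataFrame(
            {
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "channel": channel,
                "intensity": mean_intensity * rng.lognormal(0.0, 0.3, k),
                "area_um2": rng.gamma(16.0, 5.0, k),
            }
        )

    parts = [_table(td_xy, CHANNEL_TDTOMATO, 40.0), _table(fos_xy, CHANNEL_CFOS, 20.0)]
    cells = pd.concat(parts, ignore_index=True)
    return cells if len(cells) else empty_cell_table()


def _hemisphere_rois(region: str, bregma: float, area_mm2: float) -> tuple[RoiAnnotation, RoiAnnotation]:
    """Two square hemisphere ROIs of half the pooled area each, side by side."""
    side = np.sqrt(area_mm2 / 2.0) * 1000.0  # um
    gap = 500.0
    left = box(0.0, 0.0, side, side)
    right = box(side + gap, 0.0, 2 * side + gap, side)
    return (
        RoiAnnotation(region, "left", bregma, left),
        RoiAnnotation(region, "right", bregma, right),
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> SyntheticExperiment:
    """Generate a complete synthetic experiment from one master seed.

    Per-mouse USV counts (controls: 0), per-region per-section two-channel cell
    tables inside hemisphere ROIs, and a ground-truth ledger with the true effect
    type and the realized density-vs-USV correlation per region label.
    Deterministic given ``config.master_seed``.
    """
    ss = np.random.SeedSequence(config.master_seed)
    rng_usv, rng_phase, rng_regions = [np.random.default_rng(s) for s in ss.spawn(3)]

    n_total = config.n_exposed + config.n_control
    mouse_ids = [f"m{k:02d}" for k in range(n_total)]
    groups = [GROUP_EXPOSED] * config.n_exposed + [GROUP_CONTROL] * config.n_control
    p_nb = config.usv_dispersion / (config.usv_dispersion + config.usv_mean)
    usv = np.r_[
        rng_usv.negative_binomial(config.usv_dispersion, p_nb, config.n_exposed),
        np.zeros(config.n_control, dtype=int),
    ]
    mice = pd.DataFrame({"mouse_id": mouse_ids, "group": groups, "usv_count": usv})

    exposed_usv = usv[: config.n_exposed].astype(float)
    if np.ptp(exposed_usv) > 0:
        z = (exposed_usv - exposed_usv.mean()) / exposed_usv.std(ddof=1)
    else:
        z = np.zeros_like(exposed_usv)

    spacing = config.section_spacing_mm
    # per-mouse sectioning phase: which series was stained, as a bregma offset
    phases = rng_phase.uniform(0, spacing, n_total)

    sections: list[SectionRecord] = []
    truth_regions: dict[str, dict] = {}
    sigma = config.between_animal_sigma

    for spec in config.regions:
        rng_r = np.random.default_rng(rng_regions.integers(0, 2**31 - 1))
        lo, hi = spec.bregma_span_mm
        couple_lo, couple_hi = spec.coupling_span_mm or (lo, hi)
        # expected per-mouse yield inside the coupled span, for the beta solver
        n_coupled_sections = max(1, int((couple_hi - couple_lo) / spacing))
        nbar = spec.baseline_density * spec.exposure_multiplier * spec.roi_area_mm2 * n_coupled_sections
        beta = solve_coupling_beta(spec.usv_coupling, z, sigma, nbar) if config.n_exposed >= 3 else 0.0

        eps_c = rng_r.normal(0.0, sigma, n_total)   # coupled-span mouse noise
        eps_u = rng_r.normal(0.0, sigma, n_total)   # uncoupled-span mouse noise
        latent_coupled = np.empty(n_total)
        latent_uncoupled = np.empty(n_total)
        for k in range(n_total):
            mult = spec.exposure_multiplier if groups[k] == GROUP_EXPOSED else 1.0
            b_term = beta * z[k] if groups[k] == GROUP_EXPOSED else 0.0
            latent_coupled[k] = spec.baseline_density * mult * np.exp(b_term + eps_c[k])
            latent_uncoupled[k] = spec.baseline_density * mult * np.exp(eps_u[k])

        realized_counts = np.zeros(n_total)
        realized_area = np.zeros(n_total)
        for k, mouse in enumerate(mouse_ids):
            positions = np.arange(lo + phases[k], hi, spacing)
            for s_idx, bregma in enumerate(positions):
                coupled = couple_lo <= bregma <= couple_hi
                dens = latent_coupled[k] if coupled else latent_uncoupled[k]
                rois = _hemisphere_rois(spec.name, float(bregma), spec.roi_area_mm2)
                tables = []
                for roi in rois:
                    tables.append(
                        place_cells(
                            roi.polygon,
                            dens,
                            rng_r,
                            reactivation_prob=spec.reactivation_prob,
                        )
                    )
                cells = pd.concat(tables, ignore_index=True)
                n_td = int((cells["channel"] == CHANNEL_TDTOMATO).sum())
                realized_counts[k] += n_td
                realized_area[k] += spec.roi_area_mm2
                sections.append(
                    SectionRecord(
                        mouse_id=mouse,
                        section_id=f"{spec.label}_s{s_idx:02d}",
                        region=spec.name,
                        bregma_mm=float(bregma),
                        rois=rois,
                        cells=cells,
                    )
                )
        dens_measured = np.divide(realized_counts, realized_area,
                                  out=np.zeros(n_total), where=realized_area > 0)
        exp_d = dens_measured[: config.n_exposed]
        if np.ptp(exp_d) > 0 and np.ptp(exposed_usv) > 0:
            realized_r = float(np.corrcoef(exp_d, exposed_usv)[0, 1])
        else:
            realized_r = float("nan")
        truth_regions[spec.label] = {
            "region": spec.name,
            "category": CATEGORY_BY_EFFECT[spec.effect_type],
            "usv_coupling": spec.usv_coupling,
            "exposure_multiplier": spec.exposure_multiplier,
            "reactivation_prob": spec.reactivation_prob,
            "beta": float(beta),
            "realized_r": realized_r,
        }

    truth = {
        "master_seed": config.master_seed,
        "section_spacing_mm": spacing,
        "regions": truth_regions,
    }
    return SyntheticExperiment(mice=mice, sections=tuple(sections), truth=truth, config=config)


def default_regions() -> tuple[RegionSpec, ...]:
    """The 25-region panel the analysis tracks, with plausible synthetic effects.

    Baseline (no-exposure) tdTomato densities, exposure multipliers and USV
    couplings loosely follow the magnitudes the mapping analysis reports: strong
    positive couplings in rCPu and cPAG, moderate ones in mPFC subregions, negative
    couplings in LS and VMH, exposure-only (social) effects in M2/POA/LHb, and a
    majority of unrelated regions. These are synthetic-study conditions, not
    estimates of any real dataset.
    """
    r = RegionSpec
    cortical = (1.2, 2.8)
    return (
        r("MO", cortical, 17.8, 1.25, 0.647),
        r("LO", cortical, 12.0, 1.0, 0.0),
        r("VO", cortical, 14.0, 1.0, 0.0),
        r("PrL", cortical, 14.0, 1.6, 0.685),
        r("IL", cortical, 16.2, 1.5, 0.635),
        r("Cg1", (0.2, 1.6), 14.1, 1.53, 0.683),
        r("Cg2", (-0.4, 0.6), 12.0, 1.3, 0.587),
        r("M1", (0.6, 2.2), 11.0, 1.0, 0.0),
        r("M2", (0.8, 2.6), 10.0, 1.6, 0.0),
        r("InC", (0.6, 2.2), 6.5, 1.0, 0.0),
        r("Pir", (-0.6, 2.2), 15.0, 1.0, 0.0),
        r("NAc", (0.8, 1.8), 8.0, 1.0, 0.0),
        r("CPu", (0.62, 1.6), 2.8, 1.66, 0.850, label="rCPu", roi_area_mm2=2.0),
        r("CPu", (-1.02, 0.62), 3.0, 1.0, 0.0, label="cCPu", roi_area_mm2=2.0),
        r("CPu", (-2.2, -1.02), 2.5, 1.0, 0.0, label="tCPu", roi_area_mm2=1.5),
        r("LS", (-0.2, 1.0), 10.0, 1.0, -0.649),
        r("POA", (-0.6, 0.4), 12.9, 1.4, 0.0),
        r("VMH", (-2.0, -1.0), 7.5, 1.0, -0.693),
        r("LHb", (-2.0, -1.2), 9.0, 1.6, 0.0),
        r("PVT", (-1.6, -0.2), 12.0, 1.0, 0.0),
        r("CMT", (-2.0, -1.0), 10.0, 1.0, 0.0),
        r("BLA", (-2.2, -0.8), 9.0, 1.0, 0.0),
        r("AmgCM", (-2.0, -0.8), 8.0, 1.0, 0.0),
        r("PAG", (-4.2, -3.0), 12.0, 1.0, 0.0, label="rPAG"),
        r("PAG", (-5.0, -4.2), 13.1, 1.63, 0.834, label="cPAG"),
    )


# ---------------------------------------------------------------------------
# USV audio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UsvAudioSpec:
    """Synthetic ultrasonic recording: linearly frequency-modulated tonal calls over
    a white-noise floor.

    ``calls`` is a list of (start_s, duration_s, f_start_khz, f_end_khz,
    amplitude_db); amplitudes and the noise floor are dB re full scale (the noise
    level is its RMS). Calls must be non-overlapping in time, and call frequencies
    must stay below Nyquist.
    """

    sample_rate_hz: float = 250_000.0
    calls: tuple[tuple[float, float, float, float, float], ...] = ()
    noise_floor_db: float = -60.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        nyq_khz = self.sample_rate_hz / 2e3
        prev_end = -np.inf
        for start, dur, f0, f1, _amp in sorted(self.calls):
            if max(f0, f1) > nyq_khz:
                raise ValueError(
                    f"call frequency {max(f0, f1)} kHz exceeds Nyquist ({nyq_khz} kHz): aliasing"
                )
            if dur <= 0:
                raise ValueError("call duration must be positive")
            if start < prev_end:
                raise ValueError("calls must be non-overlapping in time")
            prev_end = start + dur


def generate_usv_audio(
    spec: UsvAudioSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[dict]]:
    """Render the waveform and return it with the ground-truth event list.

    The waveform is the sum of linearly frequency-modulated tones (1 ms raised-cosine
    onset/offset ramps keep them tonal) and white Gaussian noise at the requested
    floor. Truth events carry start/end times and the start/end frequencies.
    """
    sr = spec.sample_rate_hz
    if spec.duration_s is not None:
        total_s = spec.duration_s
    else:
        total_s = max((s + d for s, d, *_ in spec.calls), default=0.0) + 0.1
    n = int(round(total_s * sr))
    sigma = 10.0 ** (spec.noise_floor_db / 20.0)
    wave = rng.normal(0.0, sigma, n)
    truth = []
    for start, dur, f0_khz, f1_khz, amp_db in sorted(spec.calls):
        i0 = int(round(start * sr))
        m = int(round(dur * sr))
        if i0 + m > n:
            raise ValueError("call extends past the recording duration")
        t = np.arange(m) / sr
        f_inst = (f0_khz + (f1_khz - f0_khz) * t / dur) * 1e3
        phase = 2 * np.pi * np.cumsum(f_inst) / sr
        amp = 10.0 ** (amp_db / 20.0)
        ramp_n = min(int(0.001 * sr), m // 4)
        env = np.ones(m)
        if ramp_n > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
            env[:ramp_n] = ramp
            env[-ramp_n:] = ramp[::-1]
        wave[i0 : i0 + m] += amp * env * np.sin(phase)
        truth.append(
            {
                "start_s": start,
                "end_s": start + dur,
                "f_start_khz": f0_khz,
                "f_end_khz": f1_khz,
                "amplitude_db": amp_db,
            }
        )
    return wave, truth


def make_random_calls(
    n_calls: int,
    rng: np.random.Generator,
    snr_db: float = 20.0,
    noise_floor_db: float = -60.0,
    dur_range_s: tuple[float, float] = (0.03, 0.08),
    gap_range_s: tuple[float, float] = (0.08, 0.2),
    f_range_khz: tuple[float, float] = (50.0, 90.0),
    sweep_khz: float = 15.0,
) -> UsvAudioSpec:
    """Random non-overlapping courtship-like calls at a given tone-to-noise level
    (amplitude_db = noise_floor_db + snr_db)."""
    calls = []
    t = rng.uniform(0.05, 0.15)
    for _ in range(n_calls):
        dur = rng.uniform(*dur_range_s)
        f0 = rng.uniform(*f_range_khz)
        f1 = np.clip(f0 + rng.uniform(-sweep_khz, sweep_khz), 32.0, 118.0)
        calls.append((t, dur, float(f0), float(f1), noise_floor_db + snr_db))
        t += dur + rng.uniform(*gap_range_s)
    return UsvAudioSpec(calls=tuple(calls), noise_floor_db=noise_floor_db)


# ---------------------------------------------------------------------------
# striatal sections
# ---------------------------------------------------------------------------

def default_cp_polygon() -> Polygon:
    """A flat-topped caudoputamen-like outline (right hemisphere), micrometres."""
    return Polygon(
        [
            (1400, 400), (2600, 400), (3200, 800), (3400, 1600),
            (3000, 2400), (2400, 2750), (1700, 2750), (1300, 2300),
            (1100, 1600), (1150, 900),
        ]
    )


def default_striatal_landmarks() -> _striatum.StriatalLandmarks:
    """Landmarks consistent with :func:`default_cp_polygon` (midline near x = 0)."""
    return _striatum.StriatalLandmarks(
        dorsal_edge_left=(-2600.0, 400.0),
        dorsal_edge_right=(2600.0, 400.0),
        ac_point=(0.0, 2600.0),
        nacs_tip=(1200.0, 2500.0),
        lateral_boundary=(3400.0, 1600.0),
    )


@dataclass(frozen=True)
class StriatalSectionSpec:
    """One synthetic striatal section: CP outline, landmarks, striosome blob mask
    and compartment-specific density couplings.

    ``striosome_coupling`` / ``matrix_coupling`` multiply ``base_density_per_mm2``
    inside each compartment and may be a scalar or a per-quadrant dict
    (keys DM/DL/VM/VL) to emulate medially-restricted striosome enrichment.
    """

    cp_polygon: Polygon = field(default_factory=default_cp_polygon)
    landmarks: _striatum.StriatalLandmarks = field(default_factory=default_striatal_landmarks)
    striosome_fraction: float = 0.12
    striosome_blob_radius_um: float = 60.0
    striosome_coupling: float | dict = 1.0
    matrix_coupling: float | dict = 1.0
    base_density_per_mm2: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.striosome_fraction < 0.5):
            raise ValueError("striosome_fraction must be in [0, 0.5)")
        if self.striosome_blob_radius_um <= 0:
            raise ValueError("striosome_blob_radius_um must be positive")
        if self.base_density_per_mm2 < 0:
            raise ValueError("base_density_per_mm2 must be >= 0")

    def coupling(self, compartment: str, quadrant: str) -> float:
        c = self.striosome_coupling if compartment == _striatum.COMPARTMENT_STRIOSOME else self.matrix_coupling
        return float(c[quadrant]) if isinstance(c, dict) else float(c)


def _pack_striosome_blobs(
    cp: Polygon, fraction: float, radius: float, rng: np.random.Generator
) -> list[Polygon]:
    """Disjoint equal-radius disks inside the CP totalling ``fraction`` of its area."""
    if fraction == 0:
        return []
    blob_area = np.pi * radius**2
    n_blobs = max(1, int(round(fraction * cp.area / blob_area)))
    inner = cp.buffer(-radius)
    if inner.is_empty:
        raise ValueError("striosome_blob_radius_um too large for the CP polygon")
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 4000 * n_blobs
    while len(centers) < n_blobs:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "striosome blob packing failed after bounded retries; "
                "use a smaller striosome_blob_radius_um"
            )
        p = _uniform_points_in_polygon(inner, 1, rng)[0]
        if all(np.linalg.norm(p - c) >= 2 * radius for c in centers):
            centers.append(p)
    return [shapely_point_buffer(c, radius) for c in centers]


def shapely_point_buffer(center: np.ndarray, radius: float) -> Polygon:
    from shapely.geometry import Point

    return Point(center).buffer(radius, quad_segs=32)


def generate_striatal_section(
    spec: StriatalSectionSpec, rng: np.random.Generator
) -> tuple[Polygon, _striatum.CompartmentMask, _striatum.StriatalLandmarks, pd.DataFrame]:
    """Generate one striatal section: blob mask plus compartment-coupled cells.

    Cells are an inhomogeneous Poisson process thinned from the maximum rate, with
    rate ``base_density * coupling(compartment, quadrant)``. Only the tdTomato
    channel is rendered (the compartment analysis concerns the tagged ensemble).
    """
    cp = spec.cp_polygon
    if not cp.is_valid or cp.area <= 0:
        raise ValueError("degenerate CP polygon")
    blobs = _pack_striosome_blobs(cp, spec.striosome_fraction, spec.striosome_blob_radius_um, rng)
    mask = _striatum.CompartmentMask(cp_polygon=cp, striosomes=blobs)
    partition = _striatum.construct_quadrants(cp, spec.landmarks)

    couplings = [
        spec.coupling(comp, q)
        for comp in (_striatum.COMPARTMENT_STRIOSOME, _striatum.COMPARTMENT_MATRIX)
        for q in _striatum.QUADRANTS
    ]
    lam_max = spec.base_density_per_mm2 * max(couplings) if couplings else 0.0
    area_mm2 = cp.area / 1e6
    n_cand = rng.poisson(lam_max * area_mm2) if lam_max > 0 else 0
    xy = _uniform_points_in_polygon(cp, n_cand, rng)
    if n_cand:
        import shapely as _sh

        strio_union = mask.striosome_union
        in_strio = (
            _sh.covers(strio_union, _sh.points(xy[:, 0], xy[:, 1]))
            if not strio_union.is_empty
            else np.zeros(n_cand, bool)
        )
        quads = partition.assign(xy[:, 0], xy[:, 1])
        rates = np.array(
            [
                spec.base_density_per_mm2
                * spec.coupling(
                    _striatum.COMPARTMENT_STRIOSOME if s else _striatum.COMPARTMENT_MATRIX, q
                )
                for s, q in zip(in_strio, quads)
            ]
        )
        keep = rng.uniform(0, lam_max, n_cand) < rates
        xy = xy[keep]
    cells = pd.DataFrame(
        {
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "channel": CHANNEL_TDTOMATO,
            "intensity": 40.0 * rng.lognormal(0.0, 0.3, len(xy)),
            "area_um2": rng.gamma(16.0, 5.0, len(xy)),
        }
    )
    return cp, mask, spec.landmarks, cells
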