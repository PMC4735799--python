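"""Synthetic inputs with known ground truth.

The study's raw data are western blots and micrographs, neither of which is
deposited, so the pipeline is exercised on generated stand-ins:

* nuclei images — disk-shaped nuclei scattered around cluster centers with a
  controllable spread, optionally with an enforced minimum edge-to-edge gap
  (so the expected nucleus-nucleus distance index is known by construction);
* phospho-signal time courses — phospho-EGFR from the mechanistic receptor
  model and phospho-ERK from a phenomenological two-pulse curve (the ODE model
  deliberately stops at the receptor), with multiplicative lognormal
  replicate noise mimicking densitometry.

Scenario presets encode the study conditions: equimolar 1.8 nM ligand doses,
a 10-fold surface receptor excess in AREG-cultured cells, 0-60 and 0-310 min
sampling every 10 min, and delayed ERK re-activation starting at 160 min
after an EGF switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .estimation import FitDataset, FitSeries
from .receptor_model import (
    LigandSpec,
    ReceptorModelParams,
    areg,
    default_params,
    egf,
    initial_steady_state,
    readout,
    simulate,
)
from .signal_quant import Replicate, TimeCourseData

__all__ = [
    "ImageSpec",
    "GeneratedImage",
    "PerkShape",
    "ScenarioConfig",
    "GeneratedTimecourse",
    "LayoutInfeasibleError",
    "render_nuclei",
    "gen_nuclei_image",
    "perk_latent",
    "gen_timecourse",
    "scenario_presets",
]

DOSE_NM = 1.8  # equimolar EGF / AREG dose used throughout the study
ACELL_R_SCALE = 10.0  # surface receptor excess of AREG-cultured cells
REACTIVATION_ONSET_MIN = 160.0

_LAYOUT_RETRY_BUDGET = 10_000  # candidate draws per image before giving up


class LayoutInfeasibleError(RuntimeError):
    """Could not place the requested nuclei under the gap constraint."""


# --------------------------------------------------------------------------
# nuclei images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Layout and rendering parameters of a synthetic nuclei image.

    ``min_gap``, when set, enforces a minimum edge-to-edge Chebyshev gap (in
    pixels) between any two nuclei.  ``cluster_sd`` is the Gaussian spread of
    nuclei around their cluster center; small values produce tight clusters.
    """

    width: int = 512
    height: int = 512
    n_nuclei: int = 20
    n_clusters: int = 5
    cluster_sd: float = 30.0
    nucleus_radius: int = 5
    min_gap: int | None = None
    peak_intensity: int = 200
    background_intensity: int = 10
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (self.n_nuclei >= self.n_clusters >= 1):
            raise ValueError("need n_nuclei >= n_clusters >= 1")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if not (self.peak_intensity > self.background_intensity >= 0):
            raise ValueError("peak intensity must exceed background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GeneratedImage:
    image: np.ndarray  # uint8 grayscale
    centers: np.ndarray  # (n_nuclei, 2) integer (row, col) ground truth
    spec: ImageSpec


def render_nuclei(
    centers,
    width: int,
    height: int,
    radius: int = 5,
    peak_intensity: int = 200,
    background_intensity: int = 10,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw solid Euclidean disks at integer (row, col) centers on a flat
    background, add Gaussian noise, and clip to 8-bit range."""
    img = np.full((height, width), float(background_intensity))
    yy, xx = np.mgrid[0:height, 0:width]
    for r, c in np.asarray(centers, dtype=int):
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
        img[disk] = peak_intensity
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _min_center_separation(spec: ImageSpec) -> int | None:
    """Center Chebyshev separation guaranteeing the requested edge gap.

    A disk of radius r fits inside the Chebyshev ball of radius r, so pixel
    sets of two disks are at Chebyshev distance >= center distance - 2r; an
    edge-to-edge gap of g (g empty pixels between the sets) needs center
    distance >= g + 2r + 1.
    """
    if spec.min_gap is None:
        return None
    return spec.min_gap + 2 * spec.nucleus_radius + 1


def gen_nuclei_image(spec: ImageSpec) -> GeneratedImage:
    """Sample a layout (cluster centers uniform, nuclei Gaussian around them),
    render it, and return the image with ground-truth centers.

    Placement is rejection sampling under the frame and ``min_gap``
    constraints with a bounded retry budget; per-seed reproducible (PCG64).
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.nucleus_radius
    lo_row, hi_row = r, spec.height - 1 - r
    lo_col, hi_col = r, spec.width - 1 - r
    if lo_row > hi_row or lo_col > hi_col:
        raise LayoutInfeasibleError("frame smaller than one nucleus")

    cluster_centers = np.column_stack(
        [
            rng.integers(lo_row, hi_row + 1, size=spec.n_clusters),
            rng.integers(lo_col, hi_col + 1, size=spec.n_clusters),
        ]
    )
    sep = _min_center_separation(spec)
    accepted: list[tuple[int, int]] = []
    draws = 0
    for i in range(spec.n_nuclei):
        cluster = cluster_centers[i % spec.n_clusters]
        while True:
            draws += 1
            if draws > _LAYOUT_RETRY_BUDGET:
                raise LayoutInfeasibleError(
                    f"exceeded {_LAYOUT_RETRY_BUDGET} draws placing nucleus "
                    f"{i + 1}/{spec.n_nuclei}"
                )
            cand = np.round(
                cluster + rng.normal(0.0, spec.cluster_sd, size=2)
            ).astype(int)
            if not (lo_row <= cand[0] <= hi_row and lo_col <= cand[1] <= hi_col):
                continue
            if sep is not None and any(
                max(abs(cand[0] - a[0]), abs(cand[1] - a[1])) < sep
                for a in accepted
            ):
                continue
            accepted.append((int(cand[0]), int(cand[1])))
            break

    centers = np.array(accepted, dtype=int)
    img = render_nuclei(
        centers,
        spec.width,
        spec.height,
        radius=r,
        peak_intensity=spec.peak_intensity,
        background_intensity=spec.background_intensity,
        noise_sd=spec.noise_sd,
        rng=rng,
    )
    return GeneratedImage(image=img, centers=centers, spec=spec)


# --------------------------------------------------------------------------
# phospho-signal time courses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PerkShape:
    """Phenomenological phospho-ERK curve: an alpha-shaped immediate pulse
    (zero at t=0, peaking at ``peak_time``) plus an optional re-activation
    pulse that is exactly zero before ``second_onset`` and rises with a
    saturating time constant ``second_tau`` to ``second_amplitude``."""

    peak_time: float = 10.0
    peak_amplitude: float = 1.0
    second_onset: float | None = None
    second_amplitude: float = 0.5
    second_tau: float = 10.0

    def __post_init__(self):
        if self.peak_time <= 0 or self.peak_amplitude <= 0:
            raise ValueError("first pulse must have positive time and amplitude")
        if self.second_onset is not None and self.second_onset <= self.peak_time:
            raise ValueError("re-activation must follow the initial peak")


def perk_latent(shape: PerkShape, times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    tp = shape.peak_time
    y = shape.peak_amplitude * (t / tp) * np.exp(1.0 - t / tp)
    if shape.second_onset is not None:
        dt = t - shape.second_onset
        y = y + np.where(
            dt > 0,
            shape.second_amplitude * (1.0 - np.exp(-np.maximum(dt, 0.0) / shape.second_tau)),
            0.0,
        )
    return y


@dataclass(frozen=True)
class ScenarioConfig:
    """One stimulation scenario: which ligand, which cell state (r_scale),
    the sampling grid, and the replicate noise model."""

    name: str
    ligand: LigandSpec
    r_scale: float
    sampling_times: np.ndarray
    noise_cv: float = 0.1
    n_replicates: int = 3
    perk_shape: PerkShape = field(default_factory=PerkShape)

    def __post_init__(self):
        object.__setattr__(
            self, "sampling_times", np.asarray(self.sampling_times, dtype=float)
        )
        if self.sampling_times.size < 2 or not np.all(
            np.diff(self.sampling_times) > 0
        ):
            raise ValueError("sampling_times must be increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class GeneratedTimecourse:
    """Generated data plus ground truth for recovery tests."""

    fit_dataset: FitDataset  # replicate-mean noisy pEGFR, model units
    pegfr: TimeCourseData  # per-replicate noisy pEGFR
    perk: TimeCourseData  # per-replicate noisy pERK
    latent_pegfr: np.ndarray
    latent_perk: np.ndarray
    scenario: ScenarioConfig
    params: ReceptorModelParams
    seed: int


def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def gen_timecourse(
    scenario: ScenarioConfig,
    params: ReceptorModelParams | None = None,
    seed: int = 0,
) -> GeneratedTimecourse:
    """Simulate the scenario's latent curves and draw noisy replicates.

    pEGFR comes from the mass-action receptor model starting at the
    ligand-free steady state (so it is exactly 0 at t=0); pERK comes from the
    scenario's phenomenological pulse shape.  Each observation is the latent
    value times an independent unit-mean lognormal factor.
    """
    if params is None:
        params = default_params()
    p = replace(params, r_scale=scenario.r_scale)
    t = scenario.sampling_times
    grid = t if t[0] == 0.0 else np.concatenate(([0.0], t))
    traj = simulate(p, scenario.ligand, grid, initial_steady_state(p))
    latent_pegfr = readout(traj, "pEGFR_total")
    if t[0] != 0.0:
        latent_pegfr = latent_pegfr[1:]
    latent_perk = perk_latent(scenario.perk_shape, t)

    rng = np.random.default_rng(seed)
    shape = (scenario.n_replicates, t.size)
    pegfr_obs = latent_pegfr * _lognormal_factors(rng, scenario.noise_cv, shape)
    perk_obs = latent_perk * _lognormal_factors(rng, scenario.noise_cv, shape)

    pegfr_tc = TimeCourseData(
        condition=scenario.name,
        target="pEGFR",
        replicates=tuple(Replicate(t, row) for row in pegfr_obs),
    )
    perk_tc = TimeCourseData(
        condition=scenario.name,
        target="pERK",
        replicates=tuple(Replicate(t, row) for row in perk_obs),
    )
    fit = FitDataset(
        series=(
            FitSeries(
                condition=scenario.name,
                ligand=scenario.ligand,
                r_scale=scenario.r_scale,
                readout_kind="pEGFR_total",
                times=t,
                observed=pegfr_obs.mean(axis=0),
            ),
        )
    )
    return GeneratedTimecourse(
        fit_dataset=fit,
        pegfr=pegfr_tc,
        perk=perk_tc,
        latent_pegfr=latent_pegfr,
        latent_perk=latent_perk,
        scenario=scenario,
        params=p,
        seed=seed,
    )


def scenario_presets() -> list[ScenarioConfig]:
    """The four study scenarios.

    Short grid: 0-60 min every 10 min (immediate response); long grid:
    0-310 min every 10 min (re-activation).  The EGF-switch scenario in
    AREG-cultured cells programs the delayed ERK pulse at 160 min.  pERK
    amplitudes are generator conventions: the AREG immediate pulse is set
    2.1-fold below the EGF one, mirroring the weaker ERK response.
    """
    short = np.arange(0.0, 61.0, 10.0)
    long = np.arange(0.0, 311.0, 10.0)
    return [
        ScenarioConfig(
            name="E-EGF", ligand=egf(DOSE_NM), r_scale=1.0,
            sampling_times=short, perk_shape=PerkShape(peak_amplitude=1.0),
        ),
        ScenarioConfig(
            name="E-AREG", ligand=areg(DOSE_NM), r_scale=1.0,
            sampling_times=short,
            perk_shape=PerkShape(peak_amplitude=1.0 / 2.1),
        ),
        ScenarioConfig(
            name="A-AREG", ligand=areg(DOSE_NM), r_scale=ACELL_R_SCALE,
            sampling_times=short, perk_shape=PerkShape(peak_amplitude=1.0),
        ),
        ScenarioConfig(
            name="A-EGF-switch", ligand=egf(DOSE_NM), r_scale=ACELL_R_SCALE,
            sampling_times=long,
            perk_shape=PerkShape(
                peak_amplitude=1.0,
                second_onset=REACTIVATION_ONSET_MIN,
                second_amplitude=0.5,
                second_tau=10.0,
            ),
        ),
    ]
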