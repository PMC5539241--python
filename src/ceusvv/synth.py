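"""Synthetic CEUS cine loops and graded-atherosclerosis cohorts.

This module is the study-design generator: it renders long-axis vessel
phantoms (lumen band flanked by two adventitial bands, optional intraluminal
plaque), drives each compartment with destruction–replenishment kinetics,
and links a latent adventitial vasa-vasorum density to both the adventitial
enhancement amplitude and paired two-observer CD31/VEGF microvessel counts.

The six-group default emulates a graded carotid-atherosclerosis design:
group 0 is a chow-fed control, groups 1–3 receive a high-fat diet for
increasing durations, group 4 adds balloon endothelial injury producing a
small (<50% stenosis) plaque, and group 5 a near-occlusive plaque.  The
occlusive group has no usable luminal reference, so it contributes
histology only — its normalized MVE is never computed downstream.

Latent density calibration: group densities default to the group-mean
normalized enhancements the pipeline should recover (0.146, 0.278, 0.435,
0.660, 0.660), with the occlusive group at 1.10; with the default unit
gain-to-lumen ratio the true per-animal enhancement ratio equals the
per-animal latent density, so ground truth stays analytically transparent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError
from .imaging import (
    CineLoop,
    RoiPolygon,
    TimeIntensityCurve,
    estimate_background,
    extract_tic,
    rasterize_roi,
)
from .kinetics import KineticsParams, replenishment_intensity
from .quantify import (
    OCCLUSIVE_GROUP,
    AnimalRecord,
    build_cohort_table,
    compute_mve,
    normalized_mve,
)

__all__ = [
    "PhantomGeometry",
    "GroupSpec",
    "MarkerParams",
    "CohortConfig",
    "HistologyCounts",
    "AnimalSim",
    "CohortSimulation",
    "render_cine_loop",
    "simulate_histology_counts",
    "simulate_cohort",
    "default_phantom",
    "default_rois",
    "default_cohort_config",
    "calibrate_marker",
    "true_density_count_correlation",
    "marker_for_target_correlation",
    "DEFAULT_GROUP_DENSITIES",
]

TRUTH_COLUMNS = [
    "animal_id",
    "group_id",
    "true_density",
    "true_adv_amplitude",
    "true_lumen_amplitude",
    "true_nmve",
    "lambda_cd31",
    "lambda_vegf",
]

#: default latent vasa-vasorum density per group (0..5); groups 0–4 equal the
#: group-mean enhancement ratios the pipeline should recover, the occlusive
#: group is set above group 4 to reproduce the abrupt histology increase
DEFAULT_GROUP_DENSITIES = (0.146, 0.278, 0.435, 0.660, 0.660, 1.10)


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomGeometry:
    """Idealized 2-D long-axis vessel phantom.

    Rows are split into a luminal band and two flanking adventitial bands
    (half-open row intervals); everything else is background tissue.  An
    optional plaque polygon sits inside the luminal band.
    """

    image_height: int
    image_width: int
    lumen_band: tuple[int, int]
    adventitia_bands: tuple[tuple[int, int], tuple[int, int]]
    plaque_polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        h, w = self.image_height, self.image_width
        if h < 1 or w < 1:
            raise ConfigurationError("image dimensions must be positive")
        bands = [self.lumen_band, *self.adventitia_bands]
        for lo, hi in bands:
            if not (0 <= lo < hi <= h):
                raise ConfigurationError(f"band ({lo}, {hi}) outside image rows")
        # pairwise disjoint row intervals
        ordered = sorted(bands)
        for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
            if b0 < a1:
                raise ConfigurationError("compartment bands overlap")
        if self.plaque_polygon is not None:
            object.__setattr__(
                self, "plaque_polygon", np.asarray(self.plaque_polygon, float)
            )

    def masks(self) -> dict[str, np.ndarray]:
        """Boolean compartment masks: lumen, adventitia, background and
        (when a plaque polygon is present) plaque.

        Plaque pixels are carved out of the luminal band.  Raises
        :class:`ConfigurationError` if any compartment ends up empty or the
        plaque escapes the lumen / touches the adventitia.
        """
        h, w = self.image_height, self.image_width
        rows = np.arange(h)[:, None]
        lumen = np.broadcast_to(
            (rows >= self.lumen_band[0]) & (rows < self.lumen_band[1]), (h, w)
        ).copy()
        adventitia = np.zeros((h, w), bool)
        for lo, hi in self.adventitia_bands:
            adventitia |= np.broadcast_to((rows >= lo) & (rows < hi), (h, w))
        out = {}
        if self.plaque_polygon is not None:
            plaque = rasterize_roi(
                RoiPolygon("plaque", self.plaque_polygon), (h, w)
            )
            if (plaque & ~lumen).any():
                raise ConfigurationError("plaque extends outside the lumen band")
            if (plaque & adventitia).any():
                raise ConfigurationError("plaque intersects the adventitia")
            lumen &= ~plaque
            out["plaque"] = plaque
        out["lumen"] = lumen
        out["adventitia"] = adventitia
        out["background"] = ~(lumen | adventitia | out.get("plaque", np.zeros((h, w), bool)))
        for name, m in out.items():
            if not m.any():
                raise ConfigurationError(f"compartment {name!r} is empty")
        return out


def render_cine_loop(
    geometry: PhantomGeometry,
    lumen_kinetics: KineticsParams,
    adventitia_kinetics: KineticsParams,
    plaque_kinetics: KineticsParams | None = None,
    *,
    noise_sd: float = 0.0,
    frame_rate: float,
    duration: float,
    seed=None,
    background_level: float = 20.0,
    destruction_time: float | None = None,
) -> CineLoop:
    """Render a phantom cine loop.

    Frame count is ``floor(duration * frame_rate) + 1`` with frame k at time
    ``k / frame_rate``; each pixel's noiseless value is its compartment's
    replenishment curve at the frame time (background pixels hold a constant
    tissue level).  Additive Gaussian noise of standard deviation
    ``noise_sd`` is applied and the result clipped to [0, 255].

    ``seed`` may be an int or a :class:`numpy.random.Generator`.  The
    destruction time recorded on the loop defaults to the luminal onset.
    """
    if duration < 0 or frame_rate <= 0:
        raise ConfigurationError("duration must be >= 0 and frame_rate > 0")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    masks = geometry.masks()
    if ("plaque" in masks) != (plaque_kinetics is not None):
        raise ConfigurationError(
            "plaque kinetics must be given exactly when the geometry has a plaque"
        )
    n_frames = int(np.floor(duration * frame_rate)) + 1
    times = np.arange(n_frames) / frame_rate
    h, w = geometry.image_height, geometry.image_width
    frames = np.full((n_frames, h, w), float(background_level))
    compartments = {
        "lumen": lumen_kinetics,
        "adventitia": adventitia_kinetics,
    }
    if plaque_kinetics is not None:
        compartments["plaque"] = plaque_kinetics
    for name, params in compartments.items():
        curve = replenishment_intensity(params, times)
        frames[:, masks[name]] = curve[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, 255.0)
    if destruction_time is None:
        destruction_time = lumen_kinetics.onset_time
    return CineLoop(frames=frames, timestamps=times, destruction_time=destruction_time)


# ---------------------------------------------------------------------------
# Histology count simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerParams:
    """Poisson link from latent density to a marker's microvessel count.

    Expected count per cross-section is ``a + b * density``; both
    coefficients are non-negative so the rate is valid for any density.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise InvalidParameterError("marker coefficients must be >= 0")

    def rate(self, density: float) -> float:
        lam = self.a + self.b * density
        if lam < 0:
            raise InvalidParameterError("negative Poisson rate")
        return lam


@dataclass(frozen=True)
class HistologyCounts:
    """Per-observer counts and their arithmetic mean for one marker."""

    observer_counts: tuple[int, ...]
    mean: float
    expected: float


def simulate_histology_counts(
    vv_density: float,
    marker: MarkerParams,
    n_observers: int = 2,
    rng=None,
) -> HistologyCounts:
    """Independent per-observer Poisson counts at rate ``a + b * density``.

    Each observer counts the same cross-section independently; the summary
    used for analysis is the arithmetic mean of the observer counts.
    """
    if vv_density < 0:
        raise InvalidParameterError("vv_density must be >= 0")
    if n_observers < 1:
        raise InvalidParameterError("need at least one observer")
    lam = marker.rate(vv_density)
    rng = np.random.default_rng(rng)
    counts = tuple(int(c) for c in rng.poisson(lam, n_observers))
    return HistologyCounts(
        observer_counts=counts,
        mean=float(np.mean(counts)),
        expected=lam,
    )


def calibrate_marker(
    control_density: float,
    control_mean: float,
    early_density: float,
    early_mean: float,
) -> MarkerParams:
    """Fit ``a + b * density`` through two (density, mean count) anchors.

    Uses the exact two-point line when its intercept is non-negative;
    otherwise clamps ``a = 0`` and takes the least-squares slope through the
    two anchors, the closest valid Poisson link.
    """
    b = (early_mean - control_mean) / (early_density - control_density)
    a = control_mean - b * control_density
    if a < 0 or b < 0:
        d = np.array([control_density, early_density])
        m = np.array([control_mean, early_mean])
        b = float((d * m).sum() / (d * d).sum())
        a = 0.0
    return MarkerParams(a=a, b=b)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of the graded-atherosclerosis design."""

    group_id: int
    n_animals: int
    vv_density: float
    lumen_amplitude: float = 100.0
    plaque_present: bool = False
    plaque_occlusive: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.group_id <= 5:
            raise ConfigurationError("group_id must be in 0..5")
        if self.n_animals < 0:
            raise ConfigurationError("n_animals must be >= 0")
        if self.vv_density < 0:
            raise ConfigurationError("vv_density must be >= 0")
        if self.lumen_amplitude <= 0:
            raise ConfigurationError("lumen_amplitude must be > 0")
        if self.plaque_present and self.group_id not in (4, 5):
            raise ConfigurationError("plaque only occurs in groups 4 and 5")
        if self.plaque_occlusive and self.group_id != OCCLUSIVE_GROUP:
            raise ConfigurationError("occlusive plaque only occurs in group 5")
        if self.plaque_occlusive and not self.plaque_present:
            raise ConfigurationError("occlusive plaque requires plaque_present")


# defaults for the markers: anchored at the control density and the
# early-atherosclerosis (diet-only, groups 1–2) mean density
_D_CONTROL = DEFAULT_GROUP_DENSITIES[0]
_D_EARLY = (DEFAULT_GROUP_DENSITIES[1] + DEFAULT_GROUP_DENSITIES[2]) / 2.0
DEFAULT_VEGF = calibrate_marker(_D_CONTROL, 1.30, _D_EARLY, 3.58)
DEFAULT_CD31 = calibrate_marker(_D_CONTROL, 1.90, _D_EARLY, 6.21)


@dataclass(frozen=True)
class CohortConfig:
    """All free parameters of the cohort simulator.

    Defaults define the study conditions: 8-bit linear intensity scale,
    additive Gaussian imaging noise (sd 4), 5 fps for 30 s with the
    destruction pulse at 2 s, unit density-to-amplitude gain relative to the
    luminal amplitude (so true enhancement ratios equal latent densities),
    lognormal per-animal biological variability with sigma 0.5 (mean 1), and
    two histology observers.
    """

    groups: tuple[GroupSpec, ...]
    noise_sd: float = 4.0
    frame_rate: float = 5.0
    duration: float = 30.0
    destruction_time: float = 2.0
    density_to_amplitude_gain: float = 100.0
    lognormal_sigma: float = 0.5
    cd31: MarkerParams = DEFAULT_CD31
    vegf: MarkerParams = DEFAULT_VEGF
    baseline_lumen: float = 5.0
    baseline_tissue: float = 20.0
    lumen_rate: float = 1.0
    adventitia_rate: float = 0.4
    plaque_rate: float = 0.25
    image_height: int = 64
    image_width: int = 64
    n_observers: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("group list is empty")
        ids = [g.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate group ids")
        if self.noise_sd < 0 or self.density_to_amplitude_gain < 0:
            raise ConfigurationError("noise_sd and gain must be >= 0")
        if self.lognormal_sigma < 0:
            raise ConfigurationError("lognormal_sigma must be >= 0")
        if self.duration * self.frame_rate < 1:
            raise ConfigurationError("need at least 2 frames (duration * frame_rate >= 1)")
        if not 0 < self.destruction_time <= self.duration:
            raise ConfigurationError("destruction_time must lie in (0, duration]")
        if self.destruction_time * self.frame_rate < 1:
            raise ConfigurationError("no frame precedes the destruction pulse")

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [asdict(g) for g in self.groups]
        d["cd31"] = asdict(self.cd31)
        d["vegf"] = asdict(self.vegf)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["groups"] = tuple(GroupSpec(**g) for g in d["groups"])
        d["cd31"] = MarkerParams(**d["cd31"])
        d["vegf"] = MarkerParams(**d["vegf"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_cohort_config(
    n_per_group: int = 10,
    seed: int = 0,
    include_occlusive: bool = True,
    **overrides,
) -> CohortConfig:
    """The six-group default design (group 5 optional)."""
    groups = []
    for gid, dens in enumerate(DEFAULT_GROUP_DENSITIES):
        if gid == OCCLUSIVE_GROUP and not include_occlusive:
            continue
        groups.append(
            GroupSpec(
                group_id=gid,
                n_animals=n_per_group,
                vv_density=dens,
                plaque_present=gid in (4, 5),
                plaque_occlusive=gid == OCCLUSIVE_GROUP,
            )
        )
    return CohortConfig(groups=tuple(groups), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Default phantom and measurement ROIs per group
# ---------------------------------------------------------------------------

def default_phantom(
    config: CohortConfig, plaque_present: bool, plaque_occlusive: bool
) -> PhantomGeometry:
    """Long-axis phantom scaled to the configured image size.

    The lumen occupies the central quarter of rows, flanked by adventitial
    bands; a small plaque fills the distal lower lumen, an occlusive plaque
    most of the distal lumen.
    """
    h, w = config.image_height, config.image_width
    lum = (int(h * 0.375), int(h * 0.625))
    adv = (
        (int(h * 0.25), int(h * 0.344)),
        (int(h * 0.656), int(h * 0.75)),
    )
    plaque = None
    if plaque_present:
        if plaque_occlusive:
            x0, y0 = w * 0.53, lum[0] + 0.1
            x1, y1 = w * 0.97, lum[1] - 0.1
        else:
            x0, y0 = w * 0.62, lum[1] - (lum[1] - lum[0]) * 0.45
            x1, y1 = w * 0.94, lum[1] - 0.1
        plaque = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    return PhantomGeometry(
        image_height=h,
        image_width=w,
        lumen_band=lum,
        adventitia_bands=adv,
        plaque_polygon=plaque,
    )


def default_rois(geometry: PhantomGeometry) -> dict[str, RoiPolygon]:
    """Measurement ROIs for a phantom: adventitia (upper band) and a luminal
    reference drawn proximal (left) of any plaque."""
    w = geometry.image_width
    (a0, a1), _ = geometry.adventitia_bands
    l0, l1 = geometry.lumen_band
    rois = {
        "adventitia": RoiPolygon(
            "adventitia",
            np.array([[w * 0.06, a0], [w * 0.94, a0], [w * 0.94, a1], [w * 0.06, a1]]),
        ),
        "lumen": RoiPolygon(
            "lumen",
            np.array(
                [
                    [w * 0.06, l0 + 1],
                    [w * 0.44, l0 + 1],
                    [w * 0.44, l1 - 1],
                    [w * 0.06, l1 - 1],
                ]
            ),
        ),
    }
    if geometry.plaque_polygon is not None:
        rois["plaque"] = RoiPolygon("plaque", geometry.plaque_polygon)
    return rois


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class AnimalSim:
    """One simulated animal: imaging data, histology, and ground truth."""

    animal_id: str
    group_id: int
    tics: dict[str, TimeIntensityCurve]
    loop: CineLoop | None
    cd31: HistologyCounts
    vegf: HistologyCounts
    true_density: float
    true_adv_amplitude: float
    true_lumen_amplitude: float

    @property
    def true_nmve(self) -> float:
        return self.true_adv_amplitude / self.true_lumen_amplitude


@dataclass
class CohortSimulation:
    """Output bundle of :func:`simulate_cohort`."""

    config: CohortConfig
    animals: list[AnimalSim]
    cohort: pd.DataFrame
    truth: pd.DataFrame


def _animal_kinetics(config: CohortConfig, group: GroupSpec, adv_amp: float):
    t0 = config.destruction_time
    lumen = KineticsParams(
        config.baseline_lumen, group.lumen_amplitude, config.lumen_rate, t0
    )
    adventitia = KineticsParams(
        config.baseline_tissue, adv_amp, config.adventitia_rate, t0
    )
    plaque = None
    if group.plaque_present:
        plaque = KineticsParams(
            config.baseline_tissue, 0.5 * adv_amp, config.plaque_rate, t0
        )
    return lumen, adventitia, plaque


def _synthesize_tic(
    params: KineticsParams,
    times: np.ndarray,
    label: str,
    n_pixels: int,
    noise_sd: float,
    rng,
) -> TimeIntensityCurve:
    # direct ROI-mean synthesis: the mean of n iid pixel noises has
    # sd = noise_sd / sqrt(n); clipping is negligible away from 0/255
    curve = replenishment_intensity(params, times)
    if noise_sd > 0:
        curve = curve + rng.normal(0.0, noise_sd / np.sqrt(n_pixels), times.size)
    return TimeIntensityCurve(
        times=times,
        intensities=np.clip(curve, 0.0, 255.0),
        roi_label=label,
        n_pixels=n_pixels,
        smoothing="none",
    )


def simulate_cohort(config: CohortConfig, render: str = "frames") -> CohortSimulation:
    """Simulate a full cohort and quantify it.

    ``render="frames"`` renders every animal's cine loop and extracts TICs
    through the default measurement ROIs; ``render="tics"`` synthesizes the
    ROI-mean TICs directly (statistically equivalent up to clipping, far
    cheaper).  Each animal draws, in fixed order, a lognormal biological
    multiplier on its latent density, two-observer CD31 and VEGF counts, and
    imaging noise, from a per-animal child of the configured seed — so the
    whole simulation is reproducible bit-for-bit.

    Returns the per-animal simulations, the validated cohort table (the
    occlusive group's normalized MVE left missing) and the ground-truth
    table.
    """
    if render not in ("frames", "tics"):
        raise InvalidParameterError("render must be 'frames' or 'tics'")
    n_frames = int(np.floor(config.duration * config.frame_rate)) + 1
    times = np.arange(n_frames) / config.frame_rate
    mu = -0.5 * config.lognormal_sigma**2

    # per-group geometry, ROIs, and ROI pixel counts (shared within a group)
    geo_cache: dict[int, tuple] = {}
    for g in config.groups:
        geom = default_phantom(config, g.plaque_present, g.plaque_occlusive)
        rois = default_rois(geom)
        npix = {
            name: int(rasterize_roi(r, (geom.image_height, geom.image_width)).sum())
            for name, r in rois.items()
        }
        geo_cache[g.group_id] = (geom, rois, npix)

    n_total = sum(g.n_animals for g in config.groups)
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    animals: list[AnimalSim] = []
    records: list[AnimalRecord] = []
    idx = 0
    for g in sorted(config.groups, key=lambda s: s.group_id):
        geom, rois, npix = geo_cache[g.group_id]
        for k in range(g.n_animals):
            rng = np.random.default_rng(children[idx])
            idx += 1
            L = rng.lognormal(mu, config.lognormal_sigma) if config.lognormal_sigma else 1.0
            d_i = g.vv_density * L
            adv_amp = config.density_to_amplitude_gain * d_i
            cd31 = simulate_histology_counts(d_i, config.cd31, config.n_observers, rng)
            vegf = simulate_histology_counts(d_i, config.vegf, config.n_observers, rng)
            lum_k, adv_k, plq_k = _animal_kinetics(config, g, adv_amp)
            loop = None
            if render == "frames":
                loop = render_cine_loop(
                    geom,
                    lum_k,
                    adv_k,
                    plq_k,
                    noise_sd=config.noise_sd,
                    frame_rate=config.frame_rate,
                    duration=config.duration,
                    seed=rng,
                    background_level=config.baseline_tissue,
                    destruction_time=config.destruction_time,
                )
                tics = {
                    name: extract_tic(loop, roi)
                    for name, roi in rois.items()
                    if name in ("adventitia", "lumen")
                }
            else:
                params = {"adventitia": adv_k, "lumen": lum_k}
                tics = {
                    name: _synthesize_tic(
                        params[name], times, name, npix[name], config.noise_sd, rng
                    )
                    for name in ("adventitia", "lumen")
                }
            animal_id = f"g{g.group_id}a{k:03d}"
            animals.append(
                AnimalSim(
                    animal_id=animal_id,
                    group_id=g.group_id,
                    tics=tics,
                    loop=loop,
                    cd31=cd31,
                    vegf=vegf,
                    true_density=d_i,
                    true_adv_amplitude=adv_amp,
                    true_lumen_amplitude=g.lumen_amplitude,
                )
            )
            nmve = None
            if not g.plaque_occlusive:
                mves = {
                    name: compute_mve(
                        tic,
                        estimate_background(
                            tic, destruction_time=config.destruction_time
                        ),
                    )
                    for name, tic in tics.items()
                }
                nmve = normalized_mve(mves["adventitia"], mves["lumen"]).value
            records.append(
                AnimalRecord(
                    animal_id=animal_id,
                    group_id=g.group_id,
                    nmve=nmve,
                    cd31_mean=cd31.mean,
                    vegf_mean=vegf.mean,
                )
            )

    cohort = build_cohort_table(records)
    truth = pd.DataFrame(
        [
            {
                "animal_id": a.animal_id,
                "group_id": a.group_id,
                "true_density": a.true_density,
                "true_adv_amplitude": a.true_adv_amplitude,
                "true_lumen_amplitude": a.true_lumen_amplitude,
                "true_nmve": a.true_nmve,
                "lambda_cd31": a.cd31.expected,
                "lambda_vegf": a.vegf.expected,
            }
            for a in animals
        ],
        columns=TRUTH_COLUMNS,
    )
    return CohortSimulation(config=config, animals=animals, cohort=cohort, truth=truth)


# ---------------------------------------------------------------------------
# Analytic truth for the density–count linkage
# ---------------------------------------------------------------------------

def _density_moments(config: CohortConfig) -> tuple[float, float]:
    """Mean and variance of the per-animal latent density over the groups
    that contribute a normalized MVE (occlusive group excluded)."""
    groups = [g for g in config.groups if not g.plaque_occlusive]
    n = sum(g.n_animals for g in groups)
    if n == 0:
        raise ConfigurationError("no non-occlusive animals")
    w = np.array([g.n_animals / n for g in groups])
    d = np.array([g.vv_density for g in groups])
    v = np.expm1(config.lognormal_sigma**2)  # Var(L), E[L] = 1
    mean = float(w @ d)
    second = float(w @ (d**2) * (1.0 + v))
    return mean, second - mean**2


def true_density_count_correlation(config: CohortConfig, marker: MarkerParams) -> float:
    """Population Pearson correlation between the per-animal true
    enhancement ratio and the observer-mean count for ``marker``.

    With count rate ``a + b * D`` and ``n_obs`` independent Poisson
    observers, ``rho = b * Var(D) / sqrt(Var(D) * (b^2 Var(D) + E[rate]/n_obs))``
    where ``D`` is the latent density over the non-occlusive mixture.
    """
    mean_d, var_d = _density_moments(config)
    if var_d <= 0 or marker.b == 0:
        raise ConfigurationError("degenerate linkage: no density variance or zero slope")
    e_lam = marker.rate(mean_d)
    var_c = marker.b**2 * var_d + e_lam / config.n_observers
    return float(marker.b * var_d / np.sqrt(var_d * var_c))


def marker_for_target_correlation(
    config: CohortConfig, target_rho: float, slope: float = 2.0
) -> MarkerParams:
    """Choose marker coefficients giving a target true density–count
    correlation at a fixed slope.

    Solves ``E[rate] = n_obs * b^2 Var(D) (1/rho^2 - 1)`` for the intercept;
    raises if the implied intercept is negative (lower the slope)."""
    if not 0 < target_rho < 1:
        raise InvalidParameterError("target_rho must be in (0, 1)")
    mean_d, var_d = _density_moments(config)
    e_lam = config.n_observers * slope**2 * var_d * (1.0 / target_rho**2 - 1.0)
    a = e_lam - slope * mean_d
    if a < 0:
        raise InvalidParameterError(
            f"slope {slope} too steep for rho={target_rho}; implied intercept {a:.3f} < 0"
        )
    return MarkerParams(a=a, b=slope)
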