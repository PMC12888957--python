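"""Ground-truth track populations and confocal-like renderings.

The generator emulates the out-of-field charged-particle field seen by a
track detector placed behind a proton target volume:

* a Poisson number of ion tracks per unit area (default areal density
  5e4 per cm^2 per Gy of target dose),
* a right-skewed polar-angle distribution (scaled Beta with mode near 20
  degrees and little mass beyond 50 degrees),
* a low-LET bulk (truncated lognormal below 25 keV/um) with a small
  (default 1%) high-LET admixture drawn log-uniformly on [25, 500] keV/um,
* short delta-electron stubs visible in only 3-4 consecutive slices,
* alpha-reference irradiations of near-normal incidence and constant
  nominal LET with ranges below 16 um.

Rendering places one anisotropic Gaussian spot per slice along each track;
the in-plane elongation grows with tan(theta) (circular spots at normal
incidence turning elliptical and finally line-like), while the spot peak
amplitude is ``intensity_model(LET) * y(theta)`` with the same invertible
LET calibration and logistic angle model used by the analysis.  Noise is
additive Gaussian background plus Poisson shot noise on the spot signal.

Every rendered spot is recorded in a manifest mapping it back to its source
track, so detection, linking and dosimetry can be validated against exact
ground truth.  Depths are nominal stage depths (no refractive-index
rescaling), matching the analysis convention.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibrate import AngleCorrectionModel, LETCalibration, eval_angle_correction
from .detect import DEFAULT_PIXEL_UM, DEFAULT_SLICE_DEPTHS_UM, ImageStack
from .errors import ConfigurationError

__all__ = [
    "GroundTruthTrack",
    "NoiseConfig",
    "FieldConfig",
    "sample_tracks",
    "render_stack",
    "generate_alpha_region",
    "generate_phase_space",
    "simulate_readout",
    "PHASE_SPACE_COLUMNS",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class NoiseConfig:
    background_mean: float = 100.0
    background_sd: float = 8.0
    spot_amplitude_scale: float = 1.0   # emulates detector sensitivity
    psf_sigma_xy_um: float = 0.4
    psf_sigma_z_um: float = 0.4         # soft axial cut-off at track end
    shot_noise: bool = True

    def __post_init__(self):
        if self.background_sd < 0 or self.psf_sigma_xy_um <= 0 \
                or self.psf_sigma_z_um <= 0 or self.spot_amplitude_scale <= 0:
            raise ConfigurationError("noise scale parameters must be positive")


_DEFAULT_LET_DISTRIBUTIONS = {
    "low": {"family": "lognormal", "median": 2.0, "sigma": 0.6,
            "min": 0.5, "max": 25.0},
    "high": {"family": "loguniform", "min": 25.0, "max": 500.0},
    "delta": {"family": "lognormal", "median": 1.0, "sigma": 0.4,
              "min": 0.4, "max": 5.0},
}

_DEFAULT_ANGLE_DISTRIBUTION = {
    "family": "beta", "alpha": 2.2, "beta": 5.2, "max_deg": 90.0,
}

# Species mix of the scored charged particles behind the target: recoil
# protons dominate the fluence (~90%), deuterons ~10%, heavier fragments
# below 1% but carrying most of the high-LET tail.
_DEFAULT_SPECIES = {
    "proton":   {"z": 1, "a": 1, "fraction": 0.885, "e_per_u_mev": (3.0, 170.0)},
    "deuteron": {"z": 1, "a": 2, "fraction": 0.100, "e_per_u_mev": (3.0, 120.0)},
    "triton":   {"z": 1, "a": 3, "fraction": 0.004, "e_per_u_mev": (3.0, 100.0)},
    "helium-3": {"z": 2, "a": 3, "fraction": 0.002, "e_per_u_mev": (2.0, 100.0)},
    "helium-4": {"z": 2, "a": 4, "fraction": 0.007, "e_per_u_mev": (1.0, 40.0)},
    "Z>2":      {"z": 6, "a": 12, "fraction": 0.002, "e_per_u_mev": (5.0, 50.0)},
}


@dataclass
class FieldConfig:
    """Study conditions of a synthetic out-of-field exposure."""

    fluence_per_cm2: float = 5.0e4      # ion tracks per cm^2 (per target Gy)
    target_dose_gy: float = 1.0
    low_let_fraction: float = 0.99
    delta_fraction: float = 0.15        # delta stubs per ion track
    let_distributions: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 _DEFAULT_LET_DISTRIBUTIONS.items()})
    angle_distribution: dict = field(
        default_factory=lambda: dict(_DEFAULT_ANGLE_DISTRIBUTION))
    species: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 _DEFAULT_SPECIES.items()})
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    # readout geometry
    n_slices: int = 11
    slice_start_um: float = 2.0
    slice_step_um: float = 2.0
    fov_um: float = 100.0
    n_pixels: int = 512
    sample_margin_um: float = 30.0      # stationary sampling border
    # ranges (depth the particle can still reach, um)
    ion_residual_depth_um: tuple = (1000.0, 1000.0)
    high_let_residual_depth_um: tuple = (12.0, 22.0)
    delta_residual_depth_um: tuple = (6.0, 8.9)
    alpha_residual_depth_um: float = 15.0
    alpha_nominal_let: float = 100.0
    # shared calibration used when rendering
    angle_model: AngleCorrectionModel = field(
        default_factory=lambda: AngleCorrectionModel(0.79, 0.15, 15.0))
    let_calibration: LETCalibration = field(
        default_factory=LETCalibration.default)

    def __post_init__(self):
        if not 0 <= self.low_let_fraction <= 1:
            raise ConfigurationError("low_let_fraction must be in [0, 1]")
        if self.fluence_per_cm2 < 0:
            raise ConfigurationError("fluence_per_cm2 must be >= 0")
        total = sum(v["fraction"] for v in self.species.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"species fractions must sum to 1, got {total}")

    @property
    def slice_depths_um(self) -> np.ndarray:
        return self.slice_start_um + self.slice_step_um * np.arange(self.n_slices)

    @property
    def pixel_um(self) -> float:
        return self.fov_um / self.n_pixels

    def intensity_model(self, let_kev_um):
        """Normal-incidence spot peak amplitude for a given LET (a.u.)."""
        return self.let_calibration.intensity_from_let(let_kev_um)


@dataclass
class GroundTruthTrack:
    """One simulated particle entering the detector surface."""

    species_label: str
    let_water: float            # keV/um, > 0
    polar_deg: float            # [0, 90)
    azimuth_deg: float          # [0, 360)
    entry_xy: tuple             # um; may lie outside the FOV (margin tracks)
    residual_depth: float       # um of depth the particle can still reach
    kind: str                   # ion | delta | alpha_ref

    def __post_init__(self):
        if not (0 <= self.polar_deg < 90):
            raise ConfigurationError("polar_deg must be in [0, 90)")
        if self.let_water <= 0:
            raise ConfigurationError("let_water must be > 0")
        if self.kind not in ("ion", "delta", "alpha_ref"):
            raise ConfigurationError(f"unknown track kind {self.kind!r}")


# --------------------------------------------------------------------------
# Distribution sampling
# --------------------------------------------------------------------------

def _sample_distribution(spec: dict, n: int, rng: np.random.Generator,
                         name: str) -> np.ndarray:
    family = spec.get("family")
    if family == "lognormal":
        med, sig = spec["median"], spec["sigma"]
        lo, hi = spec.get("min", 0.0), spec.get("max", np.inf)
        out = np.empty(n)
        filled = 0
        while filled < n:  # truncation by resampling
            draw = rng.lognormal(np.log(med), sig, size=max(n - filled, 16))
            draw = draw[(draw >= lo) & (draw <= hi)]
            take = min(draw.size, n - filled)
            out[filled:filled + take] = draw[:take]
            filled += take
        return out
    if family == "loguniform":
        lo, hi = spec["min"], spec["max"]
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if family == "uniform":
        return rng.uniform(spec["min"], spec["max"], size=n)
    if family == "beta":
        return spec.get("max_deg", 90.0) * rng.beta(spec["alpha"], spec["beta"],
                                                    size=n)
    if family == "constant":
        return np.full(n, float(spec["value"]))
    raise ConfigurationError(
        f"unknown distribution family {family!r} in field {name!r}")


def _sample_angles(config: FieldConfig, n: int, rng) -> np.ndarray:
    ang = _sample_distribution(config.angle_distribution, n, rng,
                               "angle_distribution")
    return np.clip(ang, 0.0, 89.9)


def _sample_let(config: FieldConfig, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """LET values plus a boolean mask of the high-LET admixture."""
    is_high = rng.random(n) >= config.low_let_fraction
    let = np.empty(n)
    if (~is_high).any():
        let[~is_high] = _sample_distribution(
            config.let_distributions["low"], int((~is_high).sum()), rng,
            "let_distributions.low")
    if is_high.any():
        let[is_high] = _sample_distribution(
            config.let_distributions["high"], int(is_high.sum()), rng,
            "let_distributions.high")
    return let, is_high


def sample_tracks(
    config: FieldConfig,
    area_cm2: float,
    rng: np.random.Generator | None = None,
) -> list[GroundTruthTrack]:
    """Sample a ground-truth track population over a square area.

    The expected number of ion tracks is ``fluence_per_cm2 * area_cm2``
    (Poisson); delta stubs are added at ``delta_fraction`` per ion.  Entry
    points are uniform over the square, angles and LETs follow the
    configured marginals.  Deterministic for a fixed generator state.
    """
    if not area_cm2 > 0:
        raise ConfigurationError("area_cm2 must be > 0")
    rng = rng or np.random.default_rng(config.seed)
    side_um = np.sqrt(area_cm2) * 1e4

    n_ions = rng.poisson(config.fluence_per_cm2 * area_cm2)
    tracks: list[GroundTruthTrack] = []

    let, is_high = _sample_let(config, n_ions, rng)
    theta = _sample_angles(config, n_ions, rng)
    azim = rng.uniform(0, 360, n_ions)
    entry = rng.uniform(0, side_um, size=(n_ions, 2))
    resid_lo = rng.uniform(*config.ion_residual_depth_um, size=n_ions)
    resid_hi = rng.uniform(*config.high_let_residual_depth_um, size=n_ions)
    resid = np.where(is_high, resid_hi, resid_lo)
    species = _assign_species(config, let, is_high, rng)
    for i in range(n_ions):
        tracks.append(GroundTruthTrack(
            species_label=species[i], let_water=float(let[i]),
            polar_deg=float(theta[i]), azimuth_deg=float(azim[i]),
            entry_xy=(float(entry[i, 0]), float(entry[i, 1])),
            residual_depth=float(resid[i]), kind="ion"))

    n_delta = rng.poisson(config.delta_fraction * config.fluence_per_cm2
                          * area_cm2)
    dlet = _sample_distribution(config.let_distributions["delta"], n_delta,
                                rng, "let_distributions.delta")
    dtheta = _sample_angles(config, n_delta, rng)
    dazim = rng.uniform(0, 360, n_delta)
    dentry = rng.uniform(0, side_um, size=(n_delta, 2))
    dresid = rng.uniform(*config.delta_residual_depth_um, size=n_delta)
    for i in range(n_delta):
        tracks.append(GroundTruthTrack(
            species_label="electron", let_water=float(dlet[i]),
            polar_deg=float(dtheta[i]), azimuth_deg=float(dazim[i]),
            entry_xy=(float(dentry[i, 0]), float(dentry[i, 1])),
            residual_depth=float(dresid[i]), kind="delta"))
    return tracks


def _assign_species(config, let, is_high, rng):
    """Label sampled ion tracks with plausible species: the low-LET bulk is
    drawn from the configured fluence mix of hydrogen isotopes, the high-LET
    admixture from the heavier fragments."""
    names = list(config.species)
    fracs = np.array([config.species[k]["fraction"] for k in names])
    light = np.array([config.species[k]["z"] <= 1 for k in names])
    out = np.empty(let.shape, dtype=object)
    if (~is_high).any():
        p = fracs * light
        p = p / p.sum() if p.sum() > 0 else fracs / fracs.sum()
        out[~is_high] = rng.choice(names, size=int((~is_high).sum()), p=p)
    if is_high.any():
        p = fracs * ~light
        p = p / p.sum() if p.sum() > 0 else fracs / fracs.sum()
        out[is_high] = rng.choice(names, size=int(is_high.sum()), p=p)
    return out


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _render_spot(canvas, x_um, y_um, amp, sigma_along, sigma_across,
                 azimuth_deg, pixel_um):
    """Add one anisotropic Gaussian with peak ``amp`` at (x, y) um."""
    ny, nx = canvas.shape
    cx = x_um / pixel_um - 0.5
    cy = y_um / pixel_um - 0.5
    smax = max(sigma_along, sigma_across) / pixel_um
    half = int(np.ceil(4 * smax)) + 1
    r0 = max(int(np.floor(cy)) - half, 0)
    r1 = min(int(np.ceil(cy)) + half + 1, ny)
    c0 = max(int(np.floor(cx)) - half, 0)
    c1 = min(int(np.ceil(cx)) + half + 1, nx)
    if r0 >= r1 or c0 >= c1:
        return False
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = (xx - cx) * pixel_um
    dy = (yy - cy) * pixel_um
    phi = np.radians(azimuth_deg)
    u = dx * np.cos(phi) + dy * np.sin(phi)      # along-track
    v = -dx * np.sin(phi) + dy * np.cos(phi)     # across-track
    canvas[r0:r1, c0:c1] += amp * np.exp(
        -0.5 * ((u / sigma_along) ** 2 + (v / sigma_across) ** 2))
    return True


def render_stack(
    tracks: Sequence[GroundTruthTrack],
    config: FieldConfig,
    rng: np.random.Generator | None = None,
    region: str = "out_of_field",
    detector_id: str = "synt-000",
) -> tuple[ImageStack, dict]:
    """Render tracks into a confocal-like image stack plus a ground-truth
    manifest.

    Per slice at depth z, a track contributes a spot at
    ``entry + z * tan(theta) * (cos az, sin az)`` with peak amplitude
    ``intensity_model(LET) * scale * y(theta)``; beyond the residual depth
    the amplitude falls off with the axial PSF sigma.  Tracks that never
    enter the field of view are skipped with a warning and recorded in the
    manifest.
    """
    rng = rng or np.random.default_rng(config.seed)
    noise = config.noise
    depths = config.slice_depths_um
    npx = config.n_pixels
    pixel = config.pixel_um
    fov = config.fov_um
    signal = np.zeros((config.n_slices, npx, npx))

    manifest = {"detector_id": detector_id, "region": region,
                "tracks": [], "skipped": []}

    for tid, tr in enumerate(tracks):
        tan_t = np.tan(np.radians(tr.polar_deg))
        phi = np.radians(tr.azimuth_deg)
        amp0 = (config.intensity_model(tr.let_water)
                * noise.spot_amplitude_scale
                * eval_angle_correction(tr.polar_deg, config.angle_model))
        elong = config.slice_step_um * tan_t  # in-plane track segment length
        sigma_along = np.sqrt(noise.psf_sigma_xy_um**2 + (elong**2) / 12.0)
        sigma_across = noise.psf_sigma_xy_um
        spots = []
        for j, z in enumerate(depths):
            if z > tr.residual_depth:
                fall = np.exp(-0.5 * ((z - tr.residual_depth)
                                      / noise.psf_sigma_z_um) ** 2)
                if fall < 1e-4:
                    break
            else:
                fall = 1.0
            # the axial tail past the residual depth is rendered but too
            # faint to be a countable spot
            countable = fall >= 0.05
            x = tr.entry_xy[0] + z * tan_t * np.cos(phi)
            y = tr.entry_xy[1] + z * tan_t * np.sin(phi)
            if not (-4 * sigma_along <= x <= fov + 4 * sigma_along
                    and -4 * sigma_along <= y <= fov + 4 * sigma_along):
                continue
            amp = amp0 * fall
            rendered = _render_spot(signal[j], x, y, amp, sigma_along,
                                    sigma_across, tr.azimuth_deg, pixel)
            # manifest lists spots whose centre is inside the scanned field;
            # edge and axial tails are still rendered but are not countable
            if rendered and countable and 0 <= x <= fov and 0 <= y <= fov:
                spots.append({"slice_index": j, "x_um": x, "y_um": y,
                              "amplitude": amp})
        entry_in_fov = (0 <= tr.entry_xy[0] <= fov and
                        0 <= tr.entry_xy[1] <= fov)
        record = {
            "track_id": tid,
            "kind": tr.kind,
            "species": tr.species_label,
            "let_water": tr.let_water,
            "polar_deg": tr.polar_deg,
            "azimuth_deg": tr.azimuth_deg,
            "entry_xy": list(tr.entry_xy),
            "residual_depth": tr.residual_depth,
            "entry_in_fov": entry_in_fov,
            "spots": spots,
        }
        if spots:
            manifest["tracks"].append(record)
        else:
            warnings.warn(f"track {tid} lies outside the field of view; skipped")
            manifest["skipped"].append(record)

    if noise.shot_noise:
        signal = rng.poisson(signal).astype(float)
    voxels = signal + rng.normal(noise.background_mean, noise.background_sd,
                                 size=signal.shape) if noise.background_sd > 0 \
        else signal + noise.background_mean
    voxels = np.clip(voxels, 0, 65535)

    stack = ImageStack(
        voxels=voxels,
        slice_depths_um=depths,
        pixel_um=pixel,
        detector_id=detector_id,
        region=region,
    )
    return stack, manifest


def generate_alpha_region(
    n_tracks: int,
    config: FieldConfig,
    rng: np.random.Generator | None = None,
    detector_id: str = "synt-000",
) -> tuple[ImageStack, dict]:
    """Render an alpha-reference exposure: ``n_tracks`` near-normal tracks
    of constant nominal LET whose spots vanish beyond the 16 um alpha range."""
    if not n_tracks > 0:
        raise ConfigurationError("n_tracks must be > 0")
    rng = rng or np.random.default_rng(config.seed)
    fov = config.fov_um
    theta = np.abs(rng.normal(0.0, 2.0, n_tracks))
    azim = rng.uniform(0, 360, n_tracks)
    # keep entries off the very edge so every track renders countable spots
    entry = rng.uniform(1.0, fov - 1.0, size=(n_tracks, 2))
    tracks = [
        GroundTruthTrack(
            species_label="alpha", let_water=config.alpha_nominal_let,
            polar_deg=float(min(t, 89.9)), azimuth_deg=float(a),
            entry_xy=(float(x), float(y)),
            residual_depth=config.alpha_residual_depth_um, kind="alpha_ref")
        for t, a, (x, y) in zip(theta, azim, entry)
    ]
    return render_stack(tracks, config, rng, region="alpha_ref",
                        detector_id=detector_id)


def simulate_readout(
    config: FieldConfig,
    n_stacks: int,
    seed: int | None = None,
    detector_id: str = "synt-000",
):
    """Simulate a multi-field readout of one detector.

    Tracks are sampled over each field of view extended by a sampling margin
    so that tracks may also enter the stack sideways, as in a stationary
    field; the manifest's ``entry_in_fov`` flag distinguishes the tracks
    whose surface entry point lies inside the scanned area (the ground-truth
    fluence counts exactly those).

    Yields ``(stack, manifest)`` pairs.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    margin = config.sample_margin_um
    side_um = config.fov_um + 2 * margin
    area_ext_cm2 = (side_um * 1e-4) ** 2
    for k in range(n_stacks):
        tracks = sample_tracks(config, area_ext_cm2, rng)
        # shift from sampling square to FOV coordinates
        shifted = [dataclasses.replace(
            t, entry_xy=(t.entry_xy[0] - margin, t.entry_xy[1] - margin))
            for t in tracks]
        stack, manifest = render_stack(
            shifted, config, rng, region="out_of_field",
            detector_id=detector_id)
        manifest["stack_index"] = k
        yield stack, manifest


# --------------------------------------------------------------------------
# Phase space
# --------------------------------------------------------------------------

PHASE_SPACE_COLUMNS = ("z", "a", "kinetic_energy_mev", "let_water_kev_um",
                       "polar_deg", "azimuth_deg", "weight")

# LET in water versus energy per nucleon, rough stopping-power scaling used
# only to make generated (E, LET) pairs mutually consistent:
#   LET ~ 27 * z^2 * (E/A)^-0.77 keV/um
_LET_COEFF = 27.0
_LET_EXPONENT = -0.77


def let_from_energy(z, a, kinetic_energy_mev):
    """Approximate LET in water (keV/um) of an ion from its total kinetic
    energy, via a power-law stopping-power scaling in energy per nucleon."""
    e_per_u = np.asarray(kinetic_energy_mev, float) / np.asarray(a, float)
    return _LET_COEFF * np.asarray(z, float) ** 2 * e_per_u ** _LET_EXPONENT


def generate_phase_space(
    config: FieldConfig,
    n: int,
    seed: int | None = None,
):
    """Sample tabular records of charged particles crossing a scoring plane.

    Species follow the configured fluence mix; energies per nucleon are
    log-uniform within each species' band and LET values are derived from
    the energy so the two are consistent.  Returns a pandas DataFrame in the
    phase-space exchange layout.
    """
    import pandas as pd

    if n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = list(config.species)
    fracs = np.array([config.species[k]["fraction"] for k in names])
    fracs = fracs / fracs.sum()
    if n == 0:
        return pd.DataFrame(columns=list(PHASE_SPACE_COLUMNS))
    labels = rng.choice(names, size=n, p=fracs)
    z = np.array([config.species[k]["z"] for k in labels])
    a = np.array([config.species[k]["a"] for k in labels])
    e_lo = np.array([config.species[k]["e_per_u_mev"][0] for k in labels])
    e_hi = np.array([config.species[k]["e_per_u_mev"][1] for k in labels])
    e_per_u = np.exp(rng.uniform(np.log(e_lo), np.log(e_hi)))
    energy = e_per_u * a
    let = let_from_energy(z, a, energy)
    theta = _sample_angles(config, n, rng)
    azim = rng.uniform(0, 360, n)
    return pd.DataFrame({
        "z": z, "a": a,
        "kinetic_energy_mev": energy,
        "let_water_kev_um": let,
        "polar_deg": theta,
        "azimuth_deg": azim,
        "weight": np.ones(n),
    })
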