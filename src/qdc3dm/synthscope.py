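"""Synthetic microscope: blinking quantum-dot emitters rendered under a 3D PSF.

Generates every input the counting pipeline consumes -- 2D blinking movies,
3D volumetric stacks, membrane-stain point clouds, nucleus centroids, and
per-cell bound-ligand counts -- with full ground truth attached, so that
detection, quantization, calibration and internalization analysis can be
validated against known answers.

Conventions
-----------
* Images are (y, x) and stacks (z, y, x); positions are (x, y[, z]) with x
  along columns, y along rows, z in plane units.  Sub-pixel positions are
  pixel-center coordinates (position 0.0 is the center of pixel 0).
* The PSF is a separable pixel-integrated Gaussian, so an emitter of
  brightness B deposits exactly B expected photons on an unbounded grid.
* Noise model: detected = gain * Poisson(qe * expected) + N(0, read_noise).
* All randomness flows from one seed through ``numpy.random.SeedSequence``
  spawning, so identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.special import erf

from .kinetics import KineticParams, ReceptorDistribution, sample_cells

__all__ = [
    "OpticsConfig",
    "EmitterTruth",
    "SceneTruth",
    "BindingModel",
    "simulate_blinking_states",
    "render_timeseries",
    "render_stack3d",
    "generate_cell_fixture",
    "make_spot_field",
    "gaussian_mass_1d",
    "psf_window_mass",
    "write_movie_tiff",
    "write_truth_csv",
    "write_config_yaml",
]

# Stationary blink rates giving on-fraction 0.5, the regime the counting
# scheme is designed around.  Switching at 0.5/frame (mean dwell ~2 frames)
# keeps blinking fast relative to a QD's transit through the focal planes
# of a z-scan; much slower blinking leaves a fraction of QDs dark across
# all slices near focus, which no intensity-based counter can recover.
DEFAULT_K_ON_BLINK = 0.5
DEFAULT_K_OFF_BLINK = 0.5
# Expected detected photons per frame (100 ms) from one on-state QD.
# Bright stable emitters deliver 1e4-1e5 detected photons/s; 5e4/s is a
# conservative working point and keeps single emitters far above the
# photon noise of diffuse cellular background.
DEFAULT_BRIGHTNESS = 5000.0


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition geometry, PSF widths and camera noise parameters.

    Defaults mirror a 100x/1.45NA EMCCD setup: 160 nm pixels, 250 nm
    z-spacing, and a near-diffraction-limited Gaussian PSF.
    """

    pixel_size_nm: float = 160.0
    z_spacing_nm: float = 250.0
    psf_sigma_xy_px: float = 1.0
    psf_sigma_z_planes: float = 1.2
    exposure_ms: float = 100.0
    camera_gain: float = 1.0
    read_noise_sd: float = 3.0
    quantum_efficiency: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_nm",
            "z_spacing_nm",
            "psf_sigma_xy_px",
            "psf_sigma_z_planes",
            "exposure_ms",
            "camera_gain",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if not 0.0 < self.quantum_efficiency <= 1.0:
            raise ValueError("quantum_efficiency must be in (0, 1]")

    @property
    def z_scale(self) -> float:
        """Planes-to-pixels conversion factor (z_spacing / pixel_size)."""
        return self.z_spacing_nm / self.pixel_size_nm


@dataclass
class EmitterTruth:
    """Ground truth for one diffraction-limited emitter (1..n QDs)."""

    position: tuple[float, ...]  # (x, y) or (x, y, z), sub-pixel
    n_qd: int
    brightness_per_qd: float = DEFAULT_BRIGHTNESS
    states: np.ndarray | None = None  # (n_qd, n_frames) 0/1, filled on render
    id: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_qd < 1:
            raise ValueError("n_qd must be >= 1")
        if self.brightness_per_qd <= 0:
            raise ValueError("brightness_per_qd must be > 0")
        if self.states is not None:
            s = np.asarray(self.states)
            if not np.isin(s, (0, 1)).all():
                raise ValueError("states must be 0/1")
            if s.shape[0] != self.n_qd:
                raise ValueError("states must have n_qd rows")
            self.states = s.astype(np.uint8)


@dataclass
class SceneTruth:
    """One synthetic field of view with ground truth.

    ``autofluorescence_field`` holds mean background photons per pixel per
    frame (2D, applied to every frame/plane) and defines the frame shape.
    """

    emitters: list[EmitterTruth]
    autofluorescence_field: np.ndarray
    seed: int
    nucleus_centroid: tuple[float, float, float] | None = None
    membrane_points: np.ndarray | None = None  # (n, 3) in (x, y, z-plane) units
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.autofluorescence_field.shape  # (ny, nx)


@dataclass(frozen=True)
class BindingModel:
    """Per-cell bound-ligand count generator backed by the kinetic model."""

    params: KineticParams
    receptors: ReceptorDistribution

    def sample(self, rng: np.random.Generator, n_cells: int = 1) -> np.ndarray:
        return sample_cells(self.params, self.receptors, n_cells, rng)


def simulate_blinking_states(
    n_qd: int,
    n_frames: int,
    p_on: float | None = None,
    k_on_blink: float = DEFAULT_K_ON_BLINK,
    k_off_blink: float = DEFAULT_K_OFF_BLINK,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Two-state Markov blinking: (n_qd, n_frames) matrix of on(1)/off(0).

    Per frame an off QD turns on with probability ``k_on_blink`` and an on
    QD turns off with probability ``k_off_blink``; the long-run on-fraction
    is ``k_on / (k_on + k_off)``.  The initial state is Bernoulli(``p_on``),
    defaulting to the stationary on-fraction so the chain starts at
    equilibrium.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_qd < 1:
        raise ValueError("n_qd must be >= 1")
    for name, p in (("k_on_blink", k_on_blink), ("k_off_blink", k_off_blink)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if p_on is None:
        total = k_on_blink + k_off_blink
        p_on = k_on_blink / total if total > 0 else 1.0
    if not 0.0 <= p_on <= 1.0:
        raise ValueError("p_on must be in [0, 1]")
    rng = np.random.default_rng(seed)
    states = np.empty((n_qd, n_frames), dtype=np.uint8)
    states[:, 0] = rng.random(n_qd) < p_on
    u = rng.random((n_qd, n_frames - 1)) if n_frames > 1 else None
    for t in range(1, n_frames):
        on = states[:, t - 1] == 1
        flip = np.where(on, u[:, t - 1] < k_off_blink, u[:, t - 1] < k_on_blink)
        states[:, t] = np.where(flip, 1 - states[:, t - 1], states[:, t - 1])
    return states


def gaussian_mass_1d(lo: float, hi: float, mu: float, sigma: float) -> float:
    """Integral of a unit Gaussian over pixel interval [lo-0.5, hi+0.5]."""
    a = (lo - 0.5 - mu) / (sigma * np.sqrt(2.0))
    b = (hi + 0.5 - mu) / (sigma * np.sqrt(2.0))
    return 0.5 * (erf(b) - erf(a))


def psf_window_mass(
    optics: OpticsConfig,
    position: tuple[float, ...],
    half_xy: int = 1,
    half_z: int | None = None,
) -> float:
    """Analytic PSF mass inside a window centered at the rounded centroid.

    half_xy=1 gives the 3x3 window; half_z=5 the 11-plane column.  Used as
    the oracle for window-sum and calibration tests.
    """
    x0, y0 = position[0], position[1]
    cx, cy = _round_half_up(x0), _round_half_up(y0)
    mx = gaussian_mass_1d(cx - half_xy, cx + half_xy, x0, optics.psf_sigma_xy_px)
    my = gaussian_mass_1d(cy - half_xy, cy + half_xy, y0, optics.psf_sigma_xy_px)
    mass = mx * my
    if half_z is not None:
        z0 = position[2]
        cz = _round_half_up(z0)
        mass *= gaussian_mass_1d(cz - half_z, cz + half_z, z0, optics.psf_sigma_z_planes)
    return mass


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def _pixel_profile(n: int, mu: float, sigma: float, cutoff: float = 6.0):
    """Pixel-integrated 1D Gaussian restricted to a local support window."""
    half = int(np.ceil(cutoff * sigma)) + 1
    c = _round_half_up(mu)
    lo, hi = max(0, c - half), min(n - 1, c + half)
    if lo > hi:
        return lo, np.zeros(0)
    idx = np.arange(lo, hi + 1)
    sq = sigma * np.sqrt(2.0)
    vals = 0.5 * (erf((idx + 0.5 - mu) / sq) - erf((idx - 0.5 - mu) / sq))
    return lo, vals


def _expected_frame(
    scene: SceneTruth, optics: OpticsConfig, amplitudes: np.ndarray
) -> np.ndarray:
    """Expected photon image for one frame given per-emitter amplitudes."""
    ny, nx = scene.shape
    img = scene.autofluorescence_field.astype(float).copy()
    for amp, em in zip(amplitudes, scene.emitters):
        if amp == 0.0:
            continue
        x0, y0 = em.position[0], em.position[1]
        ox, px = _pixel_profile(nx, x0, optics.psf_sigma_xy_px)
        oy, py = _pixel_profile(ny, y0, optics.psf_sigma_xy_px)
        if len(px) == 0 or len(py) == 0:
            continue
        img[oy : oy + len(py), ox : ox + len(px)] += amp * np.outer(py, px)
    return img


def _apply_camera(
    expected: np.ndarray, optics: OpticsConfig, rng: np.random.Generator
) -> np.ndarray:
    photons = rng.poisson(optics.quantum_efficiency * expected)
    counts = optics.camera_gain * photons.astype(float)
    if optics.read_noise_sd > 0:
        counts += rng.normal(0.0, optics.read_noise_sd, size=counts.shape)
    return counts


def _ensure_states(
    scene: SceneTruth, n_frames: int, rng: np.random.Generator
) -> None:
    for em in scene.emitters:
        if em.states is None or em.states.shape[1] < n_frames:
            em.states = simulate_blinking_states(em.n_qd, n_frames, seed=rng)


def render_timeseries(
    scene: SceneTruth,
    optics: OpticsConfig,
    n_frames: int,
    seed: int | np.random.Generator | None = None,
    apply_noise: bool = True,
) -> np.ndarray:
    """Render a (n_frames, ny, nx) blinking movie at a single focal plane.

    Each frame sums the on-state QDs of every emitter times brightness
    under the 2D PSF, plus autofluorescence, then applies shot and read
    noise.  Emitters with no pre-assigned blinking states get fresh
    two-state Markov trajectories (recorded back into the truth).
    """
    ny, nx = scene.shape
    for em in scene.emitters:
        if not (0 <= em.position[0] < nx and 0 <= em.position[1] < ny):
            raise ValueError(f"emitter {em.id} outside field of view")
    rng = np.random.default_rng(seed)
    _ensure_states(scene, n_frames, rng)
    movie = np.empty((n_frames, ny, nx), dtype=float)
    n_on = np.stack([em.states[:, :n_frames].sum(axis=0) for em in scene.emitters]) \
        if scene.emitters else np.zeros((0, n_frames), dtype=int)
    for t in range(n_frames):
        amps = np.array(
            [em.brightness_per_qd * n_on[i, t] for i, em in enumerate(scene.emitters)]
        )
        expected = _expected_frame(scene, optics, amps)
        movie[t] = _apply_camera(expected, optics, rng) if apply_noise else expected
    return movie


def render_stack3d(
    scene: SceneTruth,
    optics: OpticsConfig,
    n_planes: int,
    seed: int | np.random.Generator | None = None,
    apply_noise: bool = True,
) -> np.ndarray:
    """Render a (n_planes, ny, nx) volumetric stack with a separable 3D PSF.

    Blinking is applied per plane (acquisition is sequential in z, so a QD
    may be dark in some slices), which is the dominant source of intensity
    dispersion the calibration has to average over.
    """
    ny, nx = scene.shape
    rng = np.random.default_rng(seed)
    _ensure_states(scene, n_planes, rng)
    stack = np.empty((n_planes, ny, nx), dtype=float)
    for z in range(n_planes):
        amps = np.zeros(len(scene.emitters))
        for i, em in enumerate(scene.emitters):
            if len(em.position) < 3:
                raise ValueError("3D rendering needs (x, y, z) emitter positions")
            zmass = gaussian_mass_1d(z, z, em.position[2], optics.psf_sigma_z_planes)
            n_on = int(em.states[:, z].sum())
            amps[i] = em.brightness_per_qd * n_on * zmass
        expected = _expected_frame(scene, optics, amps)
        stack[z] = _apply_camera(expected, optics, rng) if apply_noise else expected
    return stack


def make_spot_field(
    n_spots: int,
    shape: tuple[int, int],
    n_planes: int | None = None,
    n_qd: int | np.ndarray = 1,
    brightness: float = DEFAULT_BRIGHTNESS,
    autofluorescence: float = 3.0,
    min_separation: float = 8.0,
    margin: float = 6.0,
    seed: int | np.random.Generator | None = None,
) -> SceneTruth:
    """Scene of isolated emitters at random, well-separated positions.

    Emulates a coverslip field of isolated QDs as used for intensity
    calibration.  ``n_qd`` may be a scalar or a per-spot array.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    nz = n_planes
    positions: list[tuple[float, ...]] = []
    tries = 0
    while len(positions) < n_spots:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("could not place spots with requested separation")
        x = rng.uniform(margin, nx - 1 - margin)
        y = rng.uniform(margin, ny - 1 - margin)
        if any((x - p[0]) ** 2 + (y - p[1]) ** 2 < min_separation**2 for p in positions):
            continue
        if nz is None:
            positions.append((x, y))
        else:
            # keep the 11-plane integration window inside the stack when
            # the stack is deep enough; center the spots otherwise
            zlo, zhi = (7.0, nz - 8.0) if nz >= 16 else (0.3 * nz, 0.7 * nz)
            positions.append((x, y, rng.uniform(zlo, zhi)))
    counts = np.broadcast_to(np.asarray(n_qd), (n_spots,)).astype(int)
    emitters = [
        EmitterTruth(position=p, n_qd=int(k), brightness_per_qd=brightness, id=i)
        for i, (p, k) in enumerate(zip(positions, counts))
    ]
    af = np.full(shape, float(autofluorescence))
    return SceneTruth(
        emitters=emitters,
        autofluorescence_field=af,
        seed=int(rng.integers(2**31)),
    )


def generate_cell_fixture(
    binding_model: BindingModel | int,
    pattern: tuple[int, int] = (64, 64),
    internal_fraction_true: float = 0.0,
    n_planes: int = 40,
    optics: OpticsConfig | None = None,
    brightness: float = DEFAULT_BRIGHTNESS,
    autofluorescence: float = 3.0,
    n_membrane_points: int = 600,
    seed: int | np.random.Generator | None = None,
) -> SceneTruth:
    """Synthetic patterned cell: membrane surface, nucleus, and bound ligands.

    The membrane is an ellipsoid fitted to the adhesion-pattern rectangle;
    membrane-stain points are sampled on it with slight radial jitter.  The
    number of bound ligands is drawn from ``binding_model`` (or fixed, if
    an int is given); each ligand carries one QD and is placed internal
    (relative radial distance < 0.8) with probability
    ``internal_fraction_true``, else on the surface.  Truth labels record
    each spot's placement.
    """
    if not 0.0 <= internal_fraction_true <= 1.0:
        raise ValueError("internal_fraction_true must be in [0, 1]")
    w, h = pattern
    if w <= 0 or h <= 0:
        raise ValueError("pattern area must be > 0")
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    ny, nx = int(h * 1.5), int(w * 1.5)
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (n_planes - 1) / 2.0
    # ellipsoid semi-axes in xy-pixel units; z converted to plane units below
    rx, ry = 0.42 * w, 0.42 * h
    rz_px = 0.35 * min(w, h)
    z_scale = optics.z_scale
    # clamp the axial semi-axis so the whole cell (and the 11-plane
    # integration window of any surface spot) stays inside the stack
    rz = min(rz_px / z_scale, (n_planes - 1) / 2.0 - 7.0)  # plane units
    if rz < 4.0:
        raise ValueError("cell too thin for the z-sampling; enlarge the pattern or stack")

    def unit_dirs(n: int) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    d = unit_dirs(n_membrane_points)
    jitter = rng.normal(1.0, 0.01, size=n_membrane_points)[:, None]
    membrane = np.column_stack(
        [
            cx + rx * d[:, 0] * jitter[:, 0],
            cy + ry * d[:, 1] * jitter[:, 0],
            cz + rz * d[:, 2] * jitter[:, 0],
        ]
    )
    if np.ptp(membrane[:, 2]) < 1e-9:
        raise ValueError("degenerate (coplanar) membrane surface")

    if isinstance(binding_model, BindingModel):
        n_egf = int(binding_model.sample(rng, 1)[0])
    else:
        n_egf = int(binding_model)
    emitters = []
    labels = []
    for i in range(n_egf):
        internal = rng.random() < internal_fraction_true
        u = unit_dirs(1)[0]
        rho = rng.uniform(0.1, 0.75) if internal else 1.0
        pos = (
            cx + rho * rx * u[0],
            cy + rho * ry * u[1],
            cz + rho * rz * u[2],
        )
        labels.append("internal" if internal else "external")
        emitters.append(
            EmitterTruth(
                position=pos,
                n_qd=1,
                brightness_per_qd=brightness,
                id=i,
                label=labels[-1],
            )
        )
    af = np.full((ny, nx), float(autofluorescence))
    return SceneTruth(
        emitters=emitters,
        autofluorescence_field=af,
        seed=int(rng.integers(2**31)),
        nucleus_centroid=(cx, cy, cz),
        membrane_points=membrane,
        meta={
            "pattern": (w, h),
            "n_planes": n_planes,
            "internal_fraction_true": internal_fraction_true,
            "z_scale": z_scale,
            "semi_axes": (rx, ry, rz),
        },
    )


# ---------------------------------------------------------------------------
# I/O helpers


def write_movie_tiff(path, movie: np.ndarray) -> None:
    """Write a movie (T pages) or stack (Z pages) as multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))


def write_truth_csv(path, scene: SceneTruth) -> pd.DataFrame:
    rows = []
    for em in scene.emitters:
        pos = em.position
        rows.append(
            {
                "id": em.id,
                "x": pos[0],
                "y": pos[1],
                "z": pos[2] if len(pos) > 2 else np.nan,
                "n_qd": em.n_qd,
                "label": em.label,
            }
        )
    df = pd.DataFrame(rows, columns=["id", "x", "y", "z", "n_qd", "label"])
    df.to_csv(path, index=False)
    return df


def write_config_yaml(path, optics: OpticsConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"optics": optics.__dict__}, fh)
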