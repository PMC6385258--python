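"""Calibration arithmetic: voxel-window intensities, single-QD calibration,
per-spot and per-cell molecule counts, autofluorescence metrics, AUROC.

The counting principle: the deconvolved 3D intensity of a spot, integrated
over a fixed 3x3x11 voxel window and background-subtracted, is linear in
the number of emitters it contains.  Dividing by the mean intensity of
spots independently verified to hold exactly one QD (via blinking
quantization) converts intensity to molecule number; summing over a cell's
spots counts molecules per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .spotdetect import SpotRecord

__all__ = [
    "Calibration",
    "SpectralChannel",
    "CellResult",
    "WINDOW_HALF_XY",
    "WINDOW_HALF_Z",
    "spot_intensity_3dd",
    "estimate_background",
    "calibrate_single_qd",
    "qds_per_spot",
    "count_cell",
    "autofluorescence_spectrum",
    "autofluorescence_spot_intensity",
    "detection_auroc",
]

WINDOW_HALF_XY = 1  # 3x3 laterally
WINDOW_HALF_Z = 5  # 11 planes axially


@dataclass
class Calibration:
    """Mean deconvolved 3D intensity of a single QD and its dispersion."""

    mean_i_1qd_3dd: float
    n_single: int
    dispersion: float

    def __post_init__(self) -> None:
        if self.n_single < 1:
            raise ValueError("calibration needs at least one single QD")
        if self.mean_i_1qd_3dd <= 0:
            raise ValueError("mean single-QD intensity must be > 0")


@dataclass(frozen=True)
class SpectralChannel:
    """Emission channel with its detector quantum-efficiency curve.

    ``qe_curve`` is a (wavelength_nm, efficiency) table; the integrated
    efficiency over the band (lambda1, lambda2) normalizes
    autofluorescence intensities across channels.
    """

    lambda_em: float
    band: tuple[float, float]
    qe_curve: np.ndarray  # (n, 2): wavelength nm, Phi

    def __post_init__(self) -> None:
        l1, l2 = self.band
        if not l1 < l2:
            raise ValueError("band must satisfy lambda1 < lambda2")
        curve = np.asarray(self.qe_curve, dtype=float)
        if curve.ndim != 2 or curve.shape[1] != 2:
            raise ValueError("qe_curve must be (n, 2)")
        if np.any(curve[:, 1] <= 0) or np.any(curve[:, 1] > 1):
            raise ValueError("quantum efficiency must be in (0, 1]")
        object.__setattr__(self, "qe_curve", curve)

    def integrated_qe(self) -> float:
        l1, l2 = self.band
        lam = np.linspace(l1, l2, 257)
        phi = np.interp(lam, self.qe_curve[:, 0], self.qe_curve[:, 1])
        return float(np.trapezoid(phi, lam))

    def qe_at_peak(self) -> float:
        return float(
            np.interp(self.lambda_em, self.qe_curve[:, 0], self.qe_curve[:, 1])
        )


@dataclass
class CellResult:
    """Per-cell counting summary."""

    spots: list[SpotRecord]
    n_qd_cell: float = field(init=False)
    n_qd_cell_int: int = field(init=False)
    background_mean_3x3x11: float | None = None
    background_mean_3x3: float | None = None

    def __post_init__(self) -> None:
        total = sum(s.n_qd_spot for s in self.spots if s.n_qd_spot is not None)
        self.n_qd_cell = float(total)
        self.n_qd_cell_int = int(round(total))

    @property
    def n_egf_cell(self) -> float:
        """One QD tags one ligand, so the QD count is the ligand count."""
        return self.n_qd_cell


def spot_intensity_3dd(
    stack: np.ndarray,
    rounded_centroid: tuple[int, int, int],
    background_mean: float,
) -> float:
    """Background-subtracted integrated intensity of the 3x3x11 voxel window.

    Sums the deconvolved stack over x,y in [x0]-1..[x0]+1 and z in
    [z0]-5..[z0]+5 and subtracts the mean window-sum of background
    regions.  Raises when the window clips the stack border (such spots
    are flagged and excluded upstream).
    """
    x, y, z = (int(v) for v in rounded_centroid)
    nz, ny, nx = stack.shape
    if not (
        WINDOW_HALF_XY <= x <= nx - 1 - WINDOW_HALF_XY
        and WINDOW_HALF_XY <= y <= ny - 1 - WINDOW_HALF_XY
        and WINDOW_HALF_Z <= z <= nz - 1 - WINDOW_HALF_Z
    ):
        raise ValueError(f"3x3x11 window at ({x}, {y}, {z}) clips the stack border")
    win = stack[
        z - WINDOW_HALF_Z : z + WINDOW_HALF_Z + 1,
        y - WINDOW_HALF_XY : y + WINDOW_HALF_XY + 1,
        x - WINDOW_HALF_XY : x + WINDOW_HALF_XY + 1,
    ]
    return float(win.sum() - background_mean)


def estimate_background(
    stack: np.ndarray,
    spots: list[SpotRecord],
    mask: np.ndarray | None = None,
    exclusion_px: int = 3,
    n_windows: int = 200,
    seed: int | np.random.Generator | None = 0,
) -> dict[str, float]:
    """Mean window-sum of spot-free background regions.

    Samples ``n_windows`` window positions at least ``exclusion_px``
    pixels from every spot (and inside ``mask`` when given) and returns
    the mean 3x3x11 and 3x3 window sums, keyed ``"3x3x11"`` / ``"3x3"``.
    """
    stack = np.asarray(stack, dtype=float)
    nz, ny, nx = stack.shape
    if mask is not None and not np.asarray(mask).any():
        raise ValueError("empty background mask")
    allowed = np.ones((ny, nx), dtype=bool)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        allowed &= m if m.ndim == 2 else m.any(axis=0)
    for s in spots:
        r = s.rounded
        x, y = r[0], r[1]
        xlo, xhi = max(0, x - exclusion_px), min(nx, x + exclusion_px + 1)
        ylo, yhi = max(0, y - exclusion_px), min(ny, y + exclusion_px + 1)
        allowed[ylo:yhi, xlo:xhi] = False
    allowed[: WINDOW_HALF_XY, :] = False
    allowed[ny - WINDOW_HALF_XY :, :] = False
    allowed[:, : WINDOW_HALF_XY] = False
    allowed[:, nx - WINDOW_HALF_XY :] = False
    ys, xs = np.nonzero(allowed)
    if len(xs) < 100:
        raise ValueError(f"only {len(xs)} candidate background positions; need >= 100")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(xs), size=min(n_windows, len(xs)), replace=False)
    zs = rng.integers(WINDOW_HALF_Z, nz - WINDOW_HALF_Z, size=len(pick))
    sums_3d, sums_2d = [], []
    for i, (j, z) in enumerate(zip(pick, zs)):
        x, y = int(xs[j]), int(ys[j])
        win = stack[
            z - WINDOW_HALF_Z : z + WINDOW_HALF_Z + 1,
            y - WINDOW_HALF_XY : y + WINDOW_HALF_XY + 1,
            x - WINDOW_HALF_XY : x + WINDOW_HALF_XY + 1,
        ]
        sums_3d.append(win.sum())
        sums_2d.append(win[WINDOW_HALF_Z].sum())
    return {
        "3x3x11": float(np.mean(sums_3d)),
        "3x3": float(np.mean(sums_2d)),
        "3x3x11_sd": float(np.std(sums_3d)),
        "3x3_sd": float(np.std(sums_2d)),
    }


def calibrate_single_qd(intensities: list[float] | np.ndarray) -> Calibration:
    """Average the deconvolved 3D intensities of verified single QDs."""
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        raise ValueError("no single-QD intensities to calibrate from")
    return Calibration(
        mean_i_1qd_3dd=float(arr.mean()),
        n_single=int(arr.size),
        dispersion=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


def qds_per_spot(i_spot_3dd: float, cal: Calibration) -> float:
    """Spot intensity divided by the single-QD mean; clamps negatives to 0."""
    ratio = i_spot_3dd / cal.mean_i_1qd_3dd
    if ratio < 0:
        warnings.warn(
            "negative calibrated count (background overshoot); clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return float(ratio)


def count_cell(
    spots: list[SpotRecord],
    cal: Calibration,
    background_mean_3x3x11: float | None = None,
) -> CellResult:
    """Sum calibrated per-spot counts over one cell.

    Spots with a filled ``i_spot_3dd`` get ``n_qd_spot`` computed here;
    border-flagged spots are excluded.
    """
    kept = []
    for s in spots:
        if s.excluded:
            continue
        if s.n_qd_spot is None and s.i_spot_3dd is not None:
            s.n_qd_spot = qds_per_spot(s.i_spot_3dd, cal)
        if s.n_qd_spot is not None:
            kept.append(s)
    return CellResult(spots=kept, background_mean_3x3x11=background_mean_3x3x11)


def autofluorescence_spectrum(
    cell_pixel_means: dict[float, float],
    background_pixel_means: dict[float, float],
    channels: list[SpectralChannel],
    reference_nm: float = 562.0,
) -> pd.DataFrame:
    """Detector-normalized cellular autofluorescence spectrum.

    Per channel: (mean cell pixel - mean background pixel) divided by the
    integrated quantum efficiency over the channel band; the table is then
    normalized to the reference channel (562 nm) which is 1 by
    construction.
    """
    lams = [ch.lambda_em for ch in channels]
    if reference_nm not in lams:
        raise ValueError(f"reference channel {reference_nm} nm not present")
    raw = {}
    for ch in channels:
        lam = ch.lambda_em
        raw[lam] = (cell_pixel_means[lam] - background_pixel_means[lam]) / ch.integrated_qe()
    ref = raw[reference_nm]
    if ref == 0:
        raise ValueError("reference channel has zero net autofluorescence")
    return pd.DataFrame(
        {
            "lambda_em": lams,
            "i_af_raw": [raw[lam] for lam in lams],
            "i_af_norm": [raw[lam] / ref for lam in lams],
        }
    )


def autofluorescence_spot_intensity(
    frame: np.ndarray,
    rounded_centroid: tuple[int, int],
    background_mean_3x3: float,
    quantum_efficiency: float,
) -> float:
    """Detector-corrected 3x3 autofluorescence intensity at a QD-free site."""
    if not 0.0 < quantum_efficiency <= 1.0:
        raise ValueError("quantum_efficiency must be in (0, 1]")
    x, y = (int(v) for v in rounded_centroid)
    ny, nx = frame.shape
    if not (1 <= x <= nx - 2 and 1 <= y <= ny - 2):
        raise ValueError("3x3 window clips the frame border")
    s = float(frame[y - 1 : y + 2, x - 1 : x + 2].sum())
    return (s - background_mean_3x3) / quantum_efficiency


def detection_auroc(signal: np.ndarray, background: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUROC with mid-rank tie handling.

    Equals the probability that a randomly chosen signal intensity exceeds
    a randomly chosen background intensity (ties counted half).
    """
    s = np.asarray(signal, dtype=float)
    b = np.asarray(background, dtype=float)
    if s.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([s, b]))
    r_s = ranks[: s.size].sum()
    u = r_s - s.size * (s.size + 1) / 2.0
    return float(u / (s.size * b.size))
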