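"""Slide-adaptive Hematoxylin/Eosin stain separation in optical-density space.

The pipeline is: convert RGB tiles to optical density (Beer-Lambert law),
estimate a per-slide 2-D stain plane by PCA on pooled foreground OD pixels,
locate the two stain direction vectors as robust extreme angles within that
plane, and project tiles onto the resulting basis to obtain normalized
single-channel Hematoxylin and Eosin concentration images.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RGBTile",
    "ODTile",
    "StainBasis",
    "ChannelPair",
    "StainSepError",
    "InsufficientTissueError",
    "SingularPlaneError",
    "IllConditionedBasisError",
    "DegenerateStainWarning",
    "rgb_to_od",
    "od_to_rgb",
    "pool_od_pixels",
    "fit_stain_basis",
    "project_to_concentrations",
    "calibrate_norm_scales",
    "separate_tile",
    "fit_slide_basis",
    "fixed_default_basis",
    "basis_from_vectors",
    "save_bases",
    "load_bases",
]

#: Default intensity floor (half a quantization level) guarding log10(0).
DEFAULT_LOG_EPSILON = 0.5

#: Condition-number threshold beyond which a stain basis is rejected.
CONDITION_LIMIT = 1.0e6

# Widely used published H&E optical-density stain vectors
# (Ruifrok & Johnston 2001, "Quantification of histochemical staining by
# color deconvolution"), normalized to unit length.  Used as the canonical
# pair for the fixed (non-adaptive) separation ablation and by the simulator.
RUIFROK_H_OD = np.array([0.650, 0.704, 0.286])
RUIFROK_E_OD = np.array([0.072, 0.990, 0.105])


class StainSepError(ValueError):
    """Base class for stain-separation failures."""


class InsufficientTissueError(StainSepError):
    """Too few foreground OD pixels to fit a stain basis."""


class SingularPlaneError(StainSepError):
    """OD covariance has rank < 2; no stain plane exists."""


class IllConditionedBasisError(StainSepError):
    """Stain basis matrix too close to singular to invert reliably."""


class DegenerateStainWarning(UserWarning):
    """A stain channel carried no signal during calibration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RGBTile:
    """An 8-bit RGB image tile plus its background (blank-field) intensity."""

    pixels: np.ndarray
    background_intensity: float = 255.0
    slide_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"RGB tile must be (H, W, 3); got shape {px.shape}"
            )
        if np.any(px < 0):
            raise ValueError("negative pixel intensities")
        if np.any(px > self.background_intensity):
            raise ValueError(
                "pixel intensities exceed the background intensity"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class ODTile:
    """Per-pixel optical-density vectors (OD_R, OD_G, OD_B), all >= 0."""

    od: np.ndarray

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        if od.ndim != 3 or od.shape[2] != 3:
            raise ValueError(f"OD tile must be (H, W, 3); got {od.shape}")
        if not np.all(np.isfinite(od)):
            raise ValueError("non-finite OD values")
        if np.any(od < 0):
            raise ValueError("negative OD values")
        object.__setattr__(self, "od", od)


@dataclass(frozen=True)
class StainBasis:
    """Per-slide stain geometry: PCA axes, stain angles/vectors, matrices.

    ``axes`` holds the orthonormal PCA directions as rows, ordered by
    descending eigenvalue: ``axes[0] = V_x``, ``axes[1] = V_y``,
    ``axes[2] = V_residual``.  Angles are measured in the (V_x, V_y) plane
    and satisfy ``theta_h < 0 < theta_e`` (H in quadrant IV, E in
    quadrant I).  ``forward_matrix`` maps (alpha_H, alpha_E, alpha_res) to
    OD; ``inverse_matrix`` is its inverse.  ``norm_scale_h/e`` are the
    per-slide high-percentile concentration values used for normalization;
    they are ``None`` until :func:`calibrate_norm_scales` runs.
    """

    axes: np.ndarray
    theta_h: float
    theta_e: float
    v_h: np.ndarray
    v_e: np.ndarray
    forward_matrix: np.ndarray
    inverse_matrix: np.ndarray
    slide_id: str = ""
    norm_scale_h: float | None = None
    norm_scale_e: float | None = None
    norm_target: float = 0.5
    params: dict = field(default_factory=dict)

    @property
    def calibrated(self) -> bool:
        return self.norm_scale_h is not None and self.norm_scale_e is not None

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "axes": self.axes.tolist(),
            "theta_h": float(self.theta_h),
            "theta_e": float(self.theta_e),
            "v_h": self.v_h.tolist(),
            "v_e": self.v_e.tolist(),
            "forward_matrix": self.forward_matrix.tolist(),
            "inverse_matrix": self.inverse_matrix.tolist(),
            "norm_scale_h": self.norm_scale_h,
            "norm_scale_e": self.norm_scale_e,
            "norm_target": self.norm_target,
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StainBasis":
        return cls(
            axes=np.asarray(d["axes"], dtype=float),
            theta_h=float(d["theta_h"]),
            theta_e=float(d["theta_e"]),
            v_h=np.asarray(d["v_h"], dtype=float),
            v_e=np.asarray(d["v_e"], dtype=float),
            forward_matrix=np.asarray(d["forward_matrix"], dtype=float),
            inverse_matrix=np.asarray(d["inverse_matrix"], dtype=float),
            slide_id=d.get("slide_id", ""),
            norm_scale_h=d.get("norm_scale_h"),
            norm_scale_e=d.get("norm_scale_e"),
            norm_target=float(d.get("norm_target", 0.5)),
            params=dict(d.get("params", {})),
        )


@dataclass(frozen=True)
class ChannelPair:
    """Co-registered normalized H and E concentration images in [0, 1]."""

    h_image: np.ndarray
    e_image: np.ndarray
    basis_ref: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.h_image, dtype=float)
        e = np.asarray(self.e_image, dtype=float)
        if h.shape != e.shape:
            raise ValueError("H and E images must share shape")
        object.__setattr__(self, "h_image", h)
        object.__setattr__(self, "e_image", e)


# ---------------------------------------------------------------------------
# RGB <-> OD
# ---------------------------------------------------------------------------


def rgb_to_od(tile: RGBTile, epsilon: float = DEFAULT_LOG_EPSILON) -> ODTile:
    """Convert an RGB tile to optical density: OD_c = log10(I0_c / I_c).

    ``epsilon`` floors the transmitted intensity so fully dark pixels map to
    a large finite OD rather than infinity.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    intensity = np.maximum(np.asarray(tile.pixels, dtype=float), epsilon)
    od = np.log10(tile.background_intensity / intensity)
    return ODTile(np.maximum(od, 0.0))


def od_to_rgb(od: ODTile | np.ndarray, background_intensity: float = 255.0) -> RGBTile:
    """Invert the Beer-Lambert transform: I_c = I0 * 10**(-OD_c).

    Rounds to the nearest integer and clips to ``[0, I0]``; composed with
    :func:`rgb_to_od` this is the identity up to quantization.
    """
    arr = od.od if isinstance(od, ODTile) else np.asarray(od, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative OD values")
    intensity = background_intensity * np.power(10.0, -arr)
    pixels = np.clip(np.rint(intensity), 0, background_intensity).astype(np.int64)
    return RGBTile(pixels, background_intensity)


# ---------------------------------------------------------------------------
# Basis estimation
# ---------------------------------------------------------------------------


def pool_od_pixels(
    tiles: Iterable[RGBTile],
    max_pixels: int = 200_000,
    min_od_norm: float = 0.1,
    epsilon: float = DEFAULT_LOG_EPSILON,
    seed: int = 0,
) -> np.ndarray:
    """Pool foreground OD pixels across a slide's tiles.

    Pixels with OD norm below ``min_od_norm`` (background / faint stain) are
    discarded; the remainder is subsampled uniformly to ``max_pixels`` with
    a fixed seed so the slide-level fit is deterministic.
    """
    chunks = []
    for tile in tiles:
        od = rgb_to_od(tile, epsilon).od.reshape(-1, 3)
        keep = np.linalg.norm(od, axis=1) >= min_od_norm
        if keep.any():
            chunks.append(od[keep])
    if not chunks:
        return np.empty((0, 3))
    pooled = np.concatenate(chunks, axis=0)
    if len(pooled) > max_pixels:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pooled), size=max_pixels, replace=False)
        pooled = pooled[np.sort(idx)]
    return pooled


def _quantile(values: np.ndarray, q: float) -> float:
    # Linear interpolation between order statistics; the 1% outlier rule
    # makes the angle estimate sensitive to the quantile convention.
    return float(np.quantile(values, q, method="linear"))


def fit_stain_basis(
    od_pixels: np.ndarray,
    outlier_fraction: float = 0.01,
    min_od_norm: float = 0.1,
    min_pixels: int = 1000,
    slide_id: str = "",
) -> StainBasis:
    """Estimate per-slide stain vectors from pooled OD pixels.

    PCA on the OD covariance gives the stain plane; each foreground pixel's
    in-plane angle is computed and the ``outlier_fraction`` /
    ``1 - outlier_fraction`` quantiles of the angle distribution define the
    two stain directions.  Axis signs are fixed so the Hematoxylin vector
    lands in quadrant IV (``theta_h < 0``) and Eosin in quadrant I
    (``theta_e > 0``).  Norm scales are left unset; see
    :func:`calibrate_norm_scales`.
    """
    od = np.asarray(od_pixels, dtype=float)
    if od.ndim != 2 or od.shape[1] != 3:
        raise ValueError("od_pixels must be (N, 3)")
    fg = od[np.linalg.norm(od, axis=1) >= min_od_norm]
    if len(fg) < min_pixels:
        raise InsufficientTissueError(
            f"only {len(fg)} foreground OD pixels (need >= {min_pixels})"
        )

    # Uncentered second-moment PCA (SVD of the raw OD tuples): the leading
    # axis then lies inside the stain sector, so in-plane angles straddle it
    # and the quadrant orientation below is well defined.  Centered
    # covariance would instead align V_x with the stain-difference direction.
    cov = (fg.T @ fg) / len(fg)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[1] <= max(evals[0] * 1e-9, 1e-12):
        raise SingularPlaneError("OD covariance rank < 2: no stain plane")

    v_x = evecs[:, 0]
    v_y = evecs[:, 1]
    v_res = evecs[:, 2]

    # Orient V_x along the bulk of the tissue (mean projection positive).
    if float(np.mean(fg @ v_x)) < 0:
        v_x = -v_x

    proj_x = fg @ v_x
    proj_y = fg @ v_y
    in_plane = np.hypot(proj_x, proj_y) >= min_od_norm
    if in_plane.sum() < min_pixels:
        raise InsufficientTissueError(
            f"only {int(in_plane.sum())} pixels usable for angle estimation"
        )
    phi = np.arctan2(proj_y[in_plane], proj_x[in_plane])

    theta_lo = _quantile(phi, outlier_fraction)
    theta_hi = _quantile(phi, 1.0 - outlier_fraction)
    v_lo = np.cos(theta_lo) * v_x + np.sin(theta_lo) * v_y
    v_hi = np.cos(theta_hi) * v_x + np.sin(theta_hi) * v_y

    # Hematoxylin absorbs more red light than Eosin: larger red OD component.
    if v_lo[0] >= v_hi[0]:
        theta_h, theta_e = theta_lo, theta_hi
    else:
        theta_h, theta_e = theta_hi, theta_lo
    # Flip V_y if needed so H sits in quadrant IV and E in quadrant I.
    if theta_h > 0:
        v_y = -v_y
        theta_h, theta_e = -theta_h, -theta_e
    if not (theta_h < 0.0 < theta_e):
        raise SingularPlaneError(
            "stain angles do not straddle the principal axis "
            f"(theta_h={theta_h:.4f}, theta_e={theta_e:.4f})"
        )

    v_h = np.cos(theta_h) * v_x + np.sin(theta_h) * v_y
    v_e = np.cos(theta_e) * v_x + np.sin(theta_e) * v_y
    return _assemble_basis(
        v_x, v_y, v_res, theta_h, theta_e, v_h, v_e, slide_id,
        params={
            "outlier_fraction": outlier_fraction,
            "min_od_norm": min_od_norm,
            "min_pixels": min_pixels,
            "n_pixels": int(len(fg)),
        },
    )


def _assemble_basis(v_x, v_y, v_res, theta_h, theta_e, v_h, v_e,
                    slide_id, params, norm_scale_h=None, norm_scale_e=None,
                    norm_target=0.5) -> StainBasis:
    # Fix residual sign for a right-handed frame; the residual channel is
    # discarded downstream so only invertibility matters.
    if np.dot(np.cross(v_x, v_y), v_res) < 0:
        v_res = -v_res
    forward = np.column_stack([v_h, v_e, v_res])
    if np.linalg.cond(forward) > CONDITION_LIMIT:
        raise IllConditionedBasisError("stain vectors nearly parallel")
    inverse = np.linalg.inv(forward)
    return StainBasis(
        axes=np.vstack([v_x, v_y, v_res]),
        theta_h=float(theta_h),
        theta_e=float(theta_e),
        v_h=v_h,
        v_e=v_e,
        forward_matrix=forward,
        inverse_matrix=inverse,
        slide_id=slide_id,
        norm_scale_h=norm_scale_h,
        norm_scale_e=norm_scale_e,
        norm_target=norm_target,
        params=dict(params),
    )


def basis_from_vectors(
    v_h: np.ndarray,
    v_e: np.ndarray,
    slide_id: str = "",
    norm_scale_h: float | None = None,
    norm_scale_e: float | None = None,
    norm_target: float = 0.5,
    params: Mapping | None = None,
) -> StainBasis:
    """Build a :class:`StainBasis` from known unit stain vectors.

    The plane axes are reconstructed so that ``V_x`` bisects the stain pair
    (hence ``theta_h < 0 < theta_e``).  Used for ground-truth bases in the
    simulator and for the fixed-matrix ablation.
    """
    v_h = np.asarray(v_h, dtype=float)
    v_e = np.asarray(v_e, dtype=float)
    v_h = v_h / np.linalg.norm(v_h)
    v_e = v_e / np.linalg.norm(v_e)
    v_x = v_h + v_e
    v_x = v_x / np.linalg.norm(v_x)
    v_y = v_e - np.dot(v_e, v_x) * v_x
    ny = np.linalg.norm(v_y)
    if ny < 1e-9:
        raise IllConditionedBasisError("stain vectors are parallel")
    v_y = v_y / ny
    v_res = np.cross(v_x, v_y)
    theta_h = float(np.arctan2(np.dot(v_h, v_y), np.dot(v_h, v_x)))
    theta_e = float(np.arctan2(np.dot(v_e, v_y), np.dot(v_e, v_x)))
    return _assemble_basis(
        v_x, v_y, v_res, theta_h, theta_e, v_h, v_e, slide_id,
        params=dict(params or {}),
        norm_scale_h=norm_scale_h,
        norm_scale_e=norm_scale_e,
        norm_target=norm_target,
    )


def fixed_default_basis(norm_target: float = 0.5) -> StainBasis:
    """Globally fixed stain basis for the non-adaptive separation ablation.

    Uses the standard published Ruifrok & Johnston H/E OD vectors with unit
    normalization (norm scales equal to the target, i.e. concentrations pass
    through unscaled).
    """
    return basis_from_vectors(
        RUIFROK_H_OD,
        RUIFROK_E_OD,
        slide_id="__fixed__",
        norm_scale_h=norm_target,
        norm_scale_e=norm_target,
        norm_target=norm_target,
        params={"source": "Ruifrok & Johnston 2001 color deconvolution"},
    )


# ---------------------------------------------------------------------------
# Projection and normalization
# ---------------------------------------------------------------------------


def project_to_concentrations(
    od: ODTile | np.ndarray, basis: StainBasis
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project OD pixels onto the stain basis: raw (alpha_H, alpha_E, alpha_res).

    Accepts an :class:`ODTile` or an ``(..., 3)`` array.  Small negative
    stain concentrations arising from noise are clipped to 0; the residual
    coordinate is returned unclipped (it is only used for reconstruction).
    """
    if np.linalg.cond(basis.forward_matrix) > CONDITION_LIMIT:
        raise IllConditionedBasisError("basis condition number too large")
    arr = od.od if isinstance(od, ODTile) else np.asarray(od, dtype=float)
    alphas = arr @ basis.inverse_matrix.T
    alpha_h = np.maximum(alphas[..., 0], 0.0)
    alpha_e = np.maximum(alphas[..., 1], 0.0)
    alpha_res = alphas[..., 2]
    return alpha_h, alpha_e, alpha_res


def calibrate_norm_scales(
    basis: StainBasis,
    alpha_h_samples: np.ndarray,
    alpha_e_samples: np.ndarray,
    percentile: float = 99.0,
    target: float = 0.5,
) -> StainBasis:
    """Set per-slide normalization scales from pooled raw concentrations.

    The ``percentile``-th quantile of each channel's raw concentrations
    becomes its norm scale; normalization later divides by
    ``scale / target`` and clips to 1, so a raw value equal to the scale
    maps to ``target``.
    """
    scales = []
    for name, samples in (("H", alpha_h_samples), ("E", alpha_e_samples)):
        samples = np.asarray(samples, dtype=float).ravel()
        if samples.size == 0:
            raise ValueError("empty concentration samples")
        s = _quantile(samples, percentile / 100.0)
        if s <= 0:
            warnings.warn(
                f"all-zero {name} concentrations; scale set to 1",
                DegenerateStainWarning,
            )
            s = 1.0
        scales.append(s)
    params = dict(basis.params)
    params.update({"percentile": percentile, "target": target})
    return replace(
        basis,
        norm_scale_h=scales[0],
        norm_scale_e=scales[1],
        norm_target=target,
        params=params,
    )


def separate_tile(tile: RGBTile, basis: StainBasis,
                  epsilon: float = DEFAULT_LOG_EPSILON) -> ChannelPair:
    """Separate an RGB tile into normalized H and E concentration images."""
    if not basis.calibrated:
        raise ValueError("basis not calibrated: norm scales unset")
    od = rgb_to_od(tile, epsilon)
    alpha_h, alpha_e, _ = project_to_concentrations(od, basis)
    h = np.clip(alpha_h / (basis.norm_scale_h / basis.norm_target), 0.0, 1.0)
    e = np.clip(alpha_e / (basis.norm_scale_e / basis.norm_target), 0.0, 1.0)
    return ChannelPair(h, e, basis_ref=basis.slide_id)


def fit_slide_basis(
    tiles: Sequence[RGBTile],
    outlier_fraction: float = 0.01,
    min_od_norm: float = 0.1,
    min_pixels: int = 1000,
    max_pixels: int = 200_000,
    percentile: float = 99.0,
    target: float = 0.5,
    epsilon: float = DEFAULT_LOG_EPSILON,
    seed: int = 0,
    slide_id: str | None = None,
) -> StainBasis:
    """Fit and calibrate a stain basis for one slide from its tiles."""
    if slide_id is None:
        slide_id = tiles[0].slide_id if tiles else ""
    pooled = pool_od_pixels(tiles, max_pixels=max_pixels,
                            min_od_norm=min_od_norm, epsilon=epsilon, seed=seed)
    basis = fit_stain_basis(pooled, outlier_fraction=outlier_fraction,
                            min_od_norm=min_od_norm, min_pixels=min_pixels,
                            slide_id=slide_id)
    alpha_h, alpha_e, _ = project_to_concentrations(pooled, basis)
    return calibrate_norm_scales(basis, alpha_h, alpha_e,
                                 percentile=percentile, target=target)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_bases(bases: Mapping[str, StainBasis], path) -> None:
    payload = {sid: b.to_dict() for sid, b in bases.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_bases(path) -> dict[str, StainBasis]:
    with open(path) as fh:
        payload = json.load(fh)
    return {sid: StainBasis.from_dict(d) for sid, d in payload.items()}
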