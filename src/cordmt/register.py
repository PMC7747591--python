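"""Cord segmentation and rigid in-plane co-registration of an MT image pair.

The MT-off image (``i_o``) is registered onto the MT-on image (``i_mt``) with
an in-plane rigid transform (translation + rotation), initialized from the
centers of mass of the two cord masks and refined by maximizing normalized
cross-correlation (NCC) inside a circular mask (default diameter 35 voxels)
centered on the ``i_mt`` cord centroid.

Coordinate convention: 0-based pixel indices in ``(row, col)`` order. A
transform maps an input point ``p`` to ``R(theta) @ (p - c) + c + t`` where
``c`` is the rotation center and ``t = (tx, ty)`` is the ``(row, col)``
translation. Positive ``theta`` rotates the +row axis toward the +col axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

#: Intervertebral levels retained for analysis.
ALLOWED_LEVELS = ("C2/3", "C3/4", "C4/5", "C5/6")


@dataclass
class SlicePair:
    """One intervertebral level's co-acquired MT-off / MT-on image pair.

    ``i_o`` is the image without the MT saturation pulse, ``i_mt`` the image
    with it. ``truth`` optionally carries phantom ground truth (per-tract MTR,
    applied misalignment) for simulated pairs.
    """

    i_o: np.ndarray
    i_mt: np.ndarray
    level: str
    pixel_size_mm: float
    subject_id: str = ""
    quality_flag: str = "ok"
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.i_o = np.asarray(self.i_o, dtype=float)
        self.i_mt = np.asarray(self.i_mt, dtype=float)
        if self.i_o.shape != self.i_mt.shape:
            raise ValueError(
                f"i_o shape {self.i_o.shape} != i_mt shape {self.i_mt.shape}"
            )
        if self.level not in ALLOWED_LEVELS:
            raise ValueError(f"level {self.level!r} not in {ALLOWED_LEVELS}")


@dataclass
class RigidTransform:
    """In-plane rigid transform: rotation by ``theta_deg`` about ``center``
    followed by translation ``(tx_vox, ty_vox)`` in ``(row, col)`` voxels."""

    tx_vox: float = 0.0
    ty_vox: float = 0.0
    theta_deg: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    ncc: Optional[float] = None
    flag: str = "ok"

    @property
    def is_identity(self) -> bool:
        return self.tx_vox == 0.0 and self.ty_vox == 0.0 and self.theta_deg == 0.0

    def rotation_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, s], [-s, c]])

    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 forward map acting on (row, col, 1) columns."""
        R = self.rotation_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.array([self.tx_vox, self.ty_vox])
        M = np.eye(3)
        M[:2, :2] = R
        M[:2, 2] = c - R @ c + t
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, center: tuple[float, float] = (0.0, 0.0)) -> "RigidTransform":
        theta = np.rad2deg(np.arctan2(M[0, 1], M[0, 0]))
        R = M[:2, :2]
        c = np.asarray(center, dtype=float)
        t = M[:2, 2] - c + R @ c
        return cls(tx_vox=float(t[0]), ty_vox=float(t[1]), theta_deg=float(theta), center=center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix(), center=self.center)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()), center=self.center)


def resample(image: np.ndarray, transform: RigidTransform, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Apply a rigid transform to a 2-D image.

    The output satisfies ``out[p'] = image[T^{-1}(p')]``, so features move
    with the forward map. ``order=1`` is bilinear (the default used in both
    optimization and the final resample), ``order=0`` nearest-neighbor. The
    identity transform returns a bit-identical copy.
    """
    image = np.asarray(image, dtype=float)
    if transform.is_identity:
        return image.copy()
    Minv = np.linalg.inv(transform.matrix())
    return ndimage.affine_transform(
        image, Minv[:2, :2], offset=Minv[:2, 2], order=order, mode="constant", cval=cval
    )


def segment_cord(
    image: np.ndarray,
    pixel_size_mm: float = 0.5,
    expected_area_mm2: float = 110.0,
) -> tuple[np.ndarray, bool]:
    """Segment the spinal cord from an axial slice by intensity classes.

    The cord parenchyma occupies the middle of three intensity classes
    (air/background below, bright CSF above); the mask is the largest
    4-connected middle-class component, morphologically closed and
    hole-filled.

    Returns ``(mask, ok)``. ``ok`` is False (mask may still be returned) when
    no plausible cord is found or the mask area falls outside 25%-400% of
    ``expected_area_mm2``; callers should then set the slice quality flag to
    ``rejected``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_cord expects a 2-D image")
    empty = np.zeros(image.shape, dtype=bool)
    if not np.any(image > 0):
        return empty, False
    finite = image[np.isfinite(image)]
    try:
        lo, hi = threshold_multiotsu(image, classes=3)
    except ValueError:
        # fewer than 3 distinct grey levels; fall back to a single Otsu split
        try:
            lo = threshold_otsu(image)
        except ValueError:
            return empty, False
        hi = finite.max() + 1.0
    candidate = (image > lo) & (image <= hi)
    if not candidate.any():
        return empty, False
    lab = label(candidate, connectivity=1)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = lab == int(np.argmax(sizes))
    mask = ndimage.binary_closing(mask, structure=disk(2))
    mask = ndimage.binary_fill_holes(mask)
    # keep a single 4-connected component after closing
    lab = label(mask, connectivity=1)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = lab == int(np.argmax(sizes))
    area_mm2 = mask.sum() * pixel_size_mm**2
    ok = 0.25 * expected_area_mm2 <= area_mm2 <= 4.0 * expected_area_mm2
    return mask, bool(ok)


def _center_of_mass(mask: np.ndarray) -> np.ndarray:
    return np.array(ndimage.center_of_mass(mask.astype(float)))


def _circular_mask(shape: tuple[int, int], center: np.ndarray, diameter_vox: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= (diameter_vox / 2.0) ** 2


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Normalized cross-correlation of two images over a boolean mask."""
    av = a[mask].astype(float)
    bv = b[mask].astype(float)
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


@dataclass
class RegistrationConfig:
    """Search settings for :func:`register_rigid`.

    The coarse rotation/translation grid is scored with fast linear
    interpolation; the simplex refinement uses ``refine_order`` (cubic by
    default — linear interpolation biases the rotation estimate on smooth
    images by a few tenths of a degree). ``interp_order`` is the order of
    the final resample.
    """

    mask_diameter_vox: float = 35.0
    theta_range_deg: float = 10.0
    theta_step_deg: float = 0.5
    translation_search_vox: int = 2  # +/- window of the coarse translation grid
    interp_order: int = 1
    refine_order: int = 3
    xatol: float = 0.01
    min_ncc: float = 0.5  # quality gate applied downstream


def register_rigid(
    i_o: np.ndarray,
    i_mt: np.ndarray,
    cord_mask_o: np.ndarray,
    cord_mask_mt: np.ndarray,
    config: RegistrationConfig | None = None,
) -> RigidTransform:
    """Find the rigid transform aligning ``i_o`` onto ``i_mt``.

    Two stages: (1) translation initialization from the cord-mask centers of
    mass; (2) NCC maximization inside a circular mask centered on the
    ``i_mt`` cord centroid — a coarse grid over rotation angle with a local
    translation grid per angle, then Nelder-Mead refinement of
    ``(tx, ty, theta)``. The rotation center is the ``i_mt`` cord centroid.

    If refinement fails to improve on the center-of-mass initialization the
    initialization is returned with ``flag='com_only'``.
    """
    if config is None:
        config = RegistrationConfig()
    i_o = np.asarray(i_o, dtype=float)
    i_mt = np.asarray(i_mt, dtype=float)
    if not cord_mask_o.any() or not cord_mask_mt.any():
        raise ValueError("register_rigid requires non-empty cord masks")

    center = _center_of_mass(cord_mask_mt)
    t0 = _center_of_mass(cord_mask_mt) - _center_of_mass(cord_mask_o)

    # crop to the cost-mask bounding box (+ search margin) for speed
    margin = int(np.ceil(np.abs(t0).max())) + config.translation_search_vox + 8
    half = config.mask_diameter_vox / 2.0
    r0 = max(int(center[0] - half) - margin, 0)
    r1 = min(int(center[0] + half) + margin + 1, i_mt.shape[0])
    c0 = max(int(center[1] - half) - margin, 0)
    c1 = min(int(center[1] + half) + margin + 1, i_mt.shape[1])
    io_c = i_o[r0:r1, c0:c1]
    imt_c = i_mt[r0:r1, c0:c1]
    center_c = center - np.array([r0, c0])
    cost_mask = _circular_mask(imt_c.shape, center_c, config.mask_diameter_vox)

    def score(params: np.ndarray, order: int) -> float:
        T = RigidTransform(params[0], params[1], params[2], center=tuple(center_c))
        warped = resample(io_c, T, order=order)
        return ncc(warped, imt_c, cost_mask)

    com_tf = RigidTransform(float(t0[0]), float(t0[1]), 0.0, center=tuple(center))
    com_ncc = score(np.array([t0[0], t0[1], 0.0]), config.refine_order)

    thetas = np.arange(
        -config.theta_range_deg, config.theta_range_deg + 1e-9, config.theta_step_deg
    )
    w = config.translation_search_vox
    shifts = np.arange(-w, w + 1, 1.0)
    best = (score(np.array([t0[0], t0[1], 0.0]), 1), np.array([t0[0], t0[1], 0.0]))
    for th in thetas:
        for dr in shifts:
            for dc in shifts:
                p = np.array([t0[0] + dr, t0[1] + dc, th])
                s = score(p, 1)
                if s > best[0]:
                    best = (s, p)

    # explicit initial simplex: scipy's default perturbs zero coordinates by
    # ~2.5e-4, which strands the rotation at a theta=0 start
    x0 = best[1]
    simplex = np.vstack([x0, x0 + [0.5, 0, 0], x0 + [0, 0.5, 0], x0 + [0, 0, 0.5]])
    try:
        res = optimize.minimize(
            lambda p: -score(p, config.refine_order),
            x0,
            method="Nelder-Mead",
            options={
                "xatol": config.xatol,
                "fatol": 1e-8,
                "maxiter": 400,
                "initial_simplex": simplex,
            },
        )
        refined = res.x
        refined_ncc = score(refined, config.refine_order)
    except Exception:  # pragma: no cover - scipy failure path
        refined = best[1]
        refined_ncc = score(refined, config.refine_order)

    coarse_ncc = score(best[1], config.refine_order)
    if refined_ncc < coarse_ncc:
        refined, refined_ncc = best[1], coarse_ncc
    if refined_ncc < com_ncc:
        return replace(com_tf, ncc=com_ncc, flag="com_only")
    return RigidTransform(
        float(refined[0]),
        float(refined[1]),
        float(refined[2]),
        center=tuple(center),
        ncc=refined_ncc,
    )
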