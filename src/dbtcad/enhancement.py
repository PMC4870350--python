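"""Microcalcification enhancement: multiscale Hessian objectness, band-pass
SNR filtering, and their voxelwise product (the MOR field).

The objectness response scores how *blob-like* the local second-order
structure is.  The volume is smoothed with an anisotropy-aware 3D Gaussian at
scale sigma (mm), the 3x3 Hessian of second derivatives (physical units,
grey-level/mm^2) is diagonalized, and eigenvalues ``lam1 <= lam2 <= lam3`` are
fed to a two-factor response: a shape factor discriminating spheres from
lines/planes and a structureness factor suppressing low-contrast noise.  A
bright blob has three roughly equal negative eigenvalues; a bright line has
one near-zero eigenvalue; a bright plane has two.

Two shape-factor variants are provided.  ``as_printed`` uses
``lam1^2 / (2 alpha^2 lam2 lam3)``, which saturates to 1 for lines where
``lam3 -> 0-`` and therefore does not by itself isolate spheres;
``blobness_corrected`` (the default) uses the conventional
smallest-over-largest magnitude ratio ``lam3^2 / (2 alpha^2 |lam1 lam2|)``,
which vanishes identically for ideal lines and planes.  Both share the gate
``lam3 <= 0`` (bright structures on a darker background) and the same
structureness factor ``1 - exp(-(lam1^2+lam2^2+lam3^2)/(2 gamma^2))``.

The SNR enhancement is a 2D zero-DC band-pass filter applied to each slice
independently: the mean over a small M3 x M3 core minus the mean over the
annulus between M2 x M2 and M1 x M1 windows, with a guard ring in between to
keep pixels adjacent to the candidate out of the background estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume_io import Volume

_BOUNDARY = "reflect"  # reflective padding everywhere: no rim artifacts


@dataclass
class ObjectnessParams:
    """Parameters of the blob-objectness response.

    alpha : dimensionless shape sensitivity (default 0.1).
    gamma : structureness scale in the units of the smoothed Hessian
        eigenvalues, grey-level/mm^2 (default 3.0).
    scales : Gaussian smoothing sigmas in mm, strictly increasing; three
        scales spanning sub-voxel to ~3-voxel blobs on a ~1 mm grid.
    mode : ``blobness_corrected`` (default) or ``as_printed``; see module
        docstring.
    """

    alpha: float = 0.1
    gamma: float = 3.0
    scales: tuple[float, ...] = (0.5, 1.0, 1.5)
    mode: str = "blobness_corrected"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValidationError("alpha and gamma must be positive")
        self.scales = tuple(float(s) for s in self.scales)
        if len(self.scales) < 1 or any(s <= 0 for s in self.scales):
            raise ValidationError("scales must be a non-empty list of positive sigmas")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ValidationError("scales must be strictly increasing")
        if self.mode not in ("as_printed", "blobness_corrected"):
            raise ValidationError(f"unknown objectness mode {self.mode!r}")


@dataclass
class BandPassFilterSpec:
    """Window sizes (full-resolution pixels, odd) of the three mean filters."""

    M1: int = 15
    M2: int = 7
    M3: int = 3

    def __post_init__(self) -> None:
        for m in (self.M1, self.M2, self.M3):
            if m % 2 == 0 or m < 1:
                raise ValidationError(f"filter sizes must be odd positive, got {m}")
        if not (self.M1 > self.M2 > self.M3):
            raise ValidationError(
                f"need M1 > M2 > M3, got {self.M1}, {self.M2}, {self.M3}"
            )


@dataclass
class Kernel2D:
    """An explicit 2D convolution kernel with its center index."""

    weights: np.ndarray
    center: tuple[int, int]


# ---------------------------------------------------------------------------
# Gaussian smoothing and Hessian
# ---------------------------------------------------------------------------


def gaussian_smooth(v: Volume, sigma_mm: float) -> Volume:
    """Separable 3D Gaussian smoothing with per-axis sigma in *voxels* equal
    to ``sigma_mm / spacing_axis`` (anisotropy-aware)."""
    if sigma_mm <= 0:
        raise ValidationError(f"sigma_mm must be positive, got {sigma_mm}")
    sig_vox = [sigma_mm / s for s in v.spacing]
    out = ndimage.gaussian_filter(v.data.astype(np.float64), sig_vox, mode=_BOUNDARY)
    return v.with_data(out)


def hessian_eigenvalues(v: Volume, sigma_mm: float) -> np.ndarray:
    """Eigenvalues of the smoothed Hessian at every voxel, ascending.

    The volume is Gaussian-smoothed at ``sigma_mm``, second derivatives are
    taken by central differences in physical units (divided by the spacing
    products), and the symmetric 3x3 matrix is diagonalized per voxel.
    Returns an array of shape ``v.shape + (3,)``.
    """
    if min(v.shape) < 3:
        raise ValidationError(f"need at least 3 voxels per axis, got shape {v.shape}")
    g = gaussian_smooth(v, sigma_mm).data
    sp = v.spacing

    def d2(axis: int) -> np.ndarray:
        w = np.array([1.0, -2.0, 1.0]) / sp[axis] ** 2
        return ndimage.correlate1d(g, w, axis=axis, mode=_BOUNDARY)

    def d1(arr: np.ndarray, axis: int) -> np.ndarray:
        w = np.array([-0.5, 0.0, 0.5]) / sp[axis]
        return ndimage.correlate1d(arr, w, axis=axis, mode=_BOUNDARY)

    H = np.empty(v.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        H[..., i, i] = d2(i)
    for i in range(3):
        gi = d1(g, i)
        for j in range(i + 1, 3):
            H[..., i, j] = H[..., j, i] = d1(gi, j)
    return np.linalg.eigvalsh(H)


# ---------------------------------------------------------------------------
# Objectness response
# ---------------------------------------------------------------------------

_EPS_GUARD = 1e-12


def objectness_response(eigenvalues: np.ndarray, p: ObjectnessParams) -> np.ndarray:
    """Blob-objectness response from Hessian eigenvalues.

    Accepts any array whose last axis holds the three eigenvalues (in any
    order; they are sorted ascending internally, so the result is invariant
    to the presentation order).  Returns a non-negative response of the
    leading shape; scalar input ``(3,)`` yields a 0-d array.

    The response is gated to bright structures: it is 0 wherever the largest
    eigenvalue ``lam3 > 0``.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=np.float64), axis=-1)
    if lam.shape[-1] != 3:
        raise ValidationError("expected 3 eigenvalues on the last axis")
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    frob2 = l1 * l1 + l2 * l2 + l3 * l3
    structureness = -np.expm1(-frob2 / (2.0 * p.gamma**2))

    with np.errstate(divide="ignore", invalid="ignore"):
        if p.mode == "as_printed":
            num = l1 * l1
            denom = 2.0 * p.alpha**2 * l2 * l3
            shape = -np.expm1(-num / denom)
            # lam2*lam3 vanishing with lam1 nonzero: ratio -> infinity, shape -> 1
            tiny = denom < _EPS_GUARD * num
            shape = np.where(tiny & (num > 0), 1.0, shape)
            shape = np.where(num == 0, 0.0, shape)
        else:  # blobness_corrected
            num = l3 * l3
            denom = 2.0 * p.alpha**2 * np.abs(l1 * l2)
            shape = -np.expm1(-num / denom)
            # under the gate |l3| <= |l2| <= |l1|, denom == 0 forces l3 == 0
            shape = np.where(denom == 0, 0.0, shape)

    out = np.where(l3 <= 0, shape * structureness, 0.0)
    return out


def multiscale_objectness(v: Volume, p: ObjectnessParams) -> Volume:
    """Pointwise maximum of the objectness response over the scale list.

    Ties keep the smallest scale's value (scales are visited in ascending
    order and only strictly larger responses replace the current one, which
    is observationally identical since tied responses are equal).
    """
    best: np.ndarray | None = None
    for sigma in p.scales:
        resp = objectness_response(hessian_eigenvalues(v, sigma), p)
        best = resp if best is None else np.maximum(best, resp)
    assert best is not None
    return v.with_data(best)


# ---------------------------------------------------------------------------
# Band-pass SNR enhancement
# ---------------------------------------------------------------------------


def build_bandpass_kernel(spec: BandPassFilterSpec = BandPassFilterSpec()) -> Kernel2D:
    """Explicit M1 x M1 zero-sum band-pass kernel.

    Center ``M3 x M3`` pixels weigh ``+1/M3^2`` (the core mean), the annulus
    between the ``M2 x M2`` and ``M1 x M1`` windows weighs
    ``-1/(M1^2 - M2^2)`` (the background mean), and the guard ring between
    M3 and M2 is zero.  The weights sum to exactly 1 - 1 = 0, so constant
    backgrounds produce no response.
    """
    m1, m2, m3 = spec.M1, spec.M2, spec.M3
    c = m1 // 2
    w = np.zeros((m1, m1), dtype=np.float64)
    w[:] = -1.0 / (m1 * m1 - m2 * m2)  # annulus value, fixed below
    lo2, hi2 = c - m2 // 2, c + m2 // 2 + 1
    w[lo2:hi2, lo2:hi2] = 0.0  # guard ring + excluded M2 core
    lo3, hi3 = c - m3 // 2, c + m3 // 2 + 1
    w[lo3:hi3, lo3:hi3] = 1.0 / (m3 * m3)
    return Kernel2D(w, (c, c))


def snr_enhance(v: Volume, k: Kernel2D | BandPassFilterSpec) -> Volume:
    """Convolve every z slice with the band-pass kernel and clamp at zero.

    Negative band-pass responses carry no microcalcification evidence and
    are clipped to 0.  Boundary handling is reflective.  When given a
    :class:`BandPassFilterSpec` the response is computed through three
    separable box means (algebraically identical to the explicit kernel and
    much faster); an explicit :class:`Kernel2D` is convolved directly.
    """
    data = v.data.astype(np.float64)
    if isinstance(k, BandPassFilterSpec):
        m1 = k.M1
        _check_extent(v, m1)
        out = _bandpass_by_boxes(data, k)
    else:
        m1 = k.weights.shape[0]
        _check_extent(v, m1)
        out = ndimage.convolve(data, k.weights[:, :, None], mode=_BOUNDARY)
    np.clip(out, 0.0, None, out=out)
    return v.with_data(out)


def _check_extent(v: Volume, m1: int) -> None:
    if v.shape[0] < m1 or v.shape[1] < m1:
        raise ValidationError(
            f"in-plane extent {v.shape[:2]} smaller than kernel size {m1}"
        )


def _bandpass_by_boxes(data: np.ndarray, spec: BandPassFilterSpec) -> np.ndarray:
    m1, m2, m3 = spec.M1, spec.M2, spec.M3
    u = {
        m: ndimage.uniform_filter(data, size=(m, m, 1), mode=_BOUNDARY)
        for m in (m1, m2, m3)
    }
    annulus = (m1 * m1 * u[m1] - m2 * m2 * u[m2]) / (m1 * m1 - m2 * m2)
    return u[m3] - annulus


# ---------------------------------------------------------------------------
# Combination
# ---------------------------------------------------------------------------


def compute_mor(objectness: Volume, snr: Volume) -> Volume:
    """Voxelwise product of the objectness and SNR-enhanced fields.

    Both inputs must live on the identical grid (shape, spacing, origin);
    resample one to the other first if they do not (the reference pipeline
    max-pools the full-resolution SNR field onto the subsampled objectness
    grid with :func:`dbtcad.volume_io.subsample_xy`).
    """
    if not objectness.same_grid(snr, tol=1e-6):
        raise ValidationError(
            "objectness and SNR fields are on different grids: "
            f"{objectness.shape}/{objectness.spacing} vs {snr.shape}/{snr.spacing}"
        )
    return objectness.with_data(objectness.data * snr.data)
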