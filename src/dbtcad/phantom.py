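"""Synthetic DBT-like phantom volumes with known microcalcification-cluster
ground truth.

The generator emulates the statistics the detector cares about, not breast
anatomy: a textured background normalized to unit noise standard deviation,
bright compact Gaussian blobs (microcalcification analogues, full width at
half maximum 0.2-0.8 mm) grouped in clusters of <= 5 mm radius, elongated
(cylinder) and planar (slab) distractors at comparable contrast, and a
Gaussian blur along the slice axis standing in for the interplanar artifacts
of limited-angle reconstruction, which smear objects in the depth direction.

Grey levels are scaled so the *final* background noise standard deviation is
1, which keeps SNR-type thresholds and the structureness scale meaningful
across phantoms; blob amplitudes are pre-compensated for the depth blur so
``mc_contrast`` is the post-blur peak height above background in noise-sigma
units.  Truth geometry (centers, diameters, boxes) is recorded before
blurring, as an annotator would mark the underlying deposit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .errors import GenerationError, ValidationError
from .volume_io import Annotation, Volume

logger = logging.getLogger(__name__)


@dataclass
class PhantomConfig:
    """Phantom synthesis parameters (defaults define the study conditions).

    The default grid is a 25.6 x 25.6 x 40 mm block at the reference
    reconstruction geometry (0.1 mm in-plane pitch, 1 mm slice interval).
    ``mc_contrast`` is in multiples of the background noise sigma (post
    depth-blur); clinically conspicuous microcalcifications sit well above
    the noise floor, hence the default of 12.
    """

    shape: tuple[int, int, int] = (256, 256, 40)
    spacing: tuple[float, float, float] = (0.1, 0.1, 1.0)
    n_clusters: int = 3
    mcs_per_cluster: tuple[int, int] = (8, 15)
    cluster_radius_mm: float = 4.0
    mc_diameter_mm: tuple[float, float] = (0.2, 0.8)
    mc_contrast: float = 12.0
    n_line_distractors: int = 3
    n_plane_distractors: int = 1
    distractor_contrast: float = 8.0
    background: str = "correlated-noise"
    z_blur_sigma_mm: float = 1.5
    rng_seed: int = 0
    margin_mm: float = 6.0
    line_orientations_deg: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 4 for n in self.shape):
            raise ValidationError(f"shape must be 3 sizes >= 4, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if self.mc_diameter_mm[0] <= 0 or self.mc_diameter_mm[0] > self.mc_diameter_mm[1]:
            raise ValidationError("mc_diameter_mm must be a positive (lo, hi) range")
        if self.cluster_radius_mm <= 0:
            raise ValidationError("cluster_radius_mm must be positive")
        if self.background not in ("flat", "correlated-noise", "low-frequency-gradient"):
            raise ValidationError(f"unknown background {self.background!r}")
        ext = self.extent_mm
        need = 2 * self.margin_mm + 2 * self.cluster_radius_mm
        if self.n_clusters > 0 and (ext[0] < need or ext[1] < need):
            raise ValidationError(
                f"in-plane extent {ext[:2]} mm too small for clusters with "
                f"margin {self.margin_mm} mm"
            )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @classmethod
    def subsampled_grid(cls, **overrides) -> "PhantomConfig":
        """A profile matching the grid after x10 in-plane subsampling
        (about 1 mm isotropic); useful for fast grid-level experiments."""
        defaults = dict(shape=(64, 64, 40), spacing=(1.0, 1.0, 1.0), margin_mm=8.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class MCRecord:
    center_mm: np.ndarray
    diameter_mm: float
    contrast: float
    cluster_index: int


@dataclass
class LineRecord:
    point_mm: np.ndarray
    direction: np.ndarray  # unit vector, in-plane
    sigma_mm: float
    half_length_mm: float
    contrast: float


@dataclass
class PlaneRecord:
    z_mm: float
    sigma_mm: float
    center_xy_mm: np.ndarray
    radius_mm: float
    contrast: float


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom: one box annotation per cluster,
    per-microcalcification records, and distractor geometry."""

    cluster_boxes: list[Annotation] = field(default_factory=list)
    mcs: list[MCRecord] = field(default_factory=list)
    lines: list[LineRecord] = field(default_factory=list)
    planes: list[PlaneRecord] = field(default_factory=list)


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _insert_blob(
    data: np.ndarray,
    cfg: PhantomConfig,
    center_mm: np.ndarray,
    sigma_mm: float,
    contrast: float,
) -> None:
    """Add an isotropic Gaussian blob whose depth profile is integrated over
    each slice interval (a slice-sensitivity model).

    Point-sampling a sub-slice-thick object on a coarse slice grid would
    make its inserted amplitude depend violently on its sub-slice position;
    slice integration preserves the deposit's signal wherever it sits.  The
    profile is normalized so the peak *after* the configured depth blur
    equals ``contrast``.
    """
    sp = np.asarray(cfg.spacing)
    dz = sp[2]
    z_centers = np.arange(data.shape[2]) * dz
    a = (z_centers - dz / 2 - center_mm[2]) / (np.sqrt(2) * sigma_mm)
    b = (z_centers + dz / 2 - center_mm[2]) / (np.sqrt(2) * sigma_mm)
    pz = 0.5 * (erf(b) - erf(a))
    if cfg.z_blur_sigma_mm > 0:
        blurred = ndimage.gaussian_filter1d(pz, cfg.z_blur_sigma_mm / dz, mode="constant")
    else:
        blurred = pz
    peak = float(blurred.max())
    if peak <= 0:
        return
    pz = pz / peak
    center_idx = center_mm / sp
    half = np.maximum(np.ceil(4.0 * sigma_mm / sp[:2]).astype(int), 1)
    lo = np.maximum(np.floor(center_idx[:2]).astype(int) - half, 0)
    hi = np.minimum(np.floor(center_idx[:2]).astype(int) + half + 1, np.array(data.shape[:2]))
    x = np.arange(lo[0], hi[0]) * sp[0] - center_mm[0]
    y = np.arange(lo[1], hi[1]) * sp[1] - center_mm[1]
    xy = np.exp(-(x[:, None] ** 2 + y[None, :] ** 2) / (2.0 * sigma_mm**2))
    kz = np.flatnonzero(pz > 1e-8)
    data[lo[0] : hi[0], lo[1] : hi[1], kz] += contrast * xy[:, :, None] * pz[kz]


def _insert_line(
    data: np.ndarray,
    cfg: PhantomConfig,
    point_mm: np.ndarray,
    direction: np.ndarray,
    sigma_mm: float,
    amplitude: float,
    half_length_mm: float,
    end_taper_mm: float = 2.5,
) -> None:
    """Gaussian-profile cylinder through ``point_mm`` along ``direction``
    (unit vector), fading axially over ``end_taper_mm`` beyond
    ``half_length_mm``.  The taper is deliberately soft: a fiber that ended
    within its own cross-section width would present a point-like tip, which
    is a blob, not a line."""
    sp = np.asarray(cfg.spacing)
    coords = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(data.shape, sp)), indexing="ij"
    )
    rel = [c - p for c, p in zip(coords, point_mm)]
    axial = sum(r * d for r, d in zip(rel, direction))
    perp2 = sum(r * r for r in rel) - axial * axial
    overshoot = np.clip(np.abs(axial) - half_length_mm, 0, None)
    envelope = np.exp(-(overshoot**2) / (2 * end_taper_mm**2))
    data += amplitude * np.exp(-np.clip(perp2, 0, None) / (2.0 * sigma_mm**2)) * envelope


def _insert_plane(
    data: np.ndarray,
    cfg: PhantomConfig,
    z_mm: float,
    sigma_mm: float,
    amplitude: float,
    center_xy_mm: np.ndarray,
    radius_mm: float,
) -> None:
    """Gaussian-profile slab normal to z with a lateral Gaussian envelope
    (a bright partial plane, mimicking in-plane structured tissue)."""
    sp = np.asarray(cfg.spacing)
    x = np.arange(data.shape[0]) * sp[0]
    y = np.arange(data.shape[1]) * sp[1]
    z = np.arange(data.shape[2]) * sp[2]
    lat2 = (x[:, None] - center_xy_mm[0]) ** 2 + (y[None, :] - center_xy_mm[1]) ** 2
    lateral = np.exp(-lat2 / (2.0 * radius_mm**2))
    profile = np.exp(-((z - z_mm) ** 2) / (2.0 * sigma_mm**2))
    data += amplitude * lateral[:, :, None] * profile[None, None, :]


def _background(
    cfg: PhantomConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Returns ``(noise, deterministic_trend)``; noise is later normalized
    to unit sigma after the depth blur, the trend is added as-is."""
    shape = cfg.shape
    zero = np.zeros(shape)
    if cfg.background == "flat":
        return zero, zero
    noise = rng.standard_normal(shape)
    if cfg.background == "correlated-noise":
        # mild in-plane smoothing gives tissue-like speckle correlation
        noise = ndimage.gaussian_filter(noise, sigma=(1.0, 1.0, 0.0), mode="reflect")
    trend = zero
    if cfg.background == "low-frequency-gradient":
        sp = np.asarray(cfg.spacing)
        ext = np.asarray(cfg.extent_mm)
        x = np.arange(shape[0]) * sp[0] / ext[0]
        y = np.arange(shape[1]) * sp[1] / ext[1]
        trend = np.broadcast_to(
            3.0 * (x[:, None, None] + y[None, :, None]), shape
        ).copy()
    return noise, trend


def _z_blur_peak_factor(sigma_blob_mm: float, cfg: PhantomConfig) -> float:
    """Peak attenuation of a blob's discrete z profile under the depth blur.

    Computed on the actual slice grid: the blob's z profile sampled at the
    slice interval, convolved with the discrete blur kernel, peak compared
    to the unblurred peak.  Falls back to 1 when no blur is requested.
    """
    if cfg.z_blur_sigma_mm <= 0:
        return 1.0
    dz = cfg.spacing[2]
    half = int(np.ceil(4 * (sigma_blob_mm + cfg.z_blur_sigma_mm) / dz)) + 1
    zz = np.arange(-half, half + 1) * dz
    profile = np.exp(-(zz**2) / (2 * sigma_blob_mm**2))
    sig_vox = cfg.z_blur_sigma_mm / dz
    blurred = ndimage.gaussian_filter1d(profile, sig_vox, mode="constant")
    return float(blurred.max() / profile.max())


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, PhantomTruth]:
    """Synthesize one phantom volume and its ground truth.

    Deterministic for a fixed ``cfg.rng_seed`` (bit-identical output).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    sp = np.asarray(cfg.spacing)
    ext = np.asarray(cfg.extent_mm)

    noise_free = np.zeros(cfg.shape)
    truth = PhantomTruth()

    # --- clusters of MC analogues -------------------------------------
    centers = _place_cluster_centers(cfg, rng)
    for ci, ccenter in enumerate(centers):
        n_mc = int(rng.integers(cfg.mcs_per_cluster[0], cfg.mcs_per_cluster[1] + 1))
        members: list[MCRecord] = []
        for _ in range(n_mc):
            offset = _uniform_in_sphere(rng) * cfg.cluster_radius_mm
            center = ccenter + offset
            diameter = float(rng.uniform(*cfg.mc_diameter_mm))
            sigma = _fwhm_to_sigma(diameter)
            _insert_blob(noise_free, cfg, center, sigma, cfg.mc_contrast)
            members.append(MCRecord(center, diameter, cfg.mc_contrast, ci))
        truth.mcs.extend(members)
        box_lo = np.min([m.center_mm - m.diameter_mm for m in members], axis=0)
        box_hi = np.max([m.center_mm + m.diameter_mm for m in members], axis=0)
        truth.cluster_boxes.append(
            Annotation(f"cluster_{ci}", np.stack([box_lo, box_hi], axis=1), "phantom")
        )

    # --- distractors ---------------------------------------------------
    for li in range(cfg.n_line_distractors):
        if cfg.line_orientations_deg is not None:
            theta = np.deg2rad(cfg.line_orientations_deg[li % len(cfg.line_orientations_deg)])
        else:
            theta = rng.uniform(0, np.pi)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        # z snapped to a slice center: a fiber cross-section thinner than the
        # slice interval would otherwise vanish between slices
        z_slice = round(rng.uniform(0.2, 0.8) * ext[2] / sp[2]) * sp[2]
        point = np.array(
            [
                rng.uniform(0.25, 0.75) * ext[0],
                rng.uniform(0.25, 0.75) * ext[1],
                float(z_slice),
            ]
        )
        line_sigma = _fwhm_to_sigma(0.5)
        # fibers transit the whole field of view: a segment ending inside
        # the volume would present a point-like tip, a different object class
        half_length = 0.75 * float(max(ext[0], ext[1]))
        _insert_line(
            noise_free,
            cfg,
            point,
            direction,
            sigma_mm=line_sigma,
            # same depth-blur peak compensation as the MC blobs, so
            # "comparable contrast" means comparable post-blur conspicuity
            amplitude=cfg.distractor_contrast / _z_blur_peak_factor(line_sigma, cfg),
            half_length_mm=half_length,
        )
        truth.lines.append(
            LineRecord(point, direction, line_sigma, half_length, cfg.distractor_contrast)
        )
    for _ in range(cfg.n_plane_distractors):
        z_mm = rng.uniform(0.2, 0.8) * ext[2]
        center_xy = np.array(
            [rng.uniform(0.3, 0.7) * ext[0], rng.uniform(0.3, 0.7) * ext[1]]
        )
        _insert_plane(
            noise_free,
            cfg,
            z_mm=z_mm,
            sigma_mm=0.8,
            amplitude=0.5 * cfg.distractor_contrast / _z_blur_peak_factor(0.8, cfg),
            center_xy_mm=center_xy,
            radius_mm=6.0,
        )
        truth.planes.append(
            PlaneRecord(z_mm, 0.8, center_xy, 6.0, 0.5 * cfg.distractor_contrast)
        )

    # --- background, depth blur, normalization ------------------------
    # Signal and noise are depth-blurred separately, then the noise is
    # rescaled to unit standard deviation.  Blob amplitudes were already
    # pre-compensated for the blur, so the final signal peak sits at the
    # nominal contrast in units of the final noise sigma.
    noise, trend = _background(cfg, rng)
    if cfg.z_blur_sigma_mm > 0:
        sig_vox = cfg.z_blur_sigma_mm / sp[2]
        signal = ndimage.gaussian_filter1d(noise_free, sig_vox, axis=2, mode="reflect")
        noise = ndimage.gaussian_filter1d(noise, sig_vox, axis=2, mode="reflect")
    else:
        signal = noise_free
    if cfg.background != "flat":
        noise = noise / float(noise.std())
    full = 10.0 + signal + trend + noise  # positive DC: positive local means
    return Volume(full.astype(np.float32), tuple(cfg.spacing), (0.0, 0.0, 0.0)), truth


def _uniform_in_sphere(rng: np.random.Generator) -> np.ndarray:
    while True:
        p = rng.uniform(-1, 1, size=3)
        if p @ p <= 1.0:
            return p


def _place_cluster_centers(
    cfg: PhantomConfig, rng: np.random.Generator, max_tries: int = 200
) -> list[np.ndarray]:
    """Cluster centers inside the margin, pairwise at least 2 radii + 2 mm
    apart so truth boxes stay distinct."""
    ext = np.asarray(cfg.extent_mm)
    lo = np.array([cfg.margin_mm, cfg.margin_mm, min(cfg.margin_mm, ext[2] * 0.25)])
    hi = ext - lo
    min_sep = 2 * cfg.cluster_radius_mm + 2.0
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < cfg.n_clusters:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {cfg.n_clusters} clusters after {max_tries} tries"
            )
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - other) >= min_sep for other in centers):
            centers.append(c)
    return centers


def phantom_batch(
    cfg: PhantomConfig,
    n_volumes: int,
    truth_fraction: float,
    master_seed: int,
) -> list[tuple[Volume, PhantomTruth]]:
    """A deterministic batch of phantoms, a ``truth_fraction`` share positive
    (containing clusters) and the rest distractors/noise only.

    Per-volume seeds are spawned from ``master_seed`` so batches are
    reproducible and distinct master seeds give distinct volumes.
    """
    if not (0.0 <= truth_fraction <= 1.0):
        raise ValidationError("truth_fraction must be in [0, 1]")
    n_pos = int(round(truth_fraction * n_volumes))
    children = np.random.SeedSequence(master_seed).spawn(n_volumes)
    out: list[tuple[Volume, PhantomTruth]] = []
    for i in range(n_volumes):
        seed = int(children[i].generate_state(1)[0] % (2**31))
        vcfg = replace(cfg, rng_seed=seed, n_clusters=cfg.n_clusters if i < n_pos else 0)
        out.append(generate_phantom(vcfg))
    return out
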