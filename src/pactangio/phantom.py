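"""Synthetic inputs: breast-mimicking inclusion phantoms and vascular scenes.

Two families of ground-truth objects are generated here.

* An agarose-style breast phantom with disk-shaped absorbing inclusions of
  known diameter and absorption coefficient, used to exercise the ring-array
  forward model and the universal back-projection reconstructor.
* Synthetic maximum-amplitude-projection (MAP) angiograms containing a
  healthy compartment (long, smooth, directionally coherent vessels) and a
  tumor compartment (short, tortuous, densely packed microvessels), with a
  ``response_fraction`` knob that removes tumor microvessels to emulate
  vascular regression under neoadjuvant chemotherapy.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import MapImage

__all__ = [
    "OpticalProperties",
    "InclusionSpec",
    "BreastPhantom",
    "VascularSceneSpec",
    "GroundTruth",
    "effective_attenuation",
    "make_inclusion_phantom",
    "fluence_map",
    "make_vascular_scene",
    "make_longitudinal_series",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties: absorption and reduced scattering, in cm^-1."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if self.mu_a <= 0:
            raise ValueError("mu_a must be positive")
        if self.mu_s_prime < 0:
            raise ValueError("mu_s_prime must be non-negative")


#: optical properties of the tumor-mimicking ink inclusions at 1064 nm
TUMOR_PROPS = OpticalProperties(mu_a=0.105, mu_s_prime=5.0)
#: optical properties of the breast-mimicking background at 1064 nm
BACKGROUND_PROPS = OpticalProperties(mu_a=0.05, mu_s_prime=5.0)
#: inclusion diameters of the reference phantom (mm); the smallest is
#: additionally duplicated at the phantom center.
PHANTOM_DIAMETERS_MM = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5)


@dataclass(frozen=True)
class InclusionSpec:
    """One embedded absorber: center (y, x) in mm, diameter in mm, properties."""

    center_mm: tuple[float, float]
    diameter_mm: float
    props: OpticalProperties

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class BreastPhantom:
    """A gridded 2D slice of the breast-mimicking phantom.

    The grid is centered on the physical origin: pixel (i, j) sits at
    ``y = (i - (ny-1)/2) * h``, ``x = (j - (nx-1)/2) * h`` (mm).  The
    absorption map equals the background ``mu_a`` outside the inclusion mask
    and each inclusion's ``mu_a`` inside it.  ``depth_axis`` selects the
    in-image axis pointing away from the illuminated surface, or ``None``
    when the slice lies at a constant out-of-plane depth ``plane_depth_mm``.
    ``support_radius_mm`` is the radius of the physical phantom disk, which
    may extend beyond the rendered grid.
    """

    grid_spacing_mm: float
    absorption_map: np.ndarray
    background_props: OpticalProperties
    inclusions: list[InclusionSpec]
    inclusion_mask: np.ndarray
    depth_axis: int | None = None
    plane_depth_mm: float = 20.0
    support_radius_mm: float = 50.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorption_map.shape

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinate grids of pixel centers, in mm."""
        ny, nx = self.shape
        h = self.grid_spacing_mm
        y = (np.arange(ny) - (ny - 1) / 2.0) * h
        x = (np.arange(nx) - (nx - 1) / 2.0) * h
        return np.meshgrid(y, x, indexing="ij")


def effective_attenuation(props: OpticalProperties) -> float:
    """Effective attenuation coefficient in the diffusion approximation.

    mu_eff = sqrt(3 * mu_a * (mu_a + mu_s')), in cm^-1.  For average breast
    optical properties at 1064 nm this evaluates to about 0.9 cm^-1.
    """
    return math.sqrt(3.0 * props.mu_a * (props.mu_a + props.mu_s_prime))


def _disk_mask(shape: tuple[int, int], center_mm: tuple[float, float],
               radius_mm: float, h: float) -> np.ndarray:
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * h
    x = (np.arange(nx) - (nx - 1) / 2.0) * h
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return (yy - center_mm[0]) ** 2 + (xx - center_mm[1]) ** 2 <= radius_mm**2


def make_inclusion_phantom(
    diameters_mm=PHANTOM_DIAMETERS_MM,
    depth_mm: float = 20.0,
    tumor_props: OpticalProperties = TUMOR_PROPS,
    background_props: OpticalProperties = BACKGROUND_PROPS,
    grid_spacing_mm: float = 0.1,
    ring_radius_mm: float = 15.0,
    margin_mm: float = 5.0,
    support_radius_mm: float = 50.0,
) -> BreastPhantom:
    """Build the reference inclusion phantom.

    The listed diameters are placed evenly on a ring of radius
    ``ring_radius_mm``; the smallest diameter is duplicated at the center,
    so ``n+1`` inclusions are rendered for ``n`` listed diameters.  All
    inclusions lie in the plane at out-of-plane depth ``depth_mm`` below the
    illuminated surface.

    Raises
    ------
    ValueError
        If the placement produces overlapping inclusions.
    """
    diameters_mm = [float(d) for d in diameters_mm]
    if any(d <= 0 for d in diameters_mm):
        raise ValueError("all diameters must be positive")
    for d in diameters_mm:
        if d < 2.0 * grid_spacing_mm:
            warnings.warn(
                f"inclusion diameter {d} mm is below 2 pixels; rendering will be coarse",
                stacklevel=2,
            )

    specs: list[InclusionSpec] = [
        InclusionSpec((0.0, 0.0), min(diameters_mm), tumor_props)
    ]
    n = len(diameters_mm)
    for k, d in enumerate(diameters_mm):
        ang = 2.0 * math.pi * k / n
        c = (ring_radius_mm * math.sin(ang), ring_radius_mm * math.cos(ang))
        specs.append(InclusionSpec(c, d, tumor_props))

    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            ci, cj = specs[i].center_mm, specs[j].center_mm
            dist = math.hypot(ci[0] - cj[0], ci[1] - cj[1])
            if dist < specs[i].radius_mm + specs[j].radius_mm:
                raise ValueError(
                    f"inclusions {i} and {j} overlap (centers {dist:.2f} mm apart)"
                )

    half = ring_radius_mm + max(diameters_mm) / 2.0 + margin_mm
    npix = int(round(2.0 * half / grid_spacing_mm)) | 1  # odd → a pixel at the origin
    shape = (npix, npix)
    absorption = np.full(shape, background_props.mu_a, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    for spec in specs:
        m = _disk_mask(shape, spec.center_mm, spec.radius_mm, grid_spacing_mm)
        absorption[m] = spec.props.mu_a
        mask |= m

    return BreastPhantom(
        grid_spacing_mm=grid_spacing_mm,
        absorption_map=absorption,
        background_props=background_props,
        inclusions=specs,
        inclusion_mask=mask,
        depth_axis=None,
        plane_depth_mm=depth_mm,
        support_radius_mm=support_radius_mm,
    )


def fluence_map(phantom: BreastPhantom, surface_fluence: float = 1.0) -> np.ndarray:
    """Optical fluence on the phantom grid under 1D exponential decay.

    Phi(z) = Phi0 * exp(-mu_eff * z), with z in cm measured from the
    illuminated surface and mu_eff taken from the background optical
    properties.  When ``depth_axis`` is ``None`` the whole in-plane slice
    sits at ``plane_depth_mm`` and the map is constant.
    """
    if surface_fluence < 0:
        raise ValueError("surface_fluence must be non-negative")
    mu_eff = effective_attenuation(phantom.background_props)
    shape = phantom.shape
    if phantom.depth_axis is None:
        z_cm = phantom.plane_depth_mm / 10.0
        return np.full(shape, surface_fluence * math.exp(-mu_eff * z_cm))
    ax = phantom.depth_axis
    depth_cm = np.arange(shape[ax]) * phantom.grid_spacing_mm / 10.0
    phi = surface_fluence * np.exp(-mu_eff * depth_cm)
    if ax == 0:
        return np.repeat(phi[:, None], shape[1], axis=1)
    return np.repeat(phi[None, :], shape[0], axis=0)


# ---------------------------------------------------------------------------
# Vascular MAP scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VascularSceneSpec:
    """Parameters of a synthetic two-compartment MAP angiogram.

    The healthy compartment contains ``healthy_vessel_count`` long vessels
    whose headings are drawn near ``preferred_orientation_deg`` (withing
    ``orientation_jitter_deg``) and wander with curvature scale
    ``healthy_tortuosity`` (rad per sqrt(mm)).  The tumor compartment packs
    ``tumor_microvessel_count`` short, highly tortuous microvessels into a
    disk of ``tumor_radius_mm``; ``response_fraction`` removes that fraction
    of them (0 = pre-treatment baseline, 1 = complete vascular response).
    Vessels are rendered with a Gaussian cross-section of sigma = radius/2
    and unit peak amplitude, so compartments differ geometrically rather
    than in brightness.

    Two features emulate what a ring-array breast scanner actually records:
    the scene is blurred with the system's in-plane point-spread function
    (``psf_sigma_mm``), and the tumor disk carries a faint smooth "blush"
    texture (``tumor_blush_amplitude``) standing for sub-resolution
    angiogenic capillaries, which regresses together with the microvessels.
    """

    domain_size_mm: tuple[float, float] = (40.0, 40.0)
    pixel_size_mm: float = 0.1
    healthy_vessel_count: int = 38
    healthy_tortuosity: float = 0.12
    preferred_orientation_deg: float = 30.0
    orientation_jitter_deg: float = 10.0
    tumor_center_mm: tuple[float, float] = (14.5, 13.5)
    tumor_radius_mm: float = 4.0
    tumor_microvessel_count: int = 85
    tumor_tortuosity: float = 1.6
    tumor_vessel_length_mm: tuple[float, float] = (1.2, 2.5)
    vessel_radius_range_mm: tuple[float, float] = (0.1, 0.2)
    response_fraction: float = 0.0
    noise_sigma: float = 0.03
    psf_sigma_mm: float = 0.11
    tumor_blush_amplitude: float = 0.15
    blush_correlation_mm: float = 0.3
    edge_margin_mm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.response_fraction <= 1.0:
            raise ValueError("response_fraction must lie in [0, 1]")
        if self.tumor_microvessel_count > 0 and self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be positive when microvessels are requested")
        cy, cx = self.tumor_center_mm
        hy, hx = self.domain_size_mm
        if not (0 <= cy <= hy and 0 <= cx <= hx):
            raise ValueError("tumor center must lie inside the domain")

    @property
    def support_radius_mm(self) -> float:
        """Radius of the circular 'breast' support inside the domain."""
        return min(self.domain_size_mm) / 2.0 - self.edge_margin_mm


@dataclass
class GroundTruth:
    """Known structure of a generated scene, for validation and scoring."""

    tumor_mask: np.ndarray
    healthy_mask: np.ndarray
    support_mask: np.ndarray
    n_tumor_vessels: int
    n_healthy_vessels: int
    tumor_center_mm: tuple[float, float]
    tumor_radius_mm: float


def _walk(start: np.ndarray, heading: float, tortuosity: float, ds: float,
          max_len: float, inside, rng: np.random.Generator) -> list[np.ndarray]:
    """Random curvature walk from ``start`` until leaving ``inside`` or ``max_len``."""
    pts = [start.copy()]
    p = start.copy()
    h = heading
    n_steps = int(max_len / ds)
    sq = math.sqrt(ds)
    for _ in range(n_steps):
        h += tortuosity * rng.normal() * sq
        p = p + ds * np.array([math.sin(h), math.cos(h)])
        if not inside(p):
            break
        pts.append(p.copy())
    return pts


def _render_polyline(shape: tuple[int, int], pts: np.ndarray, sigma_px: float,
                     h: float) -> np.ndarray:
    """Intensity image of one vessel: Gaussian profile of the distance to the
    polyline, unit amplitude on the centerline."""
    centerline = np.zeros(shape, dtype=bool)
    idx = np.round(pts / h).astype(int)
    idx[:, 0] = np.clip(idx[:, 0], 0, shape[0] - 1)
    idx[:, 1] = np.clip(idx[:, 1], 0, shape[1] - 1)
    centerline[idx[:, 0], idx[:, 1]] = True
    d = ndimage.distance_transform_edt(~centerline)
    return np.exp(-(d**2) / (2.0 * sigma_px**2))


def make_vascular_scene(spec: VascularSceneSpec) -> tuple[MapImage, GroundTruth]:
    """Generate a synthetic MAP angiogram and its ground truth.

    Randomness is split into independent healthy / tumor / noise streams, so
    scenes that differ only in ``response_fraction`` share identical vessel
    geometry and the removed microvessels form nested subsets.
    """
    h = spec.pixel_size_mm
    ny = int(round(spec.domain_size_mm[0] / h))
    nx = int(round(spec.domain_size_mm[1] / h))
    shape = (ny, nx)
    rng_h, rng_t, rng_n, rng_b = (np.random.default_rng(s)
                                  for s in np.random.SeedSequence(spec.seed).spawn(4))

    center = np.array([spec.domain_size_mm[0] / 2.0, spec.domain_size_mm[1] / 2.0])
    r_support = spec.support_radius_mm
    # vessels stop short of the support edge so their rendered cross-section
    # tails decay inside it and the outside region stays pure noise
    r_vessel = r_support - 1.0

    def in_support(p: np.ndarray) -> bool:
        return float(np.hypot(*(p - center))) <= r_vessel

    ds = 0.2  # walk step, mm
    image = np.zeros(shape, dtype=float)

    # healthy compartment: long smooth vessels crossing the support.
    # Chords are drawn with the uniform (offset, angle) line measure, which
    # yields near-uniform expected line density over the disk; each vessel
    # is walked from its chord's entry point until it leaves the support.
    for _ in range(spec.healthy_vessel_count):
        heading = math.radians(
            spec.preferred_orientation_deg
            + spec.orientation_jitter_deg * rng_h.normal()
        )
        direction = np.array([math.sin(heading), math.cos(heading)])
        normal = np.array([direction[1], -direction[0]])
        offset = rng_h.uniform(-r_vessel, r_vessel)
        half_chord = math.sqrt(max(r_vessel**2 - offset**2, 0.0))
        start = center + offset * normal - (half_chord - ds) * direction
        pts = np.array(_walk(start, heading, spec.healthy_tortuosity, ds,
                             3.0 * r_support, in_support, rng_h))
        radius = rng_h.uniform(*spec.vessel_radius_range_mm)
        image = np.maximum(image, _render_polyline(shape, pts, radius / 2.0 / h, h))

    # tumor compartment: short tortuous microvessels confined to the tumor disk
    t_center = np.array(spec.tumor_center_mm, dtype=float)
    r_t = spec.tumor_radius_mm

    def in_tumor(p: np.ndarray) -> bool:
        return float(np.hypot(*(p - t_center))) <= 0.95 * r_t

    tumor_vessels = []
    for _ in range(spec.tumor_microvessel_count):
        ang = rng_t.uniform(0.0, 2.0 * math.pi)
        rad = 0.8 * r_t * math.sqrt(rng_t.uniform())
        start = t_center + rad * np.array([math.sin(ang), math.cos(ang)])
        heading = rng_t.uniform(0.0, 2.0 * math.pi)
        length = rng_t.uniform(*spec.tumor_vessel_length_mm)
        pts = np.array(_walk(start, heading, spec.tumor_tortuosity, ds,
                             length, in_tumor, rng_t))
        radius = rng_t.uniform(*spec.vessel_radius_range_mm)
        tumor_vessels.append((pts, radius))

    n_keep = int(round((1.0 - spec.response_fraction) * len(tumor_vessels)))
    for pts, radius in tumor_vessels[:n_keep]:
        image = np.maximum(image, _render_polyline(shape, pts, radius / 2.0 / h, h))

    yy, xx = np.meshgrid((np.arange(ny) + 0.5) * h, (np.arange(nx) + 0.5) * h,
                         indexing="ij")

    # angiogenic blush: smooth sub-resolution capillary texture inside the
    # tumor disk, tapered at the rim, regressing with the response fraction
    blush_amp = spec.tumor_blush_amplitude * (1.0 - spec.response_fraction)
    if blush_amp > 0 and spec.tumor_radius_mm > 0:
        tex = ndimage.gaussian_filter(rng_b.normal(size=shape),
                                      spec.blush_correlation_mm / h)
        tex = np.abs(tex) / tex.std() * blush_amp
        r_from_tumor = np.hypot(yy - t_center[0], xx - t_center[1])
        taper = np.clip((spec.tumor_radius_mm - r_from_tumor) / 0.5, 0.0, 1.0)
        image = np.maximum(image, tex * taper)
    elif spec.tumor_blush_amplitude > 0:
        rng_b.normal(size=shape)  # keep the stream aligned across specs

    # in-plane system resolution
    if spec.psf_sigma_mm > 0:
        image = ndimage.gaussian_filter(image, spec.psf_sigma_mm / h)
    peak = image.max()
    if peak > 0:
        image = image / peak

    if spec.noise_sigma > 0:
        image = image + spec.noise_sigma * rng_n.normal(size=shape)
    support = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r_support**2
    tumor = (yy - t_center[0]) ** 2 + (xx - t_center[1]) ** 2 <= r_t**2
    # healthy reference: inside the support minus a 2 mm edge band (vessel
    # walks stop short of the support edge) and a 1 mm guard ring around
    # the tumor
    margin_px = max(int(round(1.0 / h)), 1)
    tumor_dilated = ndimage.binary_dilation(tumor, iterations=margin_px)
    support_inner = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= (r_support - 2.0) ** 2
    healthy = support_inner & ~tumor_dilated

    gt = GroundTruth(
        tumor_mask=tumor,
        healthy_mask=healthy,
        support_mask=support,
        n_tumor_vessels=n_keep,
        n_healthy_vessels=spec.healthy_vessel_count,
        tumor_center_mm=spec.tumor_center_mm,
        tumor_radius_mm=r_t,
    )
    map_image = MapImage(image, h, [f"make_vascular_scene(seed={spec.seed}, "
                                    f"response={spec.response_fraction})"])
    return map_image, gt


def make_longitudinal_series(
    spec: VascularSceneSpec, response_fractions=(0.0, 0.5, 1.0)
) -> list[tuple[MapImage, GroundTruth]]:
    """Scenes of one 'patient' over treatment: same geometry, increasing response."""
    return [
        make_vascular_scene(dataclasses.replace(spec, response_fraction=f))
        for f in response_fractions
    ]
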