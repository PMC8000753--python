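"""Synthetic micro-CT volumes and embedding-force curves.

The generator emulates the statistical structure the analysis chain assumes,
so every downstream stage is testable without scanner data:

* trabecular microstructure as a Gaussian random field smoothed to a
  controllable correlation length and quantile-thresholded to a target
  marrow/soft-tissue fraction phi* (standard trabecular-phantom practice);
* canal-like tubular pores, lacuna-like spherical pores, and isolated
  single-voxel speckle "noise" carved into the bone phase;
* periapical densification zones under the spike apexes of a scaffold layout;
* replicate force-distance curves with the three-region embedding shape
  (concave onset, linear elastic-transfer mid-region, post-yield sawtooth).

All randomness is driven by the integer ``seed`` of the spec dataclass
(:class:`VolumeSpec` or :class:`CurveSpec`); no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .curves import ForceCurve
from .densitometry import CTVolume
from .geometry import ScaffoldLayout


@dataclass(frozen=True)
class VolumeSpec:
    """Parameters of the trabecular phantom.

    Lengths are in micrometres.  The default voxel size matches the study
    resolution (17.5 um); the default correlation length of 200 um yields a
    mean trabecular spacing of roughly 0.35 mm, the trabecular-scale quoted
    for periarticular cancellous bone.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 17.5
    target_marrow_fraction: float = 0.582
    correlation_length: float = 200.0
    n_canals: int = 3
    canal_radius: float = 40.0
    n_lacunae: int = 20
    lacuna_radius: float = 25.0
    n_speckles: int = 50
    intensity_bone: float = 180.0
    intensity_soft: float = 60.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_marrow_fraction < 1.0:
            raise ValueError("target_marrow_fraction must lie in (0, 1)")
        if min(self.shape) < 16:
            raise ValueError("every volume axis must be at least 16 voxels")
        if self.intensity_bone <= self.intensity_soft:
            raise ValueError("intensity_bone must exceed intensity_soft")
        if min(self.n_canals, self.n_lacunae, self.n_speckles) < 0:
            raise ValueError("object counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CurveSpec:
    """Parameters of the three-region embedding-curve generator.

    The default region-II line (slope 376.49 N/mm, intercept 209.46 N) and
    replicate count (10) are the study conditions; the region spans cover the
    3.0 mm maximum embedding depth.  Region III's sawtooth (sudden force
    drops from trabecular destruction) is a phenomenological model with
    exposed amplitude/period/slope-factor dials.
    """

    slope_a_true: float = 376.49
    intercept_b_true: float = 209.46
    region1_span: float = 0.5
    region2_span: float = 2.0
    region3_span: float = 0.5
    noise_sd: float = 15.0
    n_replicates: int = 10
    sampling_step: float = 0.01
    region3_slope_factor: float = 0.4
    sawtooth_amplitude: float = 30.0
    sawtooth_period: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.region1_span, self.region2_span, self.region3_span) <= 0:
            raise ValueError("region spans must be positive")
        if self.slope_a_true <= 0:
            raise ValueError("slope_a_true must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sampling_step <= 0:
            raise ValueError("sampling_step must be positive")


def _carve_canals(soft: np.ndarray, spec: VolumeSpec, rng: np.random.Generator) -> None:
    """Carve tubular pores along random chords of the volume."""
    shape = np.array(soft.shape, dtype=float)
    radius_vox = spec.canal_radius / spec.voxel_size
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in soft.shape),
                             indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    for _ in range(spec.n_canals):
        p0 = rng.uniform(0.2, 0.8, size=3) * shape
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        d = pts - p0
        t = d @ u
        d_perp2 = np.einsum("zyxc,zyxc->zyx", d, d) - t * t
        soft[d_perp2 <= radius_vox ** 2] = True


def _carve_lacunae(soft: np.ndarray, spec: VolumeSpec, rng: np.random.Generator) -> None:
    """Carve small spherical pores centred on bone voxels."""
    radius_vox = spec.lacuna_radius / spec.voxel_size
    r = int(np.ceil(radius_vox))
    off = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    ball = (off[0] ** 2 + off[1] ** 2 + off[2] ** 2) <= radius_vox ** 2
    bone_idx = np.argwhere(~soft)
    inner = np.all((bone_idx >= r + 1) & (bone_idx < np.array(soft.shape) - r - 1),
                   axis=1)
    bone_idx = bone_idx[inner]
    if len(bone_idx) < spec.n_lacunae:
        raise ValueError("not enough interior bone to place lacunae")
    for c in bone_idx[rng.choice(len(bone_idx), spec.n_lacunae, replace=False)]:
        sl = tuple(slice(ci - r, ci + r + 1) for ci in c)
        soft[sl] |= ball


def _plant_speckles(soft: np.ndarray, spec: VolumeSpec, rng: np.random.Generator) -> None:
    """Flip isolated single voxels to the soft phase, each fully surrounded by
    bone and pairwise non-adjacent (Chebyshev distance >= 2)."""
    if spec.n_speckles == 0:
        return
    interior_bone = ndimage.binary_erosion(~soft, structure=np.ones((3, 3, 3)))
    candidates = np.argwhere(interior_bone)
    rng.shuffle(candidates)
    placed: list[np.ndarray] = []
    for c in candidates:
        if all(np.max(np.abs(c - p)) >= 2 for p in placed):
            placed.append(c)
            if len(placed) == spec.n_speckles:
                break
    if len(placed) < spec.n_speckles:
        raise ValueError("could not place all speckles inside bone")
    for c in placed:
        soft[tuple(c)] = True


def generate_trabecular_volume(spec: VolumeSpec) -> tuple[CTVolume, np.ndarray]:
    """Generate a trabecular phantom; returns the greyscale volume and the
    ground-truth bone mask.

    The soft phase of the thresholded random field matches the target marrow
    fraction to within one voxel quantile; canals, lacunae and speckles are
    then carved into the bone phase (slightly raising the final soft
    fraction, by well under a percent at the default object counts).
    """
    rng = np.random.default_rng(spec.seed)
    sigma_vox = spec.correlation_length / spec.voxel_size / 2.0
    field_ = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma_vox)
    thr = np.quantile(field_, spec.target_marrow_fraction)
    soft = field_ < thr

    if spec.n_canals:
        _carve_canals(soft, spec, rng)
    if spec.n_lacunae:
        _carve_lacunae(soft, spec, rng)
    if spec.n_speckles:
        _plant_speckles(soft, spec, rng)

    bone = ~soft
    grey = np.where(bone, spec.intensity_bone, spec.intensity_soft).astype(float)
    if spec.noise_sd > 0:
        grey += spec.noise_sd * rng.standard_normal(spec.shape)
    return CTVolume(voxels=grey, voxel_size=spec.voxel_size), bone


def apply_densification(volume: CTVolume, bone_mask: np.ndarray,
                        layout: ScaffoldLayout, embed_depth: float,
                        zone_thickness: float, delta_phi: float,
                        zone_radius: float | None = None) -> tuple[CTVolume, np.ndarray]:
    """Densify cylindrical periapical zones under each spike apex.

    Within each zone (radius ``zone_radius``, default the spike base radius,
    extending ``zone_thickness`` mm below the apex plane at ``embed_depth``)
    the marrow fraction is reduced by ``delta_phi`` by flipping the soft
    voxels nearest to existing bone.  Voxels outside the zones are untouched.
    Lengths in mm.
    """
    if delta_phi < 0:
        raise ValueError("delta_phi must be non-negative")
    vs = volume.voxel_size_mm
    nz, ny, nx = bone_mask.shape
    z0 = int(round(embed_depth / vs))
    z1 = int(round((embed_depth + zone_thickness) / vs))
    if z0 < 0 or z1 > nz:
        raise ValueError("densification zone extends outside the volume")

    grey = volume.voxels.astype(float).copy()
    bone = bone_mask.copy()
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    # distance of each soft voxel to the nearest trabecula, for flip ordering
    dist = ndimage.distance_transform_edt(~bone)
    for i, s in enumerate(layout.spikes):
        r = (zone_radius if zone_radius is not None else s.base_radius) / vs
        cy = (ny - 1) / 2.0 + s.center_y / vs
        cx = (nx - 1) / 2.0 + s.center_x / vs
        if cy - r < -0.5 or cy + r > ny - 0.5 or cx - r < -0.5 or cx + r > nx - 0.5:
            raise ValueError(f"densification zone for spike {i} outside the volume")
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        zone = np.zeros_like(bone)
        zone[z0:z1] = disc
        n_zone = int(zone.sum())
        if n_zone == 0:
            continue
        soft_zone = zone & ~bone
        n_flip = int(round(delta_phi * n_zone))
        if n_flip == 0:
            continue
        if n_flip > soft_zone.sum():
            raise ValueError(f"delta_phi exceeds current marrow fraction in zone {i}")
        # flip the soft voxels closest to existing bone first (trabecular
        # thickening)
        zi = np.argwhere(soft_zone)
        order = np.argsort(dist[tuple(zi.T)], kind="stable")
        flip = zi[order[:n_flip]]
        bone_val = grey[zone & bone].mean() if (zone & bone).any() else grey[bone].mean()
        bone[tuple(flip.T)] = True
        grey[tuple(flip.T)] = bone_val
    return CTVolume(voxels=grey, voxel_size=volume.voxel_size), bone


def generate_force_curves(spec: CurveSpec) -> list[ForceCurve]:
    """Generate replicate three-region embedding curves.

    Region I is a concave quadratic joining the origin C1-continuously to the
    region-II line ``a*x + b``; region III superposes sawtooth force drops on
    a reduced mean slope.  Gaussian noise of SD ``noise_sd`` is added to every
    sample independently per replicate.
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.slope_a_true, spec.intercept_b_true
    x1 = spec.region1_span
    x2 = x1 + spec.region2_span
    total = x2 + spec.region3_span
    grid = np.arange(0.0, total + spec.sampling_step / 2, spec.sampling_step)

    base = np.empty_like(grid)
    r1 = grid <= x1
    r2 = (grid > x1) & (grid <= x2)
    r3 = grid > x2
    # concave C1 join: f(x) = a x + b - b (1 - x/x1)^2; f(0)=0, f(x1)=a x1+b
    base[r1] = a * grid[r1] + b - b * (1.0 - grid[r1] / x1) ** 2
    base[r2] = a * grid[r2] + b
    f2 = a * x2 + b
    t = grid[r3] - x2
    base[r3] = (f2 + spec.region3_slope_factor * a * t
                + spec.sawtooth_amplitude * np.mod(t / spec.sawtooth_period, 1.0))

    curves = []
    for rep in range(spec.n_replicates):
        noise = spec.noise_sd * rng.standard_normal(grid.shape) if spec.noise_sd > 0 \
            else np.zeros_like(grid)
        curves.append(ForceCurve(displacement=grid.copy(), force=base + noise,
                                 replicate_id=rep))
    return curves
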