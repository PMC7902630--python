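"""Synthetic micro-CT-like inner-ear phantoms.

The generator emits image/label volume pairs that reproduce the geometric and
intensity structure of labyrinth segmentation in temporal-bone micro-CT:

* a single bright, connected target — a tapering helical cochlear tube, three
  near-orthogonal semicircular-canal arcs and a vestibule ellipsoid joining
  them;
* textured "bone" surroundings;
* disconnected "air cell" confounder blobs rendered at the same intensity as
  the target, so pure intensity thresholding commits false positives that
  only 3D reasoning (largest connected component, auto-context) can remove;
* partial-volume blur and additive Gaussian noise.

Every sample is fully determined by its (spec, seed) pair.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import PhantomSpecError
from .volume_io import LabelVolume, Volume, write_volume

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CochleaSpec:
    turns: float = 2.5
    base_radius_vox: float = 10.0
    tube_radius_vox: float = 2.2
    taper: float = 0.35          # apex spiral radius as a fraction of the base radius


@dataclass
class CanalSpec:
    normal: tuple[float, float, float]
    arc_radius_vox: float = 9.0
    tube_radius_vox: float = 1.6
    span_deg: float = 230.0


@dataclass
class VestibuleSpec:
    semi_axes_vox: tuple[float, float, float] = (4.0, 3.2, 3.2)


@dataclass
class ConfounderSpec:
    count: int = 6
    radius_range_vox: tuple[float, float] = (1.2, 2.8)
    min_distance_vox: float = 5.0


@dataclass
class IntensitySpec:
    target_level: float = 1.0
    bone_level: float = 0.35
    background_level: float = 0.0
    texture_amp: float = 0.05    # band-passed bone texture amplitude
    blur_sigma_vox: float = 0.7  # partial-volume emulation
    noise_sigma: float = 0.05


def _default_canals() -> list[CanalSpec]:
    # near-orthogonal planes, slightly tilted as in real labyrinth anatomy
    return [
        CanalSpec(normal=(1.0, 0.15, -0.1)),
        CanalSpec(normal=(-0.1, 1.0, 0.15)),
        CanalSpec(normal=(0.15, -0.1, 1.0)),
    ]


@dataclass
class PhantomSpec:
    grid_size: int = 64
    spacing_mm: tuple[float, float, float] = (0.125, 0.125, 0.125)
    cochlea: CochleaSpec = field(default_factory=CochleaSpec)
    canals: list[CanalSpec] = field(default_factory=_default_canals)
    vestibule: VestibuleSpec = field(default_factory=VestibuleSpec)
    confounders: ConfounderSpec = field(default_factory=ConfounderSpec)
    intensity: IntensitySpec = field(default_factory=IntensitySpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise PhantomSpecError(f"grid_size must be >= 16, got {self.grid_size}")
        if not 0 < self.cochlea.taper < 1:
            raise PhantomSpecError(f"cochlea taper must be in (0,1), got {self.cochlea.taper}")
        if self.cochlea.turns <= 0:
            raise PhantomSpecError("cochlea turns must be > 0")
        radii = [self.cochlea.tube_radius_vox, *(c.tube_radius_vox for c in self.canals),
                 *self.vestibule.semi_axes_vox]
        if any(r <= 0 for r in radii):
            raise PhantomSpecError("all radii and semi-axes must be > 0")
        blur_support = 3.0 * self.intensity.blur_sigma_vox
        if self.confounders.count > 0 and self.confounders.min_distance_vox <= blur_support:
            raise PhantomSpecError(
                "confounder min distance must exceed the blur support "
                f"({self.confounders.min_distance_vox} <= {blur_support})"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        raw = yaml.safe_load(Path(path).read_text())
        raw["cochlea"] = CochleaSpec(**raw.get("cochlea", {}))
        raw["canals"] = [CanalSpec(**{**c, "normal": tuple(c["normal"])})
                         for c in raw.get("canals", [])] or _default_canals()
        raw["vestibule"] = VestibuleSpec(
            **{**raw.get("vestibule", {}),
               "semi_axes_vox": tuple(raw.get("vestibule", {}).get("semi_axes_vox", (4.0, 3.2, 3.2)))})
        raw["confounders"] = ConfounderSpec(
            **{**raw.get("confounders", {}),
               "radius_range_vox": tuple(raw.get("confounders", {}).get("radius_range_vox", (1.2, 2.8)))})
        raw["intensity"] = IntensitySpec(**raw.get("intensity", {}))
        raw["spacing_mm"] = tuple(raw.get("spacing_mm", (0.125, 0.125, 0.125)))
        return cls(**raw)


@dataclass
class PhantomSample:
    image: Volume
    label: LabelVolume
    spec: PhantomSpec
    seed: int


# ---------------------------------------------------------------------------
# geometry rendering
# ---------------------------------------------------------------------------

def _stamp_balls(mask: np.ndarray, points: np.ndarray, radii: np.ndarray,
                 component: str) -> None:
    """Set mask voxels within radius of each curve point; error if out of grid."""
    n = mask.shape[0]
    for (px, py, pz), r in zip(points, radii):
        if min(px, py, pz) - r < 1 or max(px, py, pz) + r > n - 2:
            raise PhantomSpecError(
                f"{component} leaves the grid (point ({px:.1f},{py:.1f},{pz:.1f}), "
                f"radius {r:.1f}, grid {n})"
            )
        lo = np.floor([px - r, py - r, pz - r]).astype(int)
        hi = np.ceil([px + r, py + r, pz + r]).astype(int) + 1
        xs, ys, zs = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        ball = (xs - px) ** 2 + (ys - py) ** 2 + (zs - pz) ** 2 <= r * r
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball


def _orthonormal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    w = np.cross(n, u)
    return u, w


def _render_label(spec: PhantomSpec) -> np.ndarray:
    n = spec.grid_size
    mask = np.zeros((n, n, n), dtype=bool)
    vcent = np.array([0.5, 0.5, 0.5]) * n  # vestibule centre = structural hub

    # cochlea: tapering helix whose outer (basal) end sits at the vestibule
    co = spec.cochlea
    t_max = 2 * np.pi * co.turns
    t = np.linspace(0.0, t_max, max(int(80 * co.turns), 60))
    frac = t / t_max
    spiral_r = co.base_radius_vox * (1 - (1 - co.taper) * frac)
    centre = vcent + np.array([-co.base_radius_vox, 0.0, 0.0])
    height = 0.25 * co.base_radius_vox  # mild helical rise towards the apex
    pts = centre + np.stack(
        [spiral_r * np.cos(t), spiral_r * np.sin(t), height * frac], axis=1
    )
    tube_r = co.tube_radius_vox * (1 - 0.4 * frac)  # lumen narrows apically
    _stamp_balls(mask, pts, tube_r, "cochlea")

    # semicircular canals: partial tori through the vestibule
    for i, canal in enumerate(spec.canals):
        u, w = _orthonormal_frame(np.asarray(canal.normal, dtype=float))
        arc_c = vcent + canal.arc_radius_vox * u
        half = np.deg2rad(canal.span_deg) / 2
        phi = np.linspace(-half, half, max(int(20 * canal.span_deg / 90), 40))
        arc_pts = arc_c[None, :] + canal.arc_radius_vox * (
            -np.cos(phi)[:, None] * u[None, :] + np.sin(phi)[:, None] * w[None, :]
        )
        _stamp_balls(mask, arc_pts, np.full(len(phi), canal.tube_radius_vox), f"canal {i}")

    # vestibule ellipsoid joining cochlea base and canal midpoints
    a, b, c = spec.vestibule.semi_axes_vox
    xs, ys, zs = np.ogrid[0:n, 0:n, 0:n]
    ell = (((xs - vcent[0]) / a) ** 2 + ((ys - vcent[1]) / b) ** 2
           + ((zs - vcent[2]) / c) ** 2) <= 1.0
    mask |= ell
    return mask


def _place_confounders(spec: PhantomSpec, label: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample target-intensity blobs well away from the label."""
    n = spec.grid_size
    conf = np.zeros_like(label)
    if spec.confounders.count == 0:
        return conf
    dist_to_label = ndimage.distance_transform_edt(~label)
    lo_r, hi_r = spec.confounders.radius_range_vox
    for k in range(spec.confounders.count):
        for attempt in range(1000):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(r + 2, n - r - 3, size=3)
            ci = tuple(np.round(c).astype(int))
            if dist_to_label[ci] < spec.confounders.min_distance_vox + r:
                continue
            _stamp_balls(conf, c[None, :], np.array([r]), f"confounder {k}")
            break
        else:
            raise PhantomSpecError(
                f"could not place confounder {k} after 1000 attempts"
            )
    return conf


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> PhantomSample:
    """Render one phantom; fully determined by (spec, seed)."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.grid_size
    label = _render_label(spec)

    n_components = ndimage.label(label, structure=CONNECTIVITY_26)[1]
    if n_components != 1:
        raise PhantomSpecError(
            f"labyrinth rendered as {n_components} 26-connected components; "
            "adjust the geometry so cochlea, canals and vestibule meet"
        )

    conf = _place_confounders(spec, label, rng)

    iv = spec.intensity
    img = np.full((n, n, n), iv.background_level, dtype=np.float64)
    # bone block fills most of the grid
    xs, ys, zs = np.ogrid[0:n, 0:n, 0:n]
    c0 = (n - 1) / 2
    bone = (((xs - c0) / (0.48 * n)) ** 2 + ((ys - c0) / (0.48 * n)) ** 2
            + ((zs - c0) / (0.48 * n)) ** 2) <= 1.0
    img[bone] = iv.bone_level
    if iv.texture_amp > 0:
        raw = rng.standard_normal((n, n, n))
        band = ndimage.gaussian_filter(raw, 1.0) - ndimage.gaussian_filter(raw, 3.0)
        band /= band.std()
        img[bone] += iv.texture_amp * band[bone]
    img[label] = iv.target_level
    img[conf] = iv.target_level
    if iv.blur_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, iv.blur_sigma_vox)
    if iv.noise_sigma > 0:
        img = img + rng.normal(0.0, iv.noise_sigma, size=img.shape)

    image = Volume(data=img, spacing=spec.spacing_mm)
    lab = LabelVolume(data=label.astype(np.uint8), spacing=spec.spacing_mm)
    return PhantomSample(image=image, label=lab, spec=spec, seed=seed)


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Independent +/-10% jitter of the geometric parameters."""
    def j() -> float:
        return float(rng.uniform(0.9, 1.1))

    co = replace(
        spec.cochlea,
        turns=spec.cochlea.turns * j(),
        base_radius_vox=spec.cochlea.base_radius_vox * j(),
        tube_radius_vox=spec.cochlea.tube_radius_vox * j(),
    )
    canals = [
        replace(c, arc_radius_vox=c.arc_radius_vox * j(),
                tube_radius_vox=c.tube_radius_vox * j(), span_deg=c.span_deg * j())
        for c in spec.canals
    ]
    vest = replace(spec.vestibule,
                   semi_axes_vox=tuple(s * j() for s in spec.vestibule.semi_axes_vox))
    return replace(spec, cochlea=co, canals=canals, vestibule=vest)


def generate_dataset(
    spec: PhantomSpec, n: int, seed: int, jitter: bool = True
) -> list[PhantomSample]:
    """n phantoms with per-sample seeds derived deterministically from seed."""
    if n < 1:
        raise PhantomSpecError(f"dataset size must be >= 1, got {n}")
    sample_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    samples = []
    for s in sample_seeds:
        s = int(s)
        sample_spec = spec
        if jitter:
            sample_spec = _jitter_spec(spec, np.random.default_rng(s + 1))
        samples.append(generate_phantom(sample_spec, seed=s))
    return samples


def write_dataset(samples: list[PhantomSample], out_dir: str | Path) -> list[tuple[Path, Path]]:
    """Write paired NIfTI files sample_%03d_img.nii.gz / sample_%03d_lab.nii.gz."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(samples):
        img_p = out_dir / f"sample_{i:03d}_img.nii.gz"
        lab_p = out_dir / f"sample_{i:03d}_lab.nii.gz"
        write_volume(s.image, img_p)
        write_volume(s.label, lab_p)
        paths.append((img_p, lab_p))
    return paths
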