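"""Synthetic 3D cardiothoracic phantom: geometry, velocity field, rendering.

A digital stand-in for a torso volume: chest-wall shell, air-filled interior
(lung), a myocardial shell around a blood pool, and great vessels as tubes —
one aligned with the readout axis and one perpendicular to it, so that the
orientation dependence of flow suppression is representable.  Voxels carry a
tissue label and a 3D velocity vector; images are rendered by looking up the
per-tissue, per-speed echo signal of the physics modules and adding Gaussian
noise.

Label convention: 0 background/lung air, 1 myocardium, 2 blood,
3 chest wall / outer tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

from .epg import FlowSpec, TissueParams, simulate_fse_train
from .flowsim import BLOOD_TISSUE, WALL_TISSUE
from .sequence import SequenceTiming
from .vfa import VFATrain

__all__ = [
    "LABELS",
    "Ellipsoid",
    "Tube",
    "PhantomConfig",
    "PhantomVolume",
    "default_config",
    "make_phantom",
    "render_black_blood",
    "render_bright_blood",
    "save_nifti",
    "load_nifti",
]

LABELS = {"background": 0, "myocardium": 1, "blood": 2, "chest_wall": 3}

#: subcutaneous/chest-wall tissue (fat-dominated) at 1.5 T
CHEST_TISSUE = TissueParams(t1=290.0, t2=85.0, label="chest wall/fat")
MYO_TISSUE = WALL_TISSUE  # myocardium modelled with the design tissue relaxation times


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: |x-c|/r <= 1 per axis (mm)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    label: int
    velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def mask(self, coords: np.ndarray) -> np.ndarray:
        d = (coords - np.asarray(self.center)) / np.asarray(self.radii)
        return np.sum(d * d, axis=-1) <= 1.0


@dataclass(frozen=True)
class Tube:
    """Circular cylinder along one axis (mm), spanning [lo, hi] on that axis."""

    axis: int  # 0, 1 or 2
    center: tuple[float, float]  # in the two perpendicular axes, in axis order
    radius: float
    span: tuple[float, float]
    label: int
    velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def mask(self, coords: np.ndarray) -> np.ndarray:
        perp = [a for a in range(3) if a != self.axis]
        d0 = coords[..., perp[0]] - self.center[0]
        d1 = coords[..., perp[1]] - self.center[1]
        along = coords[..., self.axis]
        return (d0 * d0 + d1 * d1 <= self.radius**2) & (along >= self.span[0]) & (
            along <= self.span[1]
        )


@dataclass
class PhantomConfig:
    """Volume geometry: shape in voxels, voxel size in mm, layered structures.

    Structures are painted in list order, last wins on overlap.  The readout
    axis (for velocity projection at render time) is an axis index.
    """

    shape: tuple[int, int, int] = (80, 80, 64)
    voxel: tuple[float, float, float] = (2.5, 2.5, 2.5)
    structures: list = field(default_factory=list)
    readout_axis: int = 2
    noise_sd: float = 0.005


@dataclass
class PhantomVolume:
    """Labelled volume with per-voxel velocity vectors (mm/s)."""

    labels: np.ndarray  # (nx, ny, nz) int
    velocity_field: np.ndarray  # (nx, ny, nz, 3) float, mm/s
    voxel: tuple[float, float, float]
    noise_sd: float
    seed: int
    readout_axis: int = 2

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def readout_speed(self) -> np.ndarray:
        """|velocity component along the readout axis| per voxel, mm/s."""
        return np.abs(self.velocity_field[..., self.readout_axis])


def default_config() -> PhantomConfig:
    """Torso-like geometry: chest wall shell, lungs (air), heart, two aortic tubes.

    The descending-aorta tube runs along the readout (FH) axis at 100 mm/s;
    the arch tube runs perpendicular (AP) at the same speed, so its blood is
    not dephased by the readout gradients.  The ventricular blood pool moves
    at 50 mm/s along the readout axis (diastolic filling scale).
    """
    chest = LABELS["chest_wall"]
    myo = LABELS["myocardium"]
    blood = LABELS["blood"]
    bg = LABELS["background"]
    structures = [
        Ellipsoid((0, 0, 0), (95, 85, 85), chest),
        Ellipsoid((0, 0, 0), (82, 72, 76), bg),  # interior air/lung
        Ellipsoid((5, 8, -8), (34, 34, 40), myo),
        Ellipsoid((5, 8, -8), (24, 24, 30), blood, velocity=(0, 0, 50.0)),
        Tube(axis=2, center=(-45.0, 15.0), radius=9.0, span=(-80.0, 55.0), label=blood,
             velocity=(0, 0, 100.0)),
        Tube(axis=1, center=(-45.0, 58.0), radius=9.0, span=(-30.0, 30.0), label=blood,
             velocity=(0, 100.0, 0)),
    ]
    return PhantomConfig(structures=structures)


def _coords(config: PhantomConfig) -> np.ndarray:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * dv
        for n, dv in zip(config.shape, config.voxel)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid, axis=-1)


def make_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomVolume:
    """Voxelise the layered geometry into labels and a velocity field."""
    if config is None:
        config = default_config()
    coords = _coords(config)
    labels = np.zeros(config.shape, dtype=np.int16)
    vel = np.zeros(config.shape + (3,), dtype=float)
    for s in config.structures:
        m = s.mask(coords)
        labels[m] = s.label
        vel[m] = np.asarray(s.velocity, dtype=float)
    return PhantomVolume(
        labels=labels,
        velocity_field=vel,
        voxel=config.voxel,
        noise_sd=config.noise_sd,
        seed=seed,
        readout_axis=config.readout_axis,
    )


def _k0_cache_lookup(cache, timing, train, tissue, speed) -> float:
    key = (tissue.t1, tissue.t2, round(float(speed), 9))
    if key not in cache:
        echoes = simulate_fse_train(timing, train, tissue, FlowSpec(float(speed)))
        cache[key] = float(np.abs(echoes[timing.k0_echo_index - 1]))
    return cache[key]


def render_black_blood(
    phantom: PhantomVolume,
    train: VFATrain,
    timing: SequenceTiming,
    spir_factor: float = 0.1,
    add_noise: bool = True,
) -> np.ndarray:
    """Render the 3D FSE image: per-voxel k0 echo magnitude of the voxel tissue.

    Blood and myocardium use their relaxation times and the voxel speed
    projected on the readout axis; chest wall is rendered static and scaled by
    the SPIR fat-suppression factor; background/lung is zero.  Gaussian noise
    with the phantom's noise_sd is added (reproducibly from the phantom seed).
    """
    speed = phantom.readout_speed
    image = np.zeros(phantom.shape, dtype=float)
    cache: dict = {}
    for label, tissue, factor in (
        (LABELS["myocardium"], MYO_TISSUE, 1.0),
        (LABELS["blood"], BLOOD_TISSUE, 1.0),
        (LABELS["chest_wall"], CHEST_TISSUE, spir_factor),
    ):
        mask = phantom.labels == label
        if not np.any(mask):
            continue
        for s in np.unique(speed[mask]):
            val = _k0_cache_lookup(cache, timing, train, tissue, s)
            image[mask & (speed == s)] = factor * val
    if add_noise and phantom.noise_sd > 0:
        rng = np.random.default_rng(phantom.seed)
        image = image + rng.normal(0.0, phantom.noise_sd, size=phantom.shape)
    return image


def bssfp_signal(tissue: TissueParams, tr: float = 4.2, flip: float = 60.0) -> float:
    """Closed-form on-resonance bSSFP steady-state amplitude (TE = TR/2)."""
    e1 = np.exp(-tr / tissue.t1)
    e2 = np.exp(-tr / tissue.t2)
    a = np.deg2rad(flip)
    return float(
        np.sin(a) * np.sqrt(e2) * (1.0 - e1) / (1.0 - (e1 - e2) * np.cos(a) - e1 * e2)
    )


def render_bright_blood(
    phantom: PhantomVolume,
    tr: float = 4.2,
    flip: float = 60.0,
    spir_factor: float = 0.1,
    dephasing_threshold: float | None = None,
    dephasing_factor: float = 0.3,
    add_noise: bool = True,
) -> np.ndarray:
    """Render the bSSFP comparator image from the closed-form steady state.

    Optionally applies a phenomenological flow-dephasing factor to blood
    voxels whose total speed exceeds ``dephasing_threshold`` mm/s (off by
    default), emulating the flow artefacts that hamper pulmonary-vein
    depiction with bright-blood imaging.
    """
    image = np.zeros(phantom.shape, dtype=float)
    for label, tissue, factor in (
        (LABELS["myocardium"], MYO_TISSUE, 1.0),
        (LABELS["blood"], BLOOD_TISSUE, 1.0),
        (LABELS["chest_wall"], CHEST_TISSUE, spir_factor),
    ):
        mask = phantom.labels == label
        image[mask] = factor * bssfp_signal(tissue, tr, flip)
    if dephasing_threshold is not None:
        speed = np.linalg.norm(phantom.velocity_field, axis=-1)
        fast_blood = (phantom.labels == LABELS["blood"]) & (speed > dephasing_threshold)
        image[fast_blood] *= dephasing_factor
    if add_noise and phantom.noise_sd > 0:
        rng = np.random.default_rng(phantom.seed + 1)
        image = image + rng.normal(0.0, phantom.noise_sd, size=phantom.shape)
    return image


def save_nifti(path, volume: np.ndarray, voxel: tuple[float, float, float]) -> None:
    """Write a volume as NIfTI-1 with an RAS+ affine scaled by the voxel size."""
    affine = np.diag(list(voxel) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine
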