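"""Timing, matrix-size, view-ordering and scan-time arithmetic.

Covers the bookkeeping of a navigator-gated 3D fast-spin-echo protocol:
echo spacings, startup-echo count, the centric view order that places the
k-space centre at the first acquired echo, matrix sizing from FOV/voxel/
oversampling/SENSE, and nominal scan-time estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequenceTiming",
    "ProtocolCard",
    "ViewOrder",
    "esp1_from_te_eff",
    "compute_te_eff",
    "matrix_dims",
    "centric_order",
    "max_etl",
    "estimate_scan_time",
    "default_timing",
    "default_protocol_card",
]

#: per-interval readout dephasing, rad/mm: one full dephasing cycle across a
#: 1.3 mm readout voxel per echo spacing
DEFAULT_DK = 2.0 * math.pi / 1.3


@dataclass(frozen=True)
class SequenceTiming:
    """FSE echo-train timing.

    esp1 : excitation-to-first-echo spacing, ms (>= esp2, the slab-selective
        excitation pulse is longer than a refocusing pulse).
    esp2 : inter-echo spacing, ms.
    n_startup : echoes simulated but not acquired at the train start.
    n_acquired : data echoes.
    dk : per-interval readout dephasing, rad/mm per unit configuration order.
    acq_window : acquisition window per heartbeat, ms (metadata).
    """

    esp1: float
    esp2: float
    n_startup: int
    n_acquired: int
    dk: float = DEFAULT_DK
    acq_window: float | None = None

    def __post_init__(self) -> None:
        if not (self.esp1 >= self.esp2 > 0):
            raise ValueError(
                f"require esp1 >= esp2 > 0, got esp1={self.esp1}, esp2={self.esp2}"
            )
        if self.n_startup < 0 or self.n_acquired < 0:
            raise ValueError("echo counts must be non-negative")
        if self.dk <= 0:
            raise ValueError("dk must be positive")

    @property
    def n_echoes(self) -> int:
        return self.n_startup + self.n_acquired

    @property
    def k0_echo_index(self) -> int:
        """1-based index of the echo encoding the k-space centre."""
        return self.n_startup + 1

    @property
    def echo_times(self) -> np.ndarray:
        """Time of each echo after excitation, ms."""
        return self.esp1 + np.arange(self.n_echoes) * self.esp2

    @property
    def acquired_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_echoes, dtype=bool)
        mask[self.n_startup:] = True
        return mask


def esp1_from_te_eff(te_eff: float, n_startup: int, esp2: float) -> float:
    """First echo spacing that places k0 (echo n_startup+1) at the target TE_eff."""
    esp1 = te_eff - n_startup * esp2
    if esp1 < esp2:
        raise ValueError(
            f"TE_eff {te_eff} ms unreachable: implied esp1 {esp1:.3f} < esp2 {esp2}"
        )
    return esp1


def compute_te_eff(timing: SequenceTiming) -> float:
    """Effective echo time: excitation to the k-space-centre echo, ms."""
    return timing.esp1 + timing.n_startup * timing.esp2


@dataclass(frozen=True)
class ProtocolCard:
    """Geometry/acceleration card for one protocol (extents in mm)."""

    fov: tuple[float, float, float]
    voxel: tuple[float, float, float]
    slice_oversampling: float = 1.0
    sense_factor: int = 1
    orientation: str = "coronal"
    readout_axis: str = "FH"
    trigger: str = "mid-diastole"
    nav_gating_window: float | None = None  # mm, metadata only
    nav_tracking_factor: float | None = None  # metadata only
    fat_suppression: bool = True  # metadata only

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.fov) or any(x <= 0 for x in self.voxel):
            raise ValueError("FOV and voxel extents must be positive")
        if self.sense_factor < 1:
            raise ValueError("sense_factor must be >= 1")
        if self.slice_oversampling < 1:
            raise ValueError("slice_oversampling must be >= 1")


def matrix_dims(card: ProtocolCard) -> tuple[int, int, int]:
    """(readout samples, phase encodes after SENSE, slice encodes after oversampling).

    Conservative ceil rounding at every stage; axes are ordered
    (readout, phase, slice).
    """
    n_ro = math.ceil(card.fov[0] / card.voxel[0])
    n_pe = math.ceil(math.ceil(card.fov[1] / card.voxel[1]) / card.sense_factor)
    n_sl = math.ceil(math.ceil(card.fov[2] / card.voxel[2]) * card.slice_oversampling)
    return n_ro, n_pe, n_sl


@dataclass(frozen=True)
class ViewOrder:
    """Centric ordering of (phase-encode, slice-encode) offsets."""

    entries: tuple[tuple[int, int], ...]
    scheme: str = "centric"

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["pe_offset", "sl_offset"])


def centric_order(n_pe: int, n_sl: int) -> ViewOrder:
    """All encode offsets sorted by increasing k-space radius.

    Offsets for an axis of n encodes run from -floor(n/2) to ceil(n/2)-1.
    Ties in Euclidean radius are broken by (|pe|, |sl|, sign(pe), sign(sl)) so
    the order is fully deterministic; the first entry is always (0, 0).
    """
    if n_pe < 1 or n_sl < 1:
        raise ValueError("encode counts must be positive")
    pe = np.arange(n_pe) - n_pe // 2
    sl = np.arange(n_sl) - n_sl // 2
    pe_grid, sl_grid = np.meshgrid(pe, sl, indexing="ij")
    pairs = np.column_stack([pe_grid.ravel(), sl_grid.ravel()])
    keys = sorted(
        map(tuple, pairs),
        key=lambda t: (
            t[0] ** 2 + t[1] ** 2,
            abs(t[0]),
            abs(t[1]),
            t[0] < 0,
            t[1] < 0,
        ),
    )
    return ViewOrder(entries=tuple((int(a), int(b)) for a, b in keys))


def max_etl(acq_window: float, esp2: float) -> int:
    """Largest echo-train length fitting in the per-heartbeat acquisition window."""
    if acq_window <= 0 or esp2 <= 0:
        raise ValueError("acq_window and esp2 must be positive")
    return int(math.floor(acq_window / esp2))


def estimate_scan_time(
    card: ProtocolCard,
    timing: SequenceTiming,
    etl: int,
    rr_ms: float = 1000.0,
    nav_efficiency: float = 1.0,
) -> float:
    """Nominal scan time in seconds: one shot per RR interval.

    Profiles = phase encodes (after SENSE) x slice encodes (after
    oversampling); shots = ceil(profiles / etl); time = shots * RR /
    nav_efficiency.  nav_efficiency = 1 corresponds to the scanner's
    "nominal" time with perfect respiratory gating.
    """
    if etl < 1:
        raise ValueError("etl must be >= 1")
    if not (0 < nav_efficiency <= 1):
        raise ValueError("nav_efficiency must be in (0, 1]")
    _, n_pe, n_sl = matrix_dims(card)
    shots = math.ceil(n_pe * n_sl / etl)
    return shots * rr_ms / nav_efficiency / 1000.0


def default_timing(
    esp2: float = 3.0,
    n_startup: int = 8,
    n_acquired: int = 35,
    te_eff: float = 30.0,
    dk: float = DEFAULT_DK,
    acq_window: float = 140.0,
) -> SequenceTiming:
    """Healthy-subject 3D FSE timing: TE_eff 30 ms, 3.0 ms spacing, 8 startup echoes."""
    return SequenceTiming(
        esp1=esp1_from_te_eff(te_eff, n_startup, esp2),
        esp2=esp2,
        n_startup=n_startup,
        n_acquired=n_acquired,
        dk=dk,
        acq_window=acq_window,
    )


def default_protocol_card() -> ProtocolCard:
    """Healthy-subject 3D FSE geometry: 300x300x110 mm FOV, 1.3 mm isotropic."""
    return ProtocolCard(
        fov=(300.0, 300.0, 110.0),
        voxel=(1.3, 1.3, 1.3),
        slice_oversampling=1.2,
        sense_factor=2,
        orientation="coronal",
        readout_axis="FH",
        trigger="mid-diastole",
        nav_gating_window=7.0,
        nav_tracking_factor=0.6,
        fat_suppression=True,
    )
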