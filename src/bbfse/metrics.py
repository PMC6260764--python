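"""Local SNR/CNR estimators over regions of interest.

Because a separate noise scan is impractical with parallel imaging, the
noise scale is estimated as the standard deviation of an air ROI in the
lungs, and signal as ROI means in the blood pool and myocardium:

    bright mode:  SNR_l = IB / SD(L),   CNR_l = (IB - IM) / SD(L)
    black  mode:  SNR_l = IM / SD(L),   CNR_l = (IM - IB) / SD(L)

where IB and IM are the mean blood-pool and myocardium intensities and
SD(L) the sample standard deviation of the lung ROI (minimum 100 voxels).
The bright/black distinction reflects which tissue carries the signal of
interest in each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ROISet", "MetricsResult", "compute_metrics", "paired_summary"]

MIN_LUNG_PIXELS = 100


@dataclass
class ROISet:
    """Boolean masks aligned to one image volume."""

    blood_mask: np.ndarray
    myocardium_mask: np.ndarray
    lung_mask: np.ndarray
    min_lung_pixels: int = MIN_LUNG_PIXELS

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        blood: int = 2,
        myocardium: int = 1,
        lung: int = 0,
        **kw,
    ) -> "ROISet":
        return cls(
            blood_mask=labels == blood,
            myocardium_mask=labels == myocardium,
            lung_mask=labels == lung,
            **kw,
        )


@dataclass
class MetricsResult:
    ib: float  # mean blood-pool intensity
    im: float  # mean myocardium intensity
    sd_l: float  # lung-air sample SD (noise scale)
    snr_l: float
    cnr_l: float
    mode: str


def compute_metrics(image: np.ndarray, rois: ROISet, mode: str) -> MetricsResult:
    """Local SNR/CNR of an image given blood/myocardium/lung ROIs.

    mode "bright" puts the blood signal in the numerator (bSSFP-style);
    mode "black" the myocardium signal (black-blood FSE-style).  SD(L) uses
    ddof=1.  Raises if the lung ROI has fewer than min_lung_pixels voxels or
    zero variance.
    """
    if mode not in ("bright", "black"):
        raise ValueError(f"mode must be 'bright' or 'black', got {mode!r}")
    for name, mask in (
        ("blood", rois.blood_mask),
        ("myocardium", rois.myocardium_mask),
        ("lung", rois.lung_mask),
    ):
        if mask.shape != image.shape:
            raise ValueError(f"{name} mask shape {mask.shape} != image shape {image.shape}")
    n_lung = int(np.count_nonzero(rois.lung_mask))
    if n_lung < rois.min_lung_pixels:
        raise ValueError(
            f"lung ROI has {n_lung} voxels, below the minimum of {rois.min_lung_pixels}"
        )
    ib = float(np.mean(image[rois.blood_mask]))
    im = float(np.mean(image[rois.myocardium_mask]))
    sd_l = float(np.std(image[rois.lung_mask], ddof=1))
    if sd_l == 0.0:
        raise ValueError("lung ROI has zero variance; SNR undefined")
    if mode == "bright":
        snr, cnr = ib / sd_l, (ib - im) / sd_l
    else:
        snr, cnr = im / sd_l, (im - ib) / sd_l
    return MetricsResult(ib=ib, im=im, sd_l=sd_l, snr_l=snr, cnr_l=cnr, mode=mode)


def paired_summary(
    results_a: list[MetricsResult], results_b: list[MetricsResult]
) -> pd.DataFrame:
    """Descriptive paired comparison (means +/- SD and per-pair differences).

    Purely descriptive; no hypothesis testing.
    """
    if len(results_a) != len(results_b):
        raise ValueError("paired lists must have equal length")
    if not results_a:
        raise ValueError("paired lists must be non-empty")
    rows = []
    for metric in ("snr_l", "cnr_l"):
        a = np.array([getattr(r, metric) for r in results_a], dtype=float)
        b = np.array([getattr(r, metric) for r in results_b], dtype=float)
        d = a - b
        rows.append(
            {
                "metric": metric,
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1) if a.size > 1 else 0.0,
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1) if b.size > 1 else 0.0,
                "mean_diff": d.mean(),
                "sd_diff": d.std(ddof=1) if d.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
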