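"""Pixelwise diffusion metric maps (SDC, DDVD, ADC) and ROI aggregation.

Three metrics, each from a pair of b-values of one co-registered series:

* **SDC** (slow diffusion coefficient), ``[S(b1) - S(b2)] / (b2 - b1)`` with
  b1=500 and b2=750 s/mm^2 by default — a linear signal-difference index of
  tissue slow diffusion that avoids the log-ratio T2 sensitivity of ADC.
  Reported in au/s (the field's conventional label for this quantity).
* **DDVD** (diffusion-derived vessel density), the mean per-pixel signal drop
  between b=0 and a very low b (default 10 s/mm^2), a microvascular-perfusion
  surrogate in au/pixel.  The ROI-scalar form ``S_b0/area - S_b10/area``
  equals, exactly, the ROI mean of the pixelwise ``S_b0 - S_b10`` map when
  both volumes share the mask.
* **ADC** (apparent diffusion coefficient), the conventional mono-exponential
  estimate ``ln(S(b1)/S(b2)) / (b2 - b1)``, default b = 0 and 1000 s/mm^2,
  in mm^2/s.

Maps are computed whole-volume and mask-independent; the ROI enters only at
aggregation.  Signals are raw arbitrary units — no normalization is applied
by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import DWISeries, ROIMask

__all__ = [
    "MetricMaps",
    "MetricTriplet",
    "DDVDResult",
    "ROIStats",
    "compute_sdc",
    "compute_ddvd",
    "compute_adc",
    "compute_maps",
    "normalize_by_b0_roi_mean",
    "roi_aggregate",
    "ADC_MM2S",
    "ADC_E4",
]

#: unit tags for ADC values
ADC_MM2S = "mm2/s"
ADC_E4 = "1e-4 mm2/s"

# default b-value pairs (s/mm^2)
SDC_B = (500.0, 750.0)
DDVD_B = (0.0, 10.0)
ADC_B = (0.0, 1000.0)


@dataclasses.dataclass(frozen=True)
class MetricTriplet:
    """Per-lesion scalar summary of the three metrics.

    ``adc_unit`` is mandatory: the genotype model consumes ADC in
    1e-4 mm^2/s, and a silent factor-10^4 error is the most likely misuse.
    """

    sdc: float                 # au/s
    ddvd: float                # au/pixel
    adc: float
    adc_unit: str = ADC_E4

    def __post_init__(self) -> None:
        if self.adc_unit not in (ADC_MM2S, ADC_E4):
            raise ValueError(
                f"unknown adc unit tag {self.adc_unit!r}; "
                f"use {ADC_MM2S!r} or {ADC_E4!r}")
        for name in ("sdc", "ddvd", "adc"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def adc_in(self, unit: str) -> float:
        """ADC converted to the requested unit."""
        if unit == self.adc_unit:
            return self.adc
        if (self.adc_unit, unit) == (ADC_MM2S, ADC_E4):
            return self.adc * 1e4
        if (self.adc_unit, unit) == (ADC_E4, ADC_MM2S):
            return self.adc * 1e-4
        raise ValueError(f"cannot convert {self.adc_unit!r} to {unit!r}")


@dataclasses.dataclass
class MetricMaps:
    """Whole-volume metric maps plus per-metric validity masks."""

    sdc: np.ndarray            # au/s
    ddvd: np.ndarray           # au/pixel (pixelwise S_b0 - S_b10)
    adc: np.ndarray            # mm^2/s, NaN where not computable
    sdc_valid: np.ndarray
    ddvd_valid: np.ndarray
    adc_valid: np.ndarray
    affine: np.ndarray


@dataclasses.dataclass
class DDVDResult:
    """ROI-scalar DDVD plus its pixelwise map."""

    scalar: float              # au/pixel
    pixelwise: np.ndarray      # au/pixel, whole volume
    n_pixels: int


@dataclasses.dataclass
class ROIStats:
    """ROI aggregation output: the triplet and exclusion bookkeeping."""

    triplet: MetricTriplet
    n_voxels: int
    n_excluded: dict[str, int]


def normalize_by_b0_roi_mean(series: DWISeries, mask: ROIMask) -> DWISeries:
    """Divide all volumes by the ROI-mean b=0 signal.

    A variant, not the default: SDC and DDVD are defined on raw
    arbitrary-unit intensities.  Normalizing makes SDC/DDVD dimensionless
    per-ROI quantities and is intended only for cross-series comparisons
    where scanner-side intensity normalization cannot be assumed.
    """
    mask.check_grid(series)
    ref = float(series.volume(0.0)[mask.mask].mean())
    if ref <= 0:
        raise ValueError("ROI-mean b=0 signal must be positive")
    return DWISeries(b_values=series.b_values.copy(),
                     data=series.data / ref,
                     affine=series.affine.copy())


def _check_pair(series: DWISeries, b1: float, b2: float) -> None:
    if b1 >= b2:
        raise ValueError(f"b1 must be smaller than b2 (got {b1:g} >= {b2:g})")
    for b in (b1, b2):
        if not series.has_b(b):
            raise KeyError(
                f"series has no volume at b={b:g}; available: "
                f"{series.b_values.tolist()}")


def compute_sdc(
    series: DWISeries,
    b1: float = SDC_B[0],
    b2: float = SDC_B[1],
) -> np.ndarray:
    """Pixelwise slow diffusion coefficient, ``(S(b1) - S(b2))/(b2 - b1)``.

    Negative values (noise) are preserved, not clipped: clipping would bias
    ROI means upward.  Unit: au/s.
    """
    _check_pair(series, b1, b2)
    return (series.volume(b1) - series.volume(b2)) / (b2 - b1)


def compute_adc(
    series: DWISeries,
    b1: float = ADC_B[0],
    b2: float = ADC_B[1],
) -> np.ndarray:
    """Pixelwise apparent diffusion coefficient, ``ln(S(b1)/S(b2))/(b2-b1)``.

    Voxels where either signal is non-positive are NaN (the log-ratio is
    undefined); they are excluded, and counted, at aggregation.  Unit: mm^2/s.
    """
    _check_pair(series, b1, b2)
    s1, s2 = series.volume(b1), series.volume(b2)
    adc = np.full(s1.shape, np.nan)
    ok = (s1 > 0) & (s2 > 0)
    adc[ok] = np.log(s1[ok] / s2[ok]) / (b2 - b1)
    return adc


def compute_ddvd(
    series: DWISeries,
    mask: ROIMask | None = None,
    b_low: float = DDVD_B[0],
    b_high: float = DDVD_B[1],
) -> DDVDResult:
    """Diffusion-derived vessel density.

    Pixelwise map: ``S(b_low) - S(b_high)`` per voxel.  ROI scalar (if a mask
    is given): mean in-ROI signal at b_low minus mean in-ROI signal at
    b_high — identically the ROI mean of the pixelwise map, since both
    volumes share the mask.  Unit: au/pixel.
    """
    _check_pair(series, b_low, b_high)
    pixelwise = series.volume(b_low) - series.volume(b_high)
    if mask is None:
        return DDVDResult(scalar=float("nan"), pixelwise=pixelwise,
                          n_pixels=0)
    mask.check_grid(series)
    m = mask.mask
    area = int(np.count_nonzero(m))
    scalar = (float(series.volume(b_low)[m].sum()) / area
              - float(series.volume(b_high)[m].sum()) / area)
    return DDVDResult(scalar=scalar, pixelwise=pixelwise, n_pixels=area)


def compute_maps(
    series: DWISeries,
    sdc_b: tuple[float, float] = SDC_B,
    ddvd_b: tuple[float, float] = DDVD_B,
    adc_b: tuple[float, float] = ADC_B,
) -> MetricMaps:
    """All three whole-volume metric maps from one series."""
    sdc = compute_sdc(series, *sdc_b)
    ddvd = compute_ddvd(series, None, *ddvd_b).pixelwise
    adc = compute_adc(series, *adc_b)
    return MetricMaps(
        sdc=sdc,
        ddvd=ddvd,
        adc=adc,
        sdc_valid=np.isfinite(sdc),
        ddvd_valid=np.isfinite(ddvd),
        adc_valid=np.isfinite(adc),
        affine=series.affine,
    )


def roi_aggregate(maps: MetricMaps, mask: ROIMask) -> ROIStats:
    """Mean of each metric over valid in-mask voxels.

    The mean (not median) is the aggregation statistic: the DDVD scalar
    definition is itself a ROI mean, and a single statistic keeps the three
    metrics commensurate.  ADC is converted to 1e-4 mm^2/s for the modelling
    triplet.  Invalid (NaN) voxels are dropped per metric and counted;
    a metric with no valid voxel in the ROI is an error.
    """
    if mask.mask.shape != maps.sdc.shape:
        raise ValueError(
            f"mask grid {mask.mask.shape} != map grid {maps.sdc.shape}")
    m = mask.mask
    n_vox = int(np.count_nonzero(m))
    values: dict[str, float] = {}
    n_excluded: dict[str, int] = {}
    for name, arr, valid in (
        ("sdc", maps.sdc, maps.sdc_valid),
        ("ddvd", maps.ddvd, maps.ddvd_valid),
        ("adc", maps.adc, maps.adc_valid),
    ):
        sel = m & valid
        n_excluded[name] = n_vox - int(np.count_nonzero(sel))
        if not sel.any():
            raise ValueError(
                f"all {n_vox} ROI voxels invalid for metric {name!r}")
        values[name] = float(arr[sel].mean())
    triplet = MetricTriplet(
        sdc=values["sdc"],
        ddvd=values["ddvd"],
        adc=values["adc"] * 1e4,
        adc_unit=ADC_E4,
    )
    return ROIStats(triplet=triplet, n_voxels=n_vox, n_excluded=n_excluded)
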