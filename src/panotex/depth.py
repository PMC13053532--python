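"""Transmittance depth map and the scalar texture indices derived from it.

The depth map assigns every ROI pixel a dimensionless score

    R_ij = [ ln((A_i - B_ij)^2 + 1) * sin(pi/2 * B_ij / A_i) ]^2

where ``B_ij`` is the 8-bit intensity at row *i*, column *j* and ``A_i``
is the maximum intensity of row *i* inside the ROI. The first factor grows
with the drop below the row maximum (a transmittance deficit); the sine
factor suppresses pixels that are dark in absolute terms, so R peaks for
pixels that are bright yet clearly below their row's brightest point —
exactly the signature of a radiolucent canal crossing dense dentin.

R_ij is zero iff ``B_ij = A_i`` (no deficit), ``B_ij = 0`` (sine factor
zero) or ``A_i = 0`` (row defined as all-zero: nothing transmitted, no
depth signal). Natural log is used; the base only rescales the map and is
configurable.

Two scalar indices summarise a map:

* **Xpar** — the arithmetic mean of all R_ij: average relative depth
  variation per pixel.
* **Power Xpar** — ``scale * (mean(R_ij^p))^(1/p)``, a scaled generalized
  power mean (defaults p=2, scale=10) that amplifies the large-R tail of
  the distribution and is therefore more sensitive to localized structural
  heterogeneity than the plain mean.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .imaging import GrayscaleImage, Kernel, ZoomState, digital_zoom, pixel_count

#: default exponent of the Power Xpar power mean
DEFAULT_POWER_P = 2.0
#: default multiplicative scale of Power Xpar
DEFAULT_POWER_SCALE = 10.0


class Condition(str, enum.Enum):
    NON_ZOOMED = "non_zoomed"
    ZOOMED = "zoomed"


@dataclass
class DepthMap:
    """Per-pixel depth values R_ij with the row maxima A_i used to build them."""

    r_values: np.ndarray
    row_max: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.r_values.shape


@dataclass
class TextureMetrics:
    """The three scalar indices of one ROI under one viewing condition."""

    xpar: float
    power_xpar: float
    pixel_count: int
    condition: Condition
    power_p: float = DEFAULT_POWER_P
    power_scale: float = DEFAULT_POWER_SCALE


def depth_map(roi: GrayscaleImage | np.ndarray, log_base: float = math.e) -> DepthMap:
    """Compute the transmittance depth map of an ROI.

    Rows whose maximum is zero are defined as all-zero. The result is
    finite everywhere and non-negative. ``log_base`` rescales the log
    factor (natural log by default).
    """
    px = roi.pixels if isinstance(roi, GrayscaleImage) else np.asarray(roi)
    if px.ndim != 2 or px.size == 0:
        raise ValueError("ROI must be a non-empty 2-D array")
    b = px.astype(np.float64)
    a = b.max(axis=1)  # A_i, row maxima within the ROI

    r = np.zeros_like(b)
    live = a > 0
    if live.any():
        al = a[live][:, None]
        bl = b[live]
        log_term = np.log((al - bl) ** 2 + 1.0)
        if log_base != math.e:
            log_term = log_term / math.log(log_base)
        sin_term = np.sin(0.5 * np.pi * bl / al)
        r[live] = (log_term * sin_term) ** 2
    return DepthMap(r_values=r, row_max=a)


def xpar_index(dm: DepthMap) -> float:
    """Xpar: arithmetic mean of all R_ij over the ROI."""
    return float(dm.r_values.mean())


def power_xpar_index(
    dm: DepthMap, p: float = DEFAULT_POWER_P, scale: float = DEFAULT_POWER_SCALE
) -> float:
    """Power Xpar: ``scale * (mean(R_ij^p))^(1/p)``.

    A power mean with p > 1 weights large depth values more heavily than
    the plain mean, so spatially concentrated heterogeneity (a high-contrast
    canal ribbon) raises Power Xpar faster than it raises Xpar. Monotone in
    every R_ij.
    """
    if p < 1:
        raise ValueError("power exponent p must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return float(scale * (np.mean(dm.r_values**p)) ** (1.0 / p))


def metrics_for_roi(
    roi: GrayscaleImage,
    condition: Condition,
    p: float = DEFAULT_POWER_P,
    scale: float = DEFAULT_POWER_SCALE,
    log_base: float = math.e,
) -> TextureMetrics:
    """Compute the (Xpar, Power Xpar, Pixel Count) bundle for one ROI."""
    dm = depth_map(roi, log_base=log_base)
    return TextureMetrics(
        xpar=xpar_index(dm),
        power_xpar=power_xpar_index(dm, p=p, scale=scale),
        pixel_count=pixel_count(roi),
        condition=condition,
        power_p=p,
        power_scale=scale,
    )


def metrics_bundle(
    roi: GrayscaleImage,
    zoom_factor: float = 1.5,
    kernel: Kernel | str = Kernel.BILINEAR,
    p: float = DEFAULT_POWER_P,
    scale: float = DEFAULT_POWER_SCALE,
    log_base: float = math.e,
) -> tuple[TextureMetrics, TextureMetrics]:
    """Metric bundles for the native ROI and its digitally zoomed version.

    The zoomed bundle is measured on ``digital_zoom(roi, zoom_factor,
    kernel)`` — the whole ROI resampled, with no re-selection. (The cohort
    generator additionally re-selects the zoomed ROI with jitter to emulate
    a reader re-drawing the region on the magnified image.)
    """
    non_zoomed = metrics_for_roi(
        roi, Condition.NON_ZOOMED, p=p, scale=scale, log_base=log_base
    )
    zoomed_roi = digital_zoom(roi, zoom_factor, kernel)
    zoomed = metrics_for_roi(
        zoomed_roi, Condition.ZOOMED, p=p, scale=scale, log_base=log_base
    )
    return non_zoomed, zoomed


def depth_map_to_png(dm: DepthMap, path) -> None:
    """Export a depth map as an 8-bit PNG, linearly rescaled to [0, 255]."""
    from .imaging import write_png

    write_png(dm.r_values, path)


def depth_map_to_csv(dm: DepthMap, path) -> None:
    """Export the raw R_ij matrix as CSV."""
    np.savetxt(path, dm.r_values, delimiter=",")
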