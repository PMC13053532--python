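"""Synthetic dentin–pulp ROI phantoms and labelled cohorts.

No public radiograph archive accompanies the study design this package
implements, so every downstream stage (depth maps, indices, zoom
comparison, diagnostics) is driven by phantoms generated here.

A phantom emulates a rectangular panoramic-radiograph ROI cropped to the
dentin–pulp complex of a mandibular premolar: a bright, smoothly varying
dentin field crossed by a darker root-canal region. Two canal morphologies
are rendered:

* ``simple`` — a narrow axis-aligned dark ellipse (a single straight canal
  in projection);
* ``c_shaped`` — a dark annular arc ribbon of the same area budget,
  standing in for the ribbon-like cross-section of a C-shaped canal. The
  arc spreads its darkening over fewer rows but more pixels per row, which
  is exactly the kind of localized gray-level heterogeneity the depth
  indices are designed to amplify.

The structure field is Gaussian-blurred (detector/projection unsharpness)
and corrupted with additive white Gaussian noise, then quantized to 8 bits.

A cohort couples the phantoms to the statistical frame of the study: two
native-resolution contexts with an unbalanced class split, subject
covariates with no true effect on the texture metrics, a dentin–pulp
volume covariate with a standardized group difference, and paired
zoomed/non-zoomed measurements in which the zoomed ROI is re-selected with
jitter (a reader re-drawing the region on the magnified image), so zoomed
pixel counts are larger than — but not exact multiples of — the native
counts.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .depth import (
    Condition,
    DEFAULT_POWER_P,
    DEFAULT_POWER_SCALE,
    TextureMetrics,
    metrics_for_roi,
)
from .imaging import (
    GrayscaleImage,
    Kernel,
    ROIRect,
    ResolutionTag,
    crop_roi,
    digital_zoom,
)


class CanalShape(str, enum.Enum):
    SIMPLE = "simple"
    C_SHAPED = "c_shaped"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class AgeGroup(str, enum.Enum):
    YOUNG = "17-39"
    OLD = "40-54"


class Side(str, enum.Enum):
    RIGHT = "right"
    LEFT = "left"


class ResolutionGroup(str, enum.Enum):
    GROUP_496 = "group_496"
    GROUP_593 = "group_593"


_RES_TAG = {
    ResolutionGroup.GROUP_496: ResolutionTag.R1023x496,
    ResolutionGroup.GROUP_593: ResolutionTag.R1023x593,
}


@dataclass
class PhantomParams:
    """Rendering parameters of one dentin–pulp ROI phantom.

    Intensities are 8-bit gray levels; lengths are pixels. The defaults
    are calibrated so that default cohorts produce non-zoomed Xpar and
    Pixel Count values inside the ranges reported for clinical
    dentin–pulp ROIs (see the methods note).
    """

    roi_height: int = 62
    roi_width: int = 32
    dentin_mean: float = 190.0
    dentin_gradient: float = 0.25
    canal_shape: CanalShape = CanalShape.SIMPLE
    canal_contrast: float = 12.0
    canal_width: int = 6
    c_arc_span: float = 3.8  # radians
    # relative darkening at the ROI's lateral edges; nonzero values interact
    # with canal shape (a wide arc reaches darker columns than a straight
    # band) and so bias the shape comparison — default keeps the base flat
    lateral_falloff: float = 0.0
    noise_sd: float = 2.0
    blur_sigma: float = 1.1
    bit_depth: int = 8

    def validate(self) -> None:
        if self.roi_height < 8 or self.roi_width < 8:
            raise ValueError("ROI must be at least 8x8 pixels")
        if not (0 <= self.canal_contrast <= self.dentin_mean):
            raise ValueError("canal_contrast must lie in [0, dentin_mean]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.canal_width < 1:
            raise ValueError("canal_width must be >= 1")


def make_tooth_phantom(
    params: PhantomParams, rng_seed: int
) -> tuple[GrayscaleImage, np.ndarray]:
    """Render one phantom ROI and its boolean canal mask.

    Deterministic in (params, rng_seed). The mask marks canal pixels of
    the pre-blur structure field.
    """
    params.validate()
    rng = np.random.default_rng(rng_seed)
    h, w = params.roi_height, params.roi_width
    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)

    # dentin body: vertical gradient + mild lateral falloff toward ROI edges
    base = params.dentin_mean + params.dentin_gradient * (rows - h / 2)
    lateral = 1.0 - params.lateral_falloff * ((cols - (w - 1) / 2) / (w / 2)) ** 2
    fieldv = base * lateral

    mask = _canal_mask(params)
    fieldv = fieldv - params.canal_contrast * mask

    if params.blur_sigma > 0:
        fieldv = ndimage.gaussian_filter(fieldv, params.blur_sigma, mode="nearest")
    if params.noise_sd > 0:
        fieldv = fieldv + rng.normal(0.0, params.noise_sd, size=(h, w))

    hi = 2**params.bit_depth - 1
    px = np.rint(np.clip(fieldv, 0, hi)).astype(np.uint8)
    img = GrayscaleImage(
        pixels=px,
        bit_depth=params.bit_depth,
        source_resolution_tag=ResolutionTag.SYNTHETIC,
    )
    return img, mask.astype(bool)


def _canal_mask(params: PhantomParams) -> np.ndarray:
    """Binary canal geometry: straight rounded band (simple) or annular arc.

    Both shapes are ribbons of thickness ``canal_width`` with the same
    area budget, so morphology (curvature and row distribution) — not
    total darkened area or ribbon thickness — distinguishes them.
    """
    h, w = params.roi_height, params.roi_width
    rr = np.arange(h)[:, None] - (h - 1) / 2
    cc = np.arange(w)[None, :] - (w - 1) / 2

    half_w = params.canal_width / 2.0
    # area budget shared by both shapes, limited by the largest arc that fits
    r_max = (min(h, w) - params.canal_width) / 2.0 - 1.0
    area = params.canal_width * min(0.9 * h, params.c_arc_span * r_max)

    # annular arc of thickness canal_width at the largest radius that fits
    radius = np.hypot(rr, cc)
    theta = np.arctan2(rr, cc)  # 0 rad points right, +pi/2 points down
    half = params.c_arc_span / 2.0
    ang = np.abs(np.angle(np.exp(1j * (theta - np.pi / 2))))
    r0 = min(area / (params.c_arc_span * params.canal_width), r_max)
    arc = ((np.abs(radius - r0) <= half_w) & (ang <= half)).astype(float)
    if params.canal_shape is CanalShape.C_SHAPED:
        return arc

    # vertical capsule whose *discrete* pixel area matches the discrete arc
    # area for the same parameters (pixelization shifts the continuous
    # budget by a few percent, which would otherwise leak the canal shape
    # into total darkened area)
    target = arc.sum()

    def capsule(half_len: float) -> np.ndarray:
        dr = np.maximum(np.abs(rr) - half_len, 0.0)
        return (np.hypot(dr, cc) <= half_w).astype(float)

    candidates = np.linspace(1.0, (h - params.canal_width) / 2.0, 64)
    best = min(candidates, key=lambda L: abs(capsule(L).sum() - target))
    return capsule(best)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: anchor for the control-group dentin–pulp volume distribution (mm^3)
VOLUME_CONTROL_MEAN = 383.86
#: common within-group SD of the volume covariate (mm^3); with the default
#: standardized difference 0.90 the C-shaped mean lands at 452.5 mm^3
VOLUME_SD = 76.25


@dataclass
class CohortSpec:
    """Statistical frame of a generated cohort.

    ``resolution_split`` maps each native-resolution group to its
    ``(n_c_shaped, n_control)`` pair; the pairs must sum to the top-level
    counts. ``heterogeneity_effect`` is the difference in the
    canal-complexity knob between C-shaped and control teeth (0 = null
    cohort); the knob multiplies both canal contrast and canal width.
    ``volume_effect_d`` is the standardized mean difference of the volume
    covariate. The zoomed condition magnifies by a factor drawn from
    ``zoom_factor_range`` and re-selects the ROI with up to
    ``roi_jitter_frac`` per-axis shrink and a random offset.
    """

    n_c_shaped: int = 22
    n_control: int = 21
    resolution_split: dict = field(
        default_factory=lambda: {
            ResolutionGroup.GROUP_496: (10, 16),
            ResolutionGroup.GROUP_593: (12, 5),
        }
    )
    heterogeneity_effect: float = 0.6
    volume_effect_d: float = 0.90
    sex_prob: float = 0.674  # P(male)
    age_group_prob: float = 0.558  # P(17-39)
    zoom_factor_range: tuple[float, float] = (1.25, 1.40)
    roi_jitter_frac: float = 0.10
    zoom_kernel: Kernel = Kernel.BILINEAR
    power_p: float = DEFAULT_POWER_P
    power_scale: float = DEFAULT_POWER_SCALE
    seed: int = 0

    def validate(self) -> None:
        if self.n_c_shaped < 0 or self.n_control < 0:
            raise ValueError("group counts must be >= 0")
        for p in (self.sex_prob, self.age_group_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.zoom_factor_range
        if not (1 < lo <= hi <= 4):
            raise ValueError("zoom_factor_range must be within (1, 4]")
        if self.heterogeneity_effect < 0:
            raise ValueError("heterogeneity_effect must be >= 0")
        if not 0 <= self.roi_jitter_frac < 1:
            raise ValueError("roi_jitter_frac must lie in [0, 1)")
        split = {ResolutionGroup(k): tuple(v) for k, v in self.resolution_split.items()}
        c_total = sum(v[0] for v in split.values())
        n_total = sum(v[1] for v in split.values())
        if c_total != self.n_c_shaped or n_total != self.n_control:
            raise ValueError(
                "resolution_split totals "
                f"({c_total} C-shaped, {n_total} control) disagree with group "
                f"counts ({self.n_c_shaped}, {self.n_control})"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        """Load a spec from a JSON config file."""
        raw = json.loads(Path(path).read_text())
        if "resolution_split" in raw:
            raw["resolution_split"] = {
                ResolutionGroup(k): tuple(v)
                for k, v in raw["resolution_split"].items()
            }
        if "zoom_factor_range" in raw:
            raw["zoom_factor_range"] = tuple(raw["zoom_factor_range"])
        if "zoom_kernel" in raw:
            raw["zoom_kernel"] = Kernel(raw["zoom_kernel"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["resolution_split"] = {
            ResolutionGroup(k).value: list(v) for k, v in self.resolution_split.items()
        }
        d["zoom_factor_range"] = list(self.zoom_factor_range)
        d["zoom_kernel"] = Kernel(self.zoom_kernel).value
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class CohortRecord:
    """One tooth: label, covariates and paired texture measurements."""

    tooth_id: str
    c_shaped: bool
    sex: Sex
    age_group: AgeGroup
    side: Side
    resolution_group: ResolutionGroup
    dentin_pulp_volume: float
    pulp_length: float
    metrics_non_zoomed: TextureMetrics
    metrics_zoomed: TextureMetrics
    phantom: GrayscaleImage | None = None


#: per-resolution-group noise multiplier: the higher-resolution detector
#: context produces slightly less grain, which narrows its index spread
_GROUP_NOISE_SCALE = {
    ResolutionGroup.GROUP_496: 1.0,
    ResolutionGroup.GROUP_593: 0.8,
}


def sample_cohort(spec: CohortSpec, keep_phantoms: bool = False) -> list[CohortRecord]:
    """Generate a labelled cohort; deterministic in ``spec`` (incl. seed).

    Each record's phantom is measured non-zoomed and again after digital
    magnification with jittered ROI re-selection.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    records: list[CohortRecord] = []
    idx = 0
    split = {ResolutionGroup(k): tuple(v) for k, v in spec.resolution_split.items()}
    for group, (n_c, n_ctrl) in sorted(split.items(), key=lambda kv: kv[0].value):
        for c_shaped, n in ((True, n_c), (False, n_ctrl)):
            for _ in range(n):
                rec_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                records.append(
                    _sample_record(spec, group, c_shaped, idx, rng, rec_seed,
                                   keep_phantoms)
                )
                idx += 1
    return records


def _sample_record(
    spec: CohortSpec,
    group: ResolutionGroup,
    c_shaped: bool,
    idx: int,
    rng: np.random.Generator,
    phantom_seed: int,
    keep_phantom: bool,
) -> CohortRecord:
    # covariates — no true effect on the texture metrics
    sex = Sex.MALE if rng.random() < spec.sex_prob else Sex.FEMALE
    age = AgeGroup.YOUNG if rng.random() < spec.age_group_prob else AgeGroup.OLD
    side = Side.RIGHT if rng.random() < 0.5 else Side.LEFT

    vol_mean = VOLUME_CONTROL_MEAN + (spec.volume_effect_d * VOLUME_SD if c_shaped else 0)
    volume = max(50.0, rng.normal(vol_mean, VOLUME_SD))
    pulp_length = max(5.0, rng.normal(21.7, 1.4))

    # ROI geometry: tall rectangle whose area matches clinical pixel counts
    area = float(np.clip(rng.normal(1950.0, 330.0), 1300.0, 2650.0))
    aspect = rng.uniform(1.6, 2.1)
    height = int(round(np.sqrt(area * aspect)))
    width = max(8, int(round(area / height)))

    # canal-complexity knob: group difference delta on a unit-mean scale
    knob = rng.normal(1.0 + (spec.heterogeneity_effect if c_shaped else 0.0), 0.15)
    knob = max(0.2, knob)
    noise_scale = _GROUP_NOISE_SCALE[group]
    params = PhantomParams(
        roi_height=height,
        roi_width=width,
        dentin_mean=float(rng.normal(190.0, 6.0)),
        dentin_gradient=float(rng.normal(0.25, 0.05)),
        canal_shape=CanalShape.C_SHAPED if c_shaped else CanalShape.SIMPLE,
        canal_contrast=12.0 * knob,
        canal_width=max(2, int(round(6 * knob))),
        noise_sd=float(max(0.5, rng.normal(2.0, 0.30))) * noise_scale,
    )
    img, _ = make_tooth_phantom(params, phantom_seed)
    img.source_resolution_tag = _RES_TAG[group]

    non_zoomed = metrics_for_roi(
        img, Condition.NON_ZOOMED, p=spec.power_p, scale=spec.power_scale
    )

    # zoomed condition: magnify, then re-select the ROI with jitter
    factor = rng.uniform(*spec.zoom_factor_range)
    zoomed_full = digital_zoom(img, factor, spec.zoom_kernel)
    zh, zw = zoomed_full.shape
    sel_h = min(zh, max(img.shape[0] + 1,
                        int(round(zh * (1 - rng.uniform(0, spec.roi_jitter_frac))))))
    sel_w = min(zw, max(img.shape[1] + 1,
                        int(round(zw * (1 - rng.uniform(0, spec.roi_jitter_frac))))))
    row0 = int(rng.integers(0, zh - sel_h + 1))
    col0 = int(rng.integers(0, zw - sel_w + 1))
    zoom_roi = crop_roi(zoomed_full, ROIRect(row0, col0, sel_h, sel_w))
    zoomed = metrics_for_roi(
        zoom_roi, Condition.ZOOMED, p=spec.power_p, scale=spec.power_scale
    )

    return CohortRecord(
        tooth_id=f"T{idx:03d}",
        c_shaped=c_shaped,
        sex=sex,
        age_group=age,
        side=side,
        resolution_group=group,
        dentin_pulp_volume=float(volume),
        pulp_length=float(pulp_length),
        metrics_non_zoomed=non_zoomed,
        metrics_zoomed=zoomed,
        phantom=img if keep_phantom else None,
    )


# ---------------------------------------------------------------------------
# cohort <-> table
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "tooth_id",
    "c_shaped",
    "sex",
    "age_group",
    "side",
    "resolution_group",
    "dentin_pulp_volume",
    "pulp_length",
    "xpar_non_zoomed",
    "power_xpar_non_zoomed",
    "pixel_count_non_zoomed",
    "xpar_zoomed",
    "power_xpar_zoomed",
    "pixel_count_zoomed",
]


def cohort_to_dataframe(records: list[CohortRecord]) -> pd.DataFrame:
    """One row per tooth: label, covariates and the six metric values."""
    rows = []
    for r in records:
        rows.append(
            {
                "tooth_id": r.tooth_id,
                "c_shaped": bool(r.c_shaped),
                "sex": r.sex.value,
                "age_group": r.age_group.value,
                "side": r.side.value,
                "resolution_group": r.resolution_group.value,
                "dentin_pulp_volume": r.dentin_pulp_volume,
                "pulp_length": r.pulp_length,
                "xpar_non_zoomed": r.metrics_non_zoomed.xpar,
                "power_xpar_non_zoomed": r.metrics_non_zoomed.power_xpar,
                "pixel_count_non_zoomed": r.metrics_non_zoomed.pixel_count,
                "xpar_zoomed": r.metrics_zoomed.xpar,
                "power_xpar_zoomed": r.metrics_zoomed.power_xpar,
                "pixel_count_zoomed": r.metrics_zoomed.pixel_count,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def cohort_to_csv(records: list[CohortRecord], path: str | Path) -> None:
    cohort_to_dataframe(records).to_csv(path, index=False)


def cohort_from_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table, checking the schema contract."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# screening frame of the emulated study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningFrame:
    """Bookkeeping of the emulated retrospective screen.

    602 candidate teeth were reviewed on the 3-D reference standard, 36
    showed the ribbon-like canal; of the 72 candidate radiographs (both
    classes), quality control removed 13 positives and 16 controls, and
    the survivors were matched into two native-resolution strata.
    """

    teeth_screened: int = 602
    c_shaped_found: int = 36
    candidate_radiographs: int = 72
    excluded_c_shaped: int = 13
    excluded_control: int = 16
    strata: tuple[tuple[int, int], ...] = ((10, 16), (12, 5))

    @property
    def analyzed(self) -> int:
        return self.candidate_radiographs - self.excluded_c_shaped - self.excluded_control

    @property
    def n_c_shaped(self) -> int:
        return sum(s[0] for s in self.strata)

    @property
    def n_control(self) -> int:
        return sum(s[1] for s in self.strata)

    @property
    def incidence_percent(self) -> float:
        """Prevalence of the morphology in the screened sample, in %."""
        return 100.0 * self.c_shaped_found / self.teeth_screened
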