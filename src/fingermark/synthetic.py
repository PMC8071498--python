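"""Synthetic detection-window images and donor cohorts.

No public image dataset exists for this assay, so the package carries its
own forward model.  It renders what the scanner would see: a colored
detection window on a plain background, where the mean HSB saturation of
the window is linear in the arginine concentration,

    S(C) = clamp(a + b * C, 0, 100)   [percent].

Window pixels are pure red before any tinting, with brightness pinned at
255: the pixel for target saturation ``s`` (as a fraction) is
``(255, 255*(1-s), 255*(1-s))``, so saturation alone encodes the
concentration.  Optional i.i.d. Gaussian noise is added per channel on the
0-255 scale, then clipped and rounded, emulating scanner/sensor noise.

Cohort simulation draws per-print arginine concentrations around
literature sweat means (94.8 µM for females, 54.0 µM for males) with the
total per-print spread split into a donor-level component and a
print-level component by ``between_fraction``.  Two nuisance processes of
real casework can be switched on: a multiplicative lifting-recovery loss
(prints lifted from surfaces recover less material) and dark powder
speckle overwriting part of the window (residue of magnetic fingerprint
powder).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .image_io import write_image

__all__ = [
    "ForwardModel",
    "CohortConfig",
    "SyntheticPrint",
    "SyntheticDonor",
    "DEFAULT_STANDARD_CONCENTRATIONS",
    "FINGER_ORDER",
    "render_detection_window",
    "sample_print_concentrations",
    "generate_cohort",
    "generate_standard_series",
    "noise_free",
    "write_cohort",
]

#: Standard-series concentrations in µM used for the calibration curve.
DEFAULT_STANDARD_CONCENTRATIONS: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0)

#: Finger labels in the order prints are assigned; the admitted fingers
#: (index, middle, ring) come first so the default 3 prints per donor are
#: exactly the admitted set.
FINGER_ORDER: tuple[str, ...] = ("index", "middle", "ring", "thumb", "little")


@dataclass(frozen=True)
class ForwardModel:
    """Parameters of the image rendering model.

    Defaults place the 20-120 µM standard range inside 18-83 % saturation,
    comfortably away from the 0/100 clamp.

    Attributes
    ----------
    intercept : float
        Saturation (%) at 0 µM (background color development).
    slope : float
        Saturation gain, % per µM.
    pixel_noise_sd : float
        SD of additive Gaussian channel noise on the 0-255 scale.
    image_size : (width, height) in pixels.
    window : (x, y, width, height) of the colored region, 0-based from the
        top-left corner.
    background : RGB triple of the surround.
    """

    intercept: float = 5.0
    slope: float = 0.65
    pixel_noise_sd: float = 2.0
    image_size: tuple[int, int] = (120, 90)
    window: tuple[int, int, int, int] = (30, 25, 60, 40)
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        w, h = self.image_size
        x, y, ww, wh = self.window
        if w < 1 or h < 1:
            raise ValueError("image dimensions must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.intercept < 0:
            raise ValueError("intercept must be >= 0")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        if ww < 1 or wh < 1 or x < 0 or y < 0 or x + ww > w or y + wh > h:
            raise ValueError("window outside image bounds")
        if ww * wh < 0.01 * w * h:
            raise ValueError("window area must be at least 1% of the image area")

    def target_saturation(self, concentration: float) -> float:
        """Noise-free window saturation (%) for a concentration in µM."""
        return float(np.clip(self.intercept + self.slope * concentration, 0.0, 100.0))


@dataclass(frozen=True)
class CohortConfig:
    """Statistical model of a donor cohort.

    Literature sweat-arginine means are 94.8 µM (female) and 54.0 µM
    (male).  The default per-print SDs back out the total print-to-print
    spread from blind-study standard errors (SEM * sqrt(n): 5.1*sqrt(33)
    and 5.3*sqrt(12)).  ``between_fraction`` is the share of that variance
    attributed to donor identity rather than print-to-print noise; it is a
    modelling knob, not an inference from data.
    """

    mu_female: float = 94.8
    mu_male: float = 54.0
    sd_print_female: float = 29.3
    sd_print_male: float = 18.4
    between_fraction: float = 0.7
    prints_per_donor: int = 3
    lifting_efficiency: float = 1.0
    powder_artifact_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_print_female < 0 or self.sd_print_male < 0:
            raise ValueError("per-print SDs must be >= 0")
        if not 0.0 <= self.between_fraction <= 1.0:
            raise ValueError("between_fraction must lie in [0, 1]")
        if not 0.0 < self.lifting_efficiency <= 1.0:
            raise ValueError("lifting_efficiency must lie in (0, 1]")
        if not 0.0 <= self.powder_artifact_fraction < 0.5:
            raise ValueError("powder_artifact_fraction must lie in [0, 0.5)")
        if self.prints_per_donor < 1:
            raise ValueError("prints_per_donor must be >= 1")
        if self.prints_per_donor > len(FINGER_ORDER):
            raise ValueError(f"at most {len(FINGER_ORDER)} prints per donor")

    def mu(self, sex: str) -> float:
        return {"female": self.mu_female, "male": self.mu_male}[_check_sex(sex)]

    def sd(self, sex: str) -> float:
        return {"female": self.sd_print_female, "male": self.sd_print_male}[_check_sex(sex)]


@dataclass(frozen=True)
class SyntheticPrint:
    finger: str
    concentration_true: float  # µM, before any lifting loss
    image: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SyntheticDonor:
    donor_id: str
    sex: str  # ground truth
    prints: tuple[SyntheticPrint, ...]


def _check_sex(sex: str) -> str:
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex label: {sex!r}")
    return sex


def render_detection_window(
    concentration: float,
    model: ForwardModel = ForwardModel(),
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render one detection-window image for a known concentration.

    The noise-free window has mean saturation ``model.target_saturation``
    within the half-percent error of 8-bit rounding; background pixels
    equal ``model.background``.  Deterministic for a fixed integer seed.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    w, h = model.image_size
    x, y, ww, wh = model.window

    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = np.asarray(model.background, dtype=np.float64)

    s = model.target_saturation(concentration) / 100.0
    off = 255.0 * (1.0 - s)
    img[y : y + wh, x : x + ww, 0] = 255.0
    img[y : y + wh, x : x + ww, 1] = off
    img[y : y + wh, x : x + ww, 2] = off

    if model.pixel_noise_sd > 0:
        img += rng.normal(0.0, model.pixel_noise_sd, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def sample_print_concentrations(
    config: CohortConfig,
    sex: str,
    n_donors: int,
    seed: int | np.random.Generator | None = None,
) -> list[list[float]]:
    """Draw per-print arginine concentrations for ``n_donors`` donors.

    Each print value is ``max(0, mu + donor_effect + print_noise)`` with
    ``donor_effect ~ N(0, sd*sqrt(between_fraction))`` shared within a
    donor and ``print_noise ~ N(0, sd*sqrt(1-between_fraction))`` i.i.d.
    per print.  Negative draws are truncated at zero (concentrations are
    physical quantities).
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    mu, sd = config.mu(sex), config.sd(sex)
    rng = np.random.default_rng(seed)
    sd_between = sd * np.sqrt(config.between_fraction)
    sd_within = sd * np.sqrt(1.0 - config.between_fraction)

    out: list[list[float]] = []
    for _ in range(n_donors):
        donor_effect = rng.normal(0.0, sd_between) if sd_between > 0 else 0.0
        noise = (
            rng.normal(0.0, sd_within, size=config.prints_per_donor)
            if sd_within > 0
            else np.zeros(config.prints_per_donor)
        )
        values = np.maximum(0.0, mu + donor_effect + noise)
        out.append([float(v) for v in values])
    return out


def _apply_powder(
    image: np.ndarray,
    model: ForwardModel,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overwrite a fraction of window pixels with near-black speckle."""
    if fraction <= 0:
        return image
    x, y, ww, wh = model.window
    n_window = ww * wh
    n_speckle = int(round(fraction * n_window))
    if n_speckle == 0:
        return image
    flat = rng.choice(n_window, size=n_speckle, replace=False)
    rows, cols = np.divmod(flat, ww)
    out = image.copy()
    out[y + rows, x + cols] = rng.integers(0, 31, size=(n_speckle, 3), dtype=np.uint8)
    return out


def generate_cohort(
    config: CohortConfig,
    n_female: int,
    n_male: int,
    model: ForwardModel = ForwardModel(),
    seed: int | np.random.Generator | None = None,
) -> list[SyntheticDonor]:
    """Simulate a cohort of donors with rendered images per print.

    Concentrations are multiplied by ``config.lifting_efficiency`` before
    rendering (the recorded ``concentration_true`` is the pre-lifting
    value), and ``config.powder_artifact_fraction`` of each window's pixels
    are overwritten with dark speckle.
    """
    if n_female + n_male < 1:
        raise ValueError("need at least one donor")
    if n_female < 0 or n_male < 0:
        raise ValueError("donor counts must be >= 0")
    rng = np.random.default_rng(seed)
    fingers = FINGER_ORDER[: config.prints_per_donor]

    donors: list[SyntheticDonor] = []
    for sex, n in (("female", n_female), ("male", n_male)):
        if n == 0:
            continue
        per_donor = sample_print_concentrations(config, sex, n, rng)
        for i, concentrations in enumerate(per_donor):
            donor_id = f"{sex[0].upper()}{i + 1:03d}"
            prints = []
            for finger, conc in zip(fingers, concentrations):
                img = render_detection_window(
                    conc * config.lifting_efficiency, model, rng
                )
                img = _apply_powder(img, model, config.powder_artifact_fraction, rng)
                prints.append(
                    SyntheticPrint(finger=finger, concentration_true=conc, image=img)
                )
            donors.append(SyntheticDonor(donor_id=donor_id, sex=sex, prints=tuple(prints)))
    return donors


def generate_standard_series(
    model: ForwardModel = ForwardModel(),
    concentrations: Sequence[float] = DEFAULT_STANDARD_CONCENTRATIONS,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[float, np.ndarray]]:
    """Render one image per standard concentration.

    Returns (concentration µM, image) pairs.  At least two distinct
    concentrations are required, otherwise no calibration line exists.
    """
    concs = [float(c) for c in concentrations]
    if len(set(concs)) < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    rng = np.random.default_rng(seed)
    return [(c, render_detection_window(c, model, rng)) for c in concs]


def noise_free(model: ForwardModel) -> ForwardModel:
    """Copy of ``model`` with pixel noise switched off."""
    return replace(model, pixel_noise_sd=0.0)


def write_cohort(
    donors: Iterable[SyntheticDonor],
    out_dir: str | Path,
    image_format: str = "tiff",
) -> Path:
    """Write cohort images and a manifest CSV; return the manifest path.

    Manifest columns: donor_id, sex, finger, concentration_true, image_path
    (paths relative to the manifest's directory).
    """
    out_dir = Path(out_dir)
    ext = {"tiff": ".tif", "tif": ".tif", "png": ".png"}.get(image_format.lower())
    if ext is None:
        raise ValueError(f"unsupported image format: {image_format}")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["donor_id", "sex", "finger", "concentration_true", "image_path"])
        for donor in donors:
            for p in donor.prints:
                rel = f"images/{donor.donor_id}_{p.finger}{ext}"
                write_image(p.image, out_dir / rel)
                writer.writerow(
                    [donor.donor_id, donor.sex, p.finger, f"{p.concentration_true:.4f}", rel]
                )
    return manifest_path
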