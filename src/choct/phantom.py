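"""Synthetic low-contrast phantom ROIs.

This module emulates the statistical structure of a signal-known-exactly /
location-known-exactly low-contrast detection study on CT images: square
regions of interest (ROIs) in Hounsfield units (HU) containing a centred,
anti-aliased disc target on a zero-mean noisy background.  The defaults mirror
a typical phantom protocol: 41x41-pixel ROIs at 0.59 mm/pixel, disc targets of
6 or 8 mm diameter and 10 or 20 HU contrast, 100 signal-present and 1000
signal-absent ROIs per acquisition category.

Noise is either white Gaussian or spectrally shaped ("nps_shaped"), the latter
standing in for the frequency correlation that a reconstruction kernel imparts
to CT noise.  Noise magnitude scales with nominal dose through the quantum
relation sigma ~ 1/sqrt(CTDIvol).

All randomness is counter-based: each ROI draws from its own Philox stream
keyed by the dataset seed and the ROI's class and index, so the draws for a
given ROI never depend on how many other ROIs are generated or in what order.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator

import numpy as np

DEFAULT_ROI_SIDE = 41
DEFAULT_PIXEL_PITCH = 0.59  # mm per pixel

NOISE_KINDS = ("white", "nps_shaped")

# circumradius of a unit pixel: pixels nearer/farther than this from the disc
# edge are fully inside/outside and need no supersampling
_HALF_DIAG = math.sqrt(0.5)
_EDGE_SUPERSAMPLE = 16

_SIGNAL_CLASS = 0
_NOISE_CLASS = 1


@dataclasses.dataclass(frozen=True, eq=False)
class ROIImage:
    """One square ROI of attenuation values in HU.

    The side length must be odd so a centre pixel exists; backgrounds are
    contrast-only (0 HU), since every downstream observer statistic is
    invariant to a constant offset.
    """

    pixels: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"ROI must be square, got shape {arr.shape}")
        if arr.shape[0] % 2 == 0:
            raise ValueError(
                f"ROI side must be odd so a centre pixel exists, got {arr.shape[0]}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("ROI contains non-finite values")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "pixels", arr)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclasses.dataclass(frozen=True)
class Category:
    """One acquisition condition of the factorial study design."""

    dose_mGy: float
    recon_strength: int
    contrast_hu: float
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.dose_mGy <= 0:
            raise ValueError("dose_mGy must be positive")
        if self.contrast_hu < 0:
            raise ValueError("contrast_hu must be non-negative")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")

    def label(self) -> str:
        return (
            f"dose={self.dose_mGy:g}mGy_recon={self.recon_strength}"
            f"_contrast={self.contrast_hu:g}HU_diam={self.diameter_mm:g}mm"
        )


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Surrogate noise description.

    ``white`` draws i.i.d. Gaussian pixels.  ``nps_shaped`` filters a white
    field by the square root of a radial power spectrum proportional to
    rho**nps_exponent * exp(-rho) (rho in cycles/pixel), a generic band-pass
    shape resembling reconstructed CT noise; ``nps_exponent`` is ignored for
    white noise.
    """

    kind: str
    sigma_hu: float
    nps_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}, got {self.kind!r}")
        if self.sigma_hu < 0:
            raise ValueError("sigma_hu must be non-negative")


@dataclasses.dataclass
class ROIDataset:
    """Signal-present and signal-absent ROI stacks for one category.

    ``signal_present`` and ``signal_absent`` are stacks of shape
    (n, side, side); ``truth_profile`` is the noise-free signal.  ``seed`` is
    the master seed the stacks were drawn from (None for data extracted from
    external imagery).
    """

    category: Category
    signal_present: np.ndarray
    signal_absent: np.ndarray
    truth_profile: ROIImage
    seed: int | None
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    noise_model: NoiseModel | None = None

    def __post_init__(self) -> None:
        sp = np.asarray(self.signal_present, dtype=float)
        sa = np.asarray(self.signal_absent, dtype=float)
        for name, stack in (("signal_present", sp), ("signal_absent", sa)):
            if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
                raise ValueError(f"{name} must have shape (n, side, side), got {stack.shape}")
        if sp.shape[1:] != sa.shape[1:]:
            raise ValueError(
                f"signal and noise ROIs disagree in shape: {sp.shape[1:]} vs {sa.shape[1:]}"
            )
        if self.truth_profile.side != sp.shape[1]:
            raise ValueError("truth_profile shape does not match the ROI stacks")
        self.signal_present = sp
        self.signal_absent = sa

    @property
    def roi_side(self) -> int:
        return self.signal_present.shape[1]

    @property
    def n_signal(self) -> int:
        return self.signal_present.shape[0]

    @property
    def n_noise(self) -> int:
        return self.signal_absent.shape[0]

    def iter_signal(self) -> Iterator[ROIImage]:
        for frame in self.signal_present:
            yield ROIImage(frame, self.pixel_pitch)

    def iter_noise(self) -> Iterator[ROIImage]:
        for frame in self.signal_absent:
            yield ROIImage(frame, self.pixel_pitch)


def make_signal_profile(
    diameter_mm: float,
    contrast_hu: float,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    roi_side: int = DEFAULT_ROI_SIDE,
) -> ROIImage:
    """Noise-free, anti-aliased disc target centred in the ROI.

    Interior pixels take the plateau value ``contrast_hu`` and far-field
    pixels 0; pixels straddling the disc edge take fractional values by
    16x16 sub-pixel area sampling, so the profile is exactly linear in
    contrast.

    Raises
    ------
    ValueError
        If the disc does not fit inside the ROI or the side is even.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    if contrast_hu < 0:
        raise ValueError("contrast_hu must be non-negative")
    if roi_side % 2 == 0:
        raise ValueError("roi_side must be odd")
    if diameter_mm / pixel_pitch >= roi_side:
        raise ValueError(
            f"disc of {diameter_mm} mm does not fit a {roi_side}-pixel ROI "
            f"at {pixel_pitch} mm/pixel"
        )

    radius_px = diameter_mm / pixel_pitch / 2.0
    half = roi_side // 2
    coords = np.arange(roi_side, dtype=float) - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    dist = np.hypot(xx, yy)

    coverage = np.zeros((roi_side, roi_side))
    coverage[dist <= radius_px - _HALF_DIAG] = 1.0
    edge = (dist > radius_px - _HALF_DIAG) & (dist < radius_px + _HALF_DIAG)
    if np.any(edge):
        # supersample only the boundary pixels
        ss = (np.arange(_EDGE_SUPERSAMPLE) + 0.5) / _EDGE_SUPERSAMPLE - 0.5
        ex = xx[edge][:, None, None] + ss[None, :, None]
        ey = yy[edge][:, None, None] + ss[None, None, :]
        inside = (ex * ex + ey * ey) <= radius_px * radius_px
        coverage[edge] = inside.mean(axis=(1, 2))

    return ROIImage(contrast_hu * coverage, pixel_pitch)


def _roi_rng(seed: int, roi_class: int, index: int) -> np.random.Generator:
    """Counter-based substream: one Philox stream per (seed, class, index)."""
    bitgen = np.random.Philox(key=int(seed), counter=[0, 0, int(index), int(roi_class)])
    return np.random.Generator(bitgen)


def _nps_filter(model: NoiseModel, roi_side: int) -> np.ndarray:
    """Square-root power-spectrum filter on the DFT grid, normalised so that
    filtering unit-variance white noise yields per-pixel variance sigma_hu**2."""
    freqs = np.fft.fftfreq(roi_side)
    rho = np.hypot(freqs[:, None], freqs[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        power = np.where(rho > 0, rho**model.nps_exponent * np.exp(-rho), 0.0)
    filt = np.sqrt(power)
    norm = np.sqrt(np.mean(filt**2))
    if norm == 0:
        raise ValueError("degenerate NPS filter: all-zero power spectrum")
    return filt * (model.sigma_hu / norm)


def _noise_field(model: NoiseModel, roi_side: int, rng: np.random.Generator) -> np.ndarray:
    if model.sigma_hu == 0:
        return np.zeros((roi_side, roi_side))
    if model.kind == "white":
        return rng.standard_normal((roi_side, roi_side)) * model.sigma_hu
    filt = _nps_filter(model, roi_side)
    white = rng.standard_normal((roi_side, roi_side))
    # filter is real and symmetric on the DFT grid, so the product with the
    # transform of a real field is Hermitian and the inverse transform is real
    return np.fft.ifft2(np.fft.fft2(white) * filt).real


def generate_noise_roi(
    model: NoiseModel,
    roi_side: int = DEFAULT_ROI_SIDE,
    seed: int = 0,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> ROIImage:
    """One zero-mean noise ROI; identical (model, side, seed) gives an
    identical ROI."""
    rng = _roi_rng(seed, _NOISE_CLASS, 0)
    return ROIImage(_noise_field(model, roi_side, rng), pixel_pitch)


def generate_category_dataset(
    category: Category,
    model: NoiseModel,
    n_signal: int = 100,
    n_noise: int = 1000,
    seed: int = 0,
    roi_side: int = DEFAULT_ROI_SIDE,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> ROIDataset:
    """Generate the ROI stacks for one acquisition category.

    Signal-present ROIs are the noise-free disc profile plus an independent
    noise draw; signal-absent ROIs are noise draws.  Defaults follow the
    100-signal / 1000-noise study design.

    Raises
    ------
    ValueError
        If ``n_signal`` < 1 or ``n_noise`` < 4 (a 4-AFC trial needs one
        signal-present and three distinct signal-absent ROIs).
    """
    if n_signal < 1:
        raise ValueError("n_signal must be >= 1: the 4-AFC needs a signal-present ROI")
    if n_noise < 4:
        raise ValueError(
            "n_noise must be >= 4: a 4-AFC trial needs three distinct "
            "signal-absent alternatives drawn without replacement"
        )
    truth = make_signal_profile(category.diameter_mm, category.contrast_hu, pixel_pitch, roi_side)

    signal = np.empty((n_signal, roi_side, roi_side))
    for i in range(n_signal):
        rng = _roi_rng(seed, _SIGNAL_CLASS, i)
        signal[i] = truth.pixels + _noise_field(model, roi_side, rng)

    noise = np.empty((n_noise, roi_side, roi_side))
    for j in range(n_noise):
        rng = _roi_rng(seed, _NOISE_CLASS, j)
        noise[j] = _noise_field(model, roi_side, rng)

    return ROIDataset(
        category=category,
        signal_present=signal,
        signal_absent=noise,
        truth_profile=truth,
        seed=seed,
        pixel_pitch=pixel_pitch,
        noise_model=model,
    )


def dose_to_sigma(
    dose_mGy: float, reference_sigma_hu: float, reference_dose_mGy: float
) -> float:
    """Quantum-noise scaling of image noise with dose:
    sigma = sigma_ref * sqrt(dose_ref / dose)."""
    if dose_mGy <= 0 or reference_sigma_hu <= 0 or reference_dose_mGy <= 0:
        raise ValueError("dose_to_sigma arguments must all be positive")
    return reference_sigma_hu * math.sqrt(reference_dose_mGy / dose_mGy)
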