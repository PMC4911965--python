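"""Dense difference-of-Gaussian (DDoG) frequency channels.

A channelised observer first projects each image onto a small bank of
frequency-selective channels.  The DDoG bank used here is radially symmetric:
channel j has the radial-frequency profile

    U_j(rho) = exp(-0.5 * (rho / (W * sigma_j))**2) - exp(-0.5 * (rho / sigma_j)**2)

with sigma_j = sigma0 * alpha**j (j = 1..n), bandwidth ratio W = 1.67,
sigma0 = 0.005 cycles/pixel and alpha = 1.4 by default, giving 10 log-spaced
band-pass channels.  Frequencies are in cycles/pixel on the DFT grid, so the
bank never depends on the physical pixel pitch.

Each spatial template is the inverse DFT of the sampled radial profile,
centred on the ROI centre pixel; because U_j(0) = 0, every template has
exactly zero mean, which makes all downstream observer statistics invariant
to constant image offsets.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .phantom import DEFAULT_PIXEL_PITCH, ROIImage


@dataclasses.dataclass(frozen=True)
class ChannelParams:
    """Parameters of the DDoG channel bank.

    sigma0 is the base radial-frequency scale in cycles/pixel; channel j uses
    sigma_j = sigma0 * alpha**j with j starting at 1.
    """

    n_channels: int = 10
    bandwidth_W: float = 1.67
    sigma0: float = 0.005
    alpha: float = 1.4

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.bandwidth_W <= 1:
            raise ValueError("bandwidth_W must exceed 1 (wider minus narrower Gaussian)")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")

    def sigma(self, j: int) -> float:
        """Scale of channel j (1-based)."""
        if not 1 <= j <= self.n_channels:
            raise IndexError(f"channel index {j} outside 1..{self.n_channels}")
        return self.sigma0 * self.alpha**j


@dataclasses.dataclass(frozen=True, eq=False)
class ChannelBank:
    """Matrix U of spatial channel templates.

    ``matrix_U`` has one flattened (row-major) spatial template per column,
    shape (roi_side**2, n_channels).
    """

    matrix_U: np.ndarray
    params: ChannelParams
    roi_side: int
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        U = np.asarray(self.matrix_U, dtype=float)
        expected = (self.roi_side**2, self.params.n_channels)
        if U.shape != expected:
            raise ValueError(f"matrix_U must have shape {expected}, got {U.shape}")
        if not np.all(np.isfinite(U)):
            raise ValueError("matrix_U contains non-finite values")
        object.__setattr__(self, "matrix_U", U)

    @property
    def n_channels(self) -> int:
        return self.params.n_channels

    def template_image(self, j: int) -> np.ndarray:
        """Spatial template of channel j (1-based) as a 2-D array."""
        if not 1 <= j <= self.n_channels:
            raise IndexError(f"channel index {j} outside 1..{self.n_channels}")
        return self.matrix_U[:, j - 1].reshape(self.roi_side, self.roi_side)


def ddog_profile(
    rho: float | np.ndarray, j: int, params: ChannelParams | None = None
) -> float | np.ndarray:
    """Radial-frequency response of channel j at frequency rho (cycles/pixel).

    Non-negative for all rho >= 0 when W > 1, and vanishes at rho = 0 and
    as rho -> infinity.
    """
    params = params or ChannelParams()
    sigma_j = params.sigma(j)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    wide = np.exp(-0.5 * (rho / (params.bandwidth_W * sigma_j)) ** 2)
    narrow = np.exp(-0.5 * (rho / sigma_j) ** 2)
    out = wide - narrow
    return float(out) if out.ndim == 0 else out


def _radial_frequency_grid(roi_side: int) -> np.ndarray:
    freqs = np.fft.fftfreq(roi_side)
    return np.hypot(freqs[:, None], freqs[None, :])


def build_channel_bank(
    roi_side: int,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    params: ChannelParams | None = None,
) -> ChannelBank:
    """Sample each channel's radial profile on the DFT grid of a
    roi_side x roi_side transform and inverse-transform it to a real spatial
    template centred on the ROI centre pixel."""
    if roi_side < 3:
        raise ValueError("roi_side must be >= 3")
    params = params or ChannelParams()
    rho = _radial_frequency_grid(roi_side)
    columns = []
    for j in range(1, params.n_channels + 1):
        profile = ddog_profile(rho, j, params)
        spatial = np.fft.ifft2(profile)
        # the sampled profile is conjugate-symmetric, so the imaginary part is
        # pure round-off; realise and centre on the middle pixel
        template = np.fft.fftshift(spatial.real)
        columns.append(template.ravel())
    U = np.column_stack(columns)
    return ChannelBank(matrix_U=U, params=params, roi_side=roi_side, pixel_pitch=pixel_pitch)


def _as_flat_pixels(roi: ROIImage | np.ndarray, bank: ChannelBank) -> np.ndarray:
    pixels = roi.pixels if isinstance(roi, ROIImage) else np.asarray(roi, dtype=float)
    if pixels.shape != (bank.roi_side, bank.roi_side):
        raise ValueError(
            f"ROI shape {pixels.shape} does not match channel bank "
            f"({bank.roi_side}, {bank.roi_side})"
        )
    return pixels.ravel()


def apply_channels(roi: ROIImage | np.ndarray, bank: ChannelBank) -> np.ndarray:
    """Channel outputs U^T g of a single ROI; linear in the image."""
    return bank.matrix_U.T @ _as_flat_pixels(roi, bank)


def channel_outputs(rois: np.ndarray, bank: ChannelBank) -> np.ndarray:
    """Channel outputs for a stack of ROIs, shape (n, n_channels)."""
    stack = np.asarray(rois, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[1:] != (bank.roi_side, bank.roi_side):
        raise ValueError(
            f"ROI stack shape {stack.shape[1:]} does not match channel bank "
            f"({bank.roi_side}, {bank.roi_side})"
        )
    return stack.reshape(stack.shape[0], -1) @ bank.matrix_U
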