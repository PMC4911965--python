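"""Channelised Hotelling observer (CHO).

The CHO is the Hotelling (prewhitened matched-filter) discriminant applied in
channel space: with class means g_cs, g_cn and covariances K_cs, K_cn of the
channel outputs, the template is

    w_CHO = [0.5 * (K_cs + K_cn)]^-1 (g_cs - g_cn)

and an image g is scored by the decision variable lambda = w_CHO^T U^T g.
The companion detectability index is

    d' = sqrt[(g_cs - g_cn)^T (0.5 * (K_cs + K_cn))^-1 (g_cs - g_cn)],

the signal-to-noise ratio of lambda for Gaussian channel outputs with equal
class covariances.

Covariances are estimated directly from the (few-dimensional) channel
outputs, never from image-space pixel covariances; the two routes agree
algebraically because cov(U^T g) = U^T cov(g) U.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import scipy.linalg

from .channels import ChannelBank, apply_channels, channel_outputs
from .phantom import ROIImage

logger = logging.getLogger(__name__)


@dataclasses.dataclass(eq=False)
class CHOTemplate:
    """Trained channel-space template with its training statistics."""

    w_cho: np.ndarray
    mean_signal_c: np.ndarray
    mean_noise_c: np.ndarray
    cov_signal_c: np.ndarray
    cov_noise_c: np.ndarray
    n_train_signal: int
    n_train_noise: int

    def __post_init__(self) -> None:
        n = self.w_cho.shape[0]
        for name in ("mean_signal_c", "mean_noise_c"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        for name in ("cov_signal_c", "cov_noise_c"):
            mat = getattr(self, name)
            if mat.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(mat, mat.T, rtol=1e-8, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.w_cho.shape[0]

    @property
    def mean_covariance(self) -> np.ndarray:
        return 0.5 * (self.cov_signal_c + self.cov_noise_c)


def _coerce_stack(rois, bank: ChannelBank) -> np.ndarray:
    if isinstance(rois, np.ndarray):
        stack = rois
    elif isinstance(rois, ROIImage):
        stack = rois.pixels[None]
    else:
        stack = np.stack([r.pixels if isinstance(r, ROIImage) else np.asarray(r) for r in rois])
    return channel_outputs(stack, bank)


def train_from_channel_outputs(
    gcs: np.ndarray, gcn: np.ndarray, ridge: float = 0.0
) -> CHOTemplate:
    """Estimate the template directly from channel-output samples.

    ``gcs`` / ``gcn`` are (n_samples, n_channels) arrays of signal-present and
    signal-absent channel outputs.  Uses unbiased (n-1) sample covariances and
    a linear solve (no explicit inverse); if the solve reports singularity, a
    ridge of 1e-8 * trace / n_channels is applied once with a logged warning.
    """
    gcs = np.asarray(gcs, dtype=float)
    gcn = np.asarray(gcn, dtype=float)
    if gcs.ndim != 2 or gcn.ndim != 2 or gcs.shape[1] != gcn.shape[1]:
        raise ValueError("channel outputs must be 2-D with matching channel count")
    if gcs.shape[0] < 2 or gcn.shape[0] < 2:
        raise ValueError("need at least 2 ROIs per class to estimate a sample covariance")
    if not (np.all(np.isfinite(gcs)) and np.all(np.isfinite(gcn))):
        raise ValueError("non-finite channel outputs in training data")

    mean_s = gcs.mean(axis=0)
    mean_n = gcn.mean(axis=0)
    cov_s = np.cov(gcs, rowvar=False)
    cov_n = np.cov(gcn, rowvar=False)
    cov_s = np.atleast_2d(cov_s)
    cov_n = np.atleast_2d(cov_n)

    n = gcs.shape[1]
    delta = mean_s - mean_n
    mean_cov = 0.5 * (cov_s + cov_n)
    system = mean_cov + ridge * np.eye(n)
    try:
        # escalate scipy's ill-conditioning warning: a numerically singular
        # system goes through the ridge path instead of returning garbage
        with warnings.catch_warnings():
            warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
            w = scipy.linalg.solve(system, delta, assume_a="sym")
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError("non-finite solution")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, scipy.linalg.LinAlgWarning):
        auto_ridge = 1e-8 * np.trace(mean_cov) / n
        warnings.warn(
            f"mean channel covariance numerically singular; retrying with "
            f"ridge {auto_ridge:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("singular covariance in CHO training; ridge %.3e applied", auto_ridge)
        w = scipy.linalg.solve(system + auto_ridge * np.eye(n), delta, assume_a="sym")

    return CHOTemplate(
        w_cho=w,
        mean_signal_c=mean_s,
        mean_noise_c=mean_n,
        cov_signal_c=cov_s,
        cov_noise_c=cov_n,
        n_train_signal=gcs.shape[0],
        n_train_noise=gcn.shape[0],
    )


def train_template(
    signal_rois, noise_rois, bank: ChannelBank, ridge: float = 0.0
) -> CHOTemplate:
    """Train the CHO from signal-present and signal-absent ROIs.

    Accepts ROI stacks of shape (n, side, side) or sequences of
    :class:`~choct.phantom.ROIImage`.
    """
    gcs = _coerce_stack(signal_rois, bank)
    gcn = _coerce_stack(noise_rois, bank)
    return train_from_channel_outputs(gcs, gcn, ridge=ridge)


def decision_variable(
    roi: ROIImage | np.ndarray, template: CHOTemplate, bank: ChannelBank
) -> float:
    """Scalar decision variable lambda = w_CHO^T (U^T g).

    Adding a constant to every pixel leaves lambda unchanged because the
    channels have zero mean.
    """
    return float(template.w_cho @ apply_channels(roi, bank))


def decision_variables(
    rois: np.ndarray, template: CHOTemplate, bank: ChannelBank
) -> np.ndarray:
    """Decision variables for a stack of ROIs, shape (n,)."""
    return channel_outputs(rois, bank) @ template.w_cho


def detectability_index(template: CHOTemplate) -> float:
    """Hotelling detectability d' of the trained template.

    d' = sqrt[(delta)^T (0.5 (K_cs + K_cn))^-1 (delta)] with
    delta = g_cs - g_cn; requires a positive-definite mean covariance.
    """
    delta = template.mean_signal_c - template.mean_noise_c
    try:
        chol = scipy.linalg.cho_factor(template.mean_covariance)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "mean channel covariance is singular; retrain with a positive ridge"
        ) from exc
    value = float(delta @ scipy.linalg.cho_solve(chol, delta))
    return float(np.sqrt(max(value, 0.0)))
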