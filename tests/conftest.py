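import numpy as np
import pytest
import scipy.linalg
from hypothesis import settings

from choct import (
    Category,
    ChannelParams,
    CHOTemplate,
    NoiseModel,
    ROIDataset,
    build_channel_bank,
    generate_category_dataset,
    make_signal_profile,
)

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

# the default 10-channel bank is tuned to 41x41 ROIs; on tiny 9x9 grids the
# lowest-frequency channels have no support (the lowest nonzero DFT frequency
# is 1/9 cycles/pixel), so small-ROI scenarios use a bank matched to the grid
PARAMS9 = ChannelParams(n_channels=6, sigma0=0.03, alpha=1.4)


@pytest.fixture(scope="session")
def bank41():
    return build_channel_bank(41)


@pytest.fixture(scope="session")
def bank9():
    return build_channel_bank(9, params=PARAMS9)


@pytest.fixture(scope="session")
def easy_dataset():
    """Default-sized easy category: 8 mm / 20 HU disc in 5 HU white noise."""
    category = Category(dose_mGy=15.0, recon_strength=1, contrast_hu=20.0, diameter_mm=8.0)
    model = NoiseModel(kind="white", sigma_hu=5.0)
    return generate_category_dataset(category, model, seed=1)


def gaussian_dprime_dataset(
    dprime: float,
    n_signal: int,
    n_noise: int,
    seed: int,
    roi_side: int = 9,
    sigma: float = 10.0,
    diameter_mm: float = 3.0,
):
    """White-noise dataset plus the analytically exact template at a known d'.

    White Gaussian pixels are exactly Gaussian in channel space, so the
    population statistics are known in closed form: K = sigma^2 U^T U and
    delta = amp * U^T s.  The disc amplitude is scaled so the population
    Hotelling detectability equals ``dprime`` exactly, and the returned
    template is built from the population statistics rather than trained,
    giving a Gaussian decision variable with equal class variances at that d'.
    """
    bank = build_channel_bank(
        roi_side, params=PARAMS9 if roi_side < 21 else ChannelParams()
    )
    profile = make_signal_profile(diameter_mm, 1.0, roi_side=roi_side)
    s = profile.pixels.ravel()
    U = bank.matrix_U
    K = sigma**2 * (U.T @ U)
    delta_unit = U.T @ s
    d_unit = float(np.sqrt(delta_unit @ scipy.linalg.solve(K, delta_unit, assume_a="pos")))
    amp = dprime / d_unit

    category = Category(dose_mGy=1.0, recon_strength=1, contrast_hu=0.0, diameter_mm=diameter_mm)
    base = generate_category_dataset(
        category,
        NoiseModel(kind="white", sigma_hu=sigma),
        n_signal=n_signal,
        n_noise=n_noise,
        seed=seed,
        roi_side=roi_side,
    )
    dataset = ROIDataset(
        category=category,
        signal_present=base.signal_present + amp * profile.pixels,
        signal_absent=base.signal_absent,
        truth_profile=make_signal_profile(diameter_mm, amp, roi_side=roi_side),
        seed=seed,
        pixel_pitch=base.pixel_pitch,
        noise_model=base.noise_model,
    )
    delta = amp * delta_unit
    template = CHOTemplate(
        w_cho=scipy.linalg.solve(K, delta, assume_a="pos"),
        mean_signal_c=delta,
        mean_noise_c=np.zeros_like(delta),
        cov_signal_c=K,
        cov_noise_c=K.copy(),
        n_train_signal=n_signal,
        n_train_noise=n_noise,
    )
    return dataset, template, bank
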