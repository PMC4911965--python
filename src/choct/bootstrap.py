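"""Bootstrap uncertainty of the percent correct, and human-reader summaries.

The model observer's PC is a single number per category; its sampling
variability is estimated by resampling the signal-present ROI collection with
replacement to its original size and re-running a full M-AFC pass against the
fixed signal-absent pool, 150 times by default.  The summary is the mean and
standard deviation of the replicate PCs with a normal-approximation 95 %
confidence interval (mean +/- 1.96 SD), clipped to [0, 100]; a percentile
interval is available as an option.

Human-reader PC tables (one PC per observer and category) are summarised per
category by the across-observer mean and standard error, with a
mean +/- 1.96 SE interval.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .afc import _afc_pass
from .channels import ChannelBank, channel_outputs
from .observer import CHOTemplate, train_from_channel_outputs
from .phantom import ROIDataset


@dataclasses.dataclass(eq=False)
class BootstrapSummary:
    """Bootstrap distribution of PC for one category."""

    n_boot: int
    pc_values: np.ndarray
    pc_mean: float
    pc_sd: float
    ci95_low: float
    ci95_high: float
    seed: int

    def __post_init__(self) -> None:
        if self.pc_values.shape != (self.n_boot,):
            raise ValueError("pc_values length must equal n_boot")
        if not (self.ci95_low <= self.pc_mean <= self.ci95_high):
            raise ValueError("CI must bracket the mean")


def bootstrap_pc(
    template: CHOTemplate,
    bank: ChannelBank,
    dataset: ROIDataset,
    n_boot: int = 150,
    seed: int = 0,
    m_alternatives: int = 4,
    refit_per_replicate: bool = False,
    ci_method: str = "normal",
) -> BootstrapSummary:
    """Bootstrap the M-AFC percent correct.

    Each replicate resamples the signal-present collection with replacement to
    its original size and runs one full M-AFC pass (one trial per resampled
    signal ROI) against the fixed noise pool.  The template is trained once
    and held fixed unless ``refit_per_replicate`` is set, in which case it is
    re-estimated from each replicate's resampled signal outputs and the full
    noise pool.

    ``ci_method`` is "normal" (mean +/- 1.96 SD, clipped to [0, 100]) or
    "percentile" (2.5th / 97.5th percentiles of the replicate PCs).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 for the SD to be defined")
    if ci_method not in ("normal", "percentile"):
        raise ValueError("ci_method must be 'normal' or 'percentile'")

    gcs = channel_outputs(dataset.signal_present, bank)
    gcn = channel_outputs(dataset.signal_absent, bank)
    lam_sig = gcs @ template.w_cho
    lam_noise = gcn @ template.w_cho
    n_signal = dataset.n_signal

    pcs = np.empty(n_boot)
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        resample = rng.integers(0, n_signal, size=n_signal)
        if refit_per_replicate:
            tpl_b = train_from_channel_outputs(gcs[resample], gcn)
            lam_s_b = gcs[resample] @ tpl_b.w_cho
            lam_n_b = gcn @ tpl_b.w_cho
        else:
            lam_s_b = lam_sig[resample]
            lam_n_b = lam_noise
        correct, _, _, _ = _afc_pass(lam_s_b, lam_n_b, m_alternatives, rng)
        pcs[b] = 100.0 * correct.mean()

    mean = float(pcs.mean())
    sd = float(pcs.std(ddof=1))
    if ci_method == "normal":
        low = max(0.0, mean - 1.96 * sd)
        high = min(100.0, mean + 1.96 * sd)
    else:
        low, high = (float(q) for q in np.percentile(pcs, [2.5, 97.5]))
    return BootstrapSummary(
        n_boot=n_boot,
        pc_values=pcs,
        pc_mean=mean,
        pc_sd=sd,
        ci95_low=low,
        ci95_high=high,
        seed=seed,
    )


def summarize_human_pcs(
    per_observer_pcs: pd.DataFrame,
    category_cols: list[str] | None = None,
    observer_col: str = "observer",
    pc_col: str = "pc",
) -> pd.DataFrame:
    """Per-category mean PC of human readers with a 95 % confidence interval.

    ``per_observer_pcs`` holds one row per (observer, category) with the PC in
    ``pc_col``; all columns other than the observer and PC columns are treated
    as category keys unless ``category_cols`` is given.  The interval is
    mean +/- 1.96 * SE with SE = SD / sqrt(n_observers).  Categories with a
    single observer are flagged with NaN SE/CI and a warning.
    """
    df = per_observer_pcs
    for col in (observer_col, pc_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if category_cols is None:
        category_cols = [c for c in df.columns if c not in (observer_col, pc_col)]
    if not category_cols:
        raise ValueError("no category columns to group by")

    rows = []
    for keys, group in df.groupby(category_cols, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n_obs = group[observer_col].nunique()
        mean = float(group[pc_col].mean())
        if n_obs < 2:
            warnings.warn(
                f"single observer for category {dict(zip(category_cols, keys))}; "
                "confidence interval undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            se = np.nan
            low = high = np.nan
        else:
            se = float(group[pc_col].std(ddof=1) / np.sqrt(n_obs))
            low = max(0.0, mean - 1.96 * se)
            high = min(100.0, mean + 1.96 * se)
        rows.append(
            dict(zip(category_cols, keys))
            | {"n_observers": n_obs, "pc_mean": mean, "pc_se": se, "ci95_low": low, "ci95_high": high}
        )
    return pd.DataFrame(rows)
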