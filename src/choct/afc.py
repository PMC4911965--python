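"""M-alternative forced-choice (M-AFC) experiments with a model observer.

Each trial presents one signal-present ROI together with m-1 distinct
signal-absent ROIs in a randomly shuffled order; the observer picks the
alternative with the largest decision variable, and the percentage of correct
picks (PC) is the figure of merit.  Chance performance is 100/m percent.

For Gaussian decision variables with equal class variances the expected PC
has the classical closed form

    PC(d', m) = 100 * Integral phi(x - d') * Phi(x)**(m-1) dx

which :func:`pc_closed_form` evaluates by adaptive quadrature and which the
empirical PC of :func:`run_afc` converges to; this serves as an independent
oracle for the simulation machinery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .channels import ChannelBank
from .observer import CHOTemplate, decision_variables
from .phantom import ROIDataset


@dataclasses.dataclass(eq=False)
class AFCOutcome:
    """Result of one M-AFC experiment."""

    n_trials: int
    n_correct: int
    pc: float
    m_alternatives: int
    trial_log: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError("n_correct must lie in [0, n_trials]")


def _distinct_noise_indices(
    rng: np.random.Generator, n_trials: int, k: int, pool_size: int
) -> np.ndarray:
    """(n_trials, k) noise-pool indices, distinct within each row."""
    if pool_size < k:
        raise ValueError(f"noise pool of {pool_size} cannot supply {k} distinct alternatives")
    idx = rng.integers(0, pool_size, size=(n_trials, k))
    while True:
        ordered = np.sort(idx, axis=1)
        dup_rows = np.nonzero((np.diff(ordered, axis=1) == 0).any(axis=1))[0]
        if dup_rows.size == 0:
            return idx
        idx[dup_rows] = rng.integers(0, pool_size, size=(dup_rows.size, k))


def _afc_pass(
    lam_signal: np.ndarray,
    lam_noise_pool: np.ndarray,
    m: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run one trial per entry of ``lam_signal`` against the noise pool.

    Returns (correct, noise_indices, signal_position, decision_position).
    The presentation order of the m alternatives is shuffled per trial; the
    decision is the position of the largest lambda, ties resolved by the
    lowest presentation index.
    """
    n_trials = lam_signal.size
    k = m - 1
    noise_idx = _distinct_noise_indices(rng, n_trials, k, lam_noise_pool.size)
    lam = np.column_stack([lam_signal, lam_noise_pool[noise_idx]])
    # presentation permutation: position p shows alternative perm[t, p]
    perm = rng.random((n_trials, m)).argsort(axis=1)
    lam_presented = np.take_along_axis(lam, perm, axis=1)
    decision_pos = lam_presented.argmax(axis=1)
    signal_pos = np.argmax(perm == 0, axis=1)
    return decision_pos == signal_pos, noise_idx, signal_pos, decision_pos


def run_afc(
    template: CHOTemplate,
    bank: ChannelBank,
    dataset: ROIDataset,
    m_alternatives: int = 4,
    n_trials: int | None = None,
    seed: int = 0,
) -> AFCOutcome:
    """Seeded M-AFC experiment of the CHO on a dataset.

    Signal-present ROIs are used once per pass in a seeded-shuffled order (the
    default trial count is one pass, i.e. the number of signal ROIs); the m-1
    noise alternatives of each trial are drawn without replacement within the
    trial from the shared signal-absent pool.
    """
    if m_alternatives < 2:
        raise ValueError("m_alternatives must be >= 2")
    if dataset.n_signal < 1 or dataset.n_noise < m_alternatives - 1:
        raise ValueError(
            f"dataset too small for {m_alternatives}-AFC: needs >= 1 signal and "
            f">= {m_alternatives - 1} noise ROIs, has {dataset.n_signal}/{dataset.n_noise}"
        )
    if n_trials is None:
        n_trials = dataset.n_signal
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    lam_sig_pool = decision_variables(dataset.signal_present, template, bank)
    lam_noise_pool = decision_variables(dataset.signal_absent, template, bank)

    rng = np.random.default_rng(seed)
    n_passes = -(-n_trials // dataset.n_signal)
    order = np.concatenate(
        [rng.permutation(dataset.n_signal) for _ in range(n_passes)]
    )[:n_trials]

    correct, noise_idx, signal_pos, decision_pos = _afc_pass(
        lam_sig_pool[order], lam_noise_pool, m_alternatives, rng
    )

    log = pd.DataFrame({"trial": np.arange(n_trials), "signal_index": order})
    for c in range(m_alternatives - 1):
        log[f"noise_index_{c}"] = noise_idx[:, c]
    log["lam_signal"] = lam_sig_pool[order]
    for c in range(m_alternatives - 1):
        log[f"lam_noise_{c}"] = lam_noise_pool[noise_idx[:, c]]
    log["signal_position"] = signal_pos
    log["decision_position"] = decision_pos
    log["correct"] = correct

    n_correct = int(correct.sum())
    return AFCOutcome(
        n_trials=n_trials,
        n_correct=n_correct,
        pc=100.0 * n_correct / n_trials,
        m_alternatives=m_alternatives,
        trial_log=log,
    )


def pc_closed_form(dprime: float, m_alternatives: int) -> float:
    """Expected M-AFC percent correct of a Gaussian decision variable at a
    given detectability d', by adaptive quadrature of
    phi(x - d') Phi(x)**(m-1) over the real line."""
    if dprime < 0:
        raise ValueError("dprime must be non-negative")
    if m_alternatives < 2:
        raise ValueError("m_alternatives must be >= 2")

    def integrand(x: float) -> float:
        return stats.norm.pdf(x - dprime) * stats.norm.cdf(x) ** (m_alternatives - 1)

    value, _ = integrate.quad(integrand, -np.inf, np.inf)
    return 100.0 * value
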