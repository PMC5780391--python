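"""MCMC convergence diagnostics: autocorrelations and effective sample size.

The effective sample size (ESS) is estimated with Geyer's initial
positive sequence: the autocorrelation function is summed over pairs
``(rho_{2m}, rho_{2m+1})`` for as long as the pair sums stay positive,
which for a reversible chain never underestimates the asymptotic
integrated autocorrelation time.  A chain with zero variance has no
defined ESS; it is flagged rather than raised, since a stuck chain is a
diagnostic finding, not a programming error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["autocorrelation", "effective_sample_size", "convergence_diagnostics"]

ESS_METHOD = "initial_positive_sequence"


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelations rho_1..rho_max_lag (FFT-based, biased norm)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        return np.full(max_lag, np.nan)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov[1:] / acov[0]


def effective_sample_size(x: np.ndarray) -> float:
    """Geyer initial-positive-sequence ESS; NaN for a constant chain."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return np.nan
    rho = np.concatenate([[1.0], autocorrelation(x, n - 2)])
    # pair sums Gamma_m = rho_{2m} + rho_{2m+1}; keep while positive
    n_pairs = rho.size // 2
    gamma = rho[: 2 * n_pairs].reshape(n_pairs, 2).sum(axis=1)
    positive = np.nonzero(gamma <= 0)[0]
    cutoff = positive[0] if positive.size else n_pairs
    tau = max(2.0 * gamma[:cutoff].sum() - 1.0, 1.0)
    return float(min(n / tau, n))


def convergence_diagnostics(samples, max_lag: int = 10) -> pd.DataFrame:
    """Per-parameter diagnostics table for a set of posterior draws.

    Accepts a :class:`~voleherit.model.PosteriorSamples` or a DataFrame of
    draws (one column per parameter).  Returns one row per parameter with
    the posterior mean and SD, the ESS (``ess_method`` names the
    estimator), lag-1..``max_lag`` autocorrelations, and a ``constant``
    flag for degenerate chains whose ESS is undefined.
    """
    frame = getattr(samples, "frame", samples)
    if len(frame) < 100:
        raise ValueError("need at least 100 retained draws for diagnostics")
    rows = {}
    for name in frame.columns:
        x = frame[name].to_numpy(dtype=float)
        constant = bool(np.var(x) == 0)
        acf = autocorrelation(x, max_lag)
        rows[name] = {
            "mean": x.mean(),
            "sd": x.std(ddof=1),
            "ess": effective_sample_size(x),
            "ess_method": ESS_METHOD,
            "constant": constant,
            **{f"acf_lag{k}": acf[k - 1] for k in range(1, max_lag + 1)},
        }
    return pd.DataFrame.from_dict(rows, orient="index")
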