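"""The 24-feature representation of a segregant phenotype distribution.

The bimodality model consumes, per cross x condition panel:

* 11 quantiles of the growth ratio (0%, 10%, ..., 100%);
* the means and standard deviations of a two-component normal mixture
  fitted by EM, plus a two-vs-one-component likelihood-ratio statistic;
* Ashman's D mode-separation statistic of the fitted mixture;
* the Kolmogorov-Smirnov statistic and p-value against a normal of
  matched mean and variance;
* the frequencies of tetrads with 0, 1, 2, 3 or 4 spores above the
  panel-wide mean phenotype (2:2 segregation gives all mass on 2).

All computations are deterministic given the data: the EM is initialised
from the 25th/75th percentiles with pooled standard deviations and equal
mixing weights.  Degenerate inputs (constant panels, collapsed variances)
yield flagged sentinel values rather than NaN so that feature vectors are
always finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .simulate import TetradPanel

__all__ = [
    "FEATURE_NAMES",
    "MixtureFit",
    "fit_two_component_mixture",
    "single_normal_loglik",
    "mixture_test_statistic",
    "ashman_d",
    "ks_against_matched_normal",
    "tetrad_segregation_profile",
    "extract_features",
    "feature_matrix",
]

QUANTILE_LEVELS = np.linspace(0.0, 1.0, 11)

#: Canonical feature order; part of the trained-model contract.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"q{int(q * 100)}" for q in QUANTILE_LEVELS]
    + ["mix_mu1", "mix_mu2", "mix_sd1", "mix_sd2", "mix_stat", "ashman_d"]
    + ["ks_stat", "ks_p"]
    + [f"tetrad_freq_{k}" for k in range(5)]
)

EM_TOL = 1e-8
EM_MAX_ITER = 500
#: Variance floor relative to the data variance; prevents component collapse.
EM_VAR_FLOOR = 1e-6
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class MixtureFit:
    """A two-component normal mixture fit, components ordered by mean."""

    mu1: float
    mu2: float
    sd1: float
    sd2: float
    pi1: float
    loglik: float
    converged: bool
    degenerate: bool = False
    n_iter: int = 0

    @property
    def pi2(self) -> float:
        return 1.0 - self.pi1

    def posterior_low(self, x) -> np.ndarray:
        """Posterior probability that ``x`` belongs to the lower component."""
        x = np.asarray(x, dtype=float)
        l1 = np.log(max(self.pi1, 1e-300)) + _norm_logpdf(x, self.mu1, self.sd1)
        l2 = np.log(max(self.pi2, 1e-300)) + _norm_logpdf(x, self.mu2, self.sd2)
        return special.expit(l1 - l2)


def _norm_logpdf(x, mu, sd):
    sd = max(sd, 1e-300)
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI


def _em_batch(V: np.ndarray, trace: list | None = None):
    """Fit 2-component normal mixtures row-wise on ``V`` (n_panels, n_obs).

    Deterministic initialisation: component means at the 25th/75th
    percentiles, both standard deviations at the pooled value, equal mixing
    weights.  Returns a dict of per-row arrays.  If ``trace`` is a list, the
    per-iteration log-likelihood vector of the active rows is appended to it
    (only meaningful for single-row input).
    """
    V = np.asarray(V, dtype=float)
    n, m = V.shape
    var = V.var(axis=1)
    scale = np.sqrt(var)
    # all-equal rows (range exactly zero) are degenerate; a variance test
    # alone is fooled by float round-off in the mean
    degenerate = (np.ptp(V, axis=1) == 0) | ~np.isfinite(var)
    floor_sd = np.sqrt(np.maximum(EM_VAR_FLOOR * var, 1e-300))

    mu = np.quantile(V, [0.25, 0.75], axis=1).T  # (n, 2)
    sd = np.repeat(np.maximum(scale, floor_sd)[:, None], 2, axis=1)
    pi = np.full((n, 2), 0.5)
    loglik = np.full(n, -np.inf)
    n_iter = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)

    active = np.flatnonzero(~degenerate)
    ll_prev = np.full(n, -np.inf)
    for it in range(EM_MAX_ITER):
        if active.size == 0:
            break
        Va = V[active]  # (a, m)
        mua, sda, pia = mu[active], sd[active], pi[active]
        z1 = (Va - mua[:, :1]) / sda[:, :1]
        z2 = (Va - mua[:, 1:]) / sda[:, 1:]
        l1 = -0.5 * z1 * z1 - np.log(sda[:, :1]) + np.log(pia[:, :1])
        l2 = -0.5 * z2 * z2 - np.log(sda[:, 1:]) + np.log(pia[:, 1:])
        tot = np.logaddexp(l1, l2)
        ll = tot.sum(axis=1) - m * _LOG_SQRT_2PI
        r1 = np.exp(l1 - tot)

        s1 = r1.sum(axis=1)
        s2 = m - s1
        s1 = np.maximum(s1, 1e-12)
        s2 = np.maximum(s2, 1e-12)
        m1 = (r1 * Va).sum(axis=1) / s1
        m2 = ((1.0 - r1) * Va).sum(axis=1) / s2
        v1 = (r1 * (Va - m1[:, None]) ** 2).sum(axis=1) / s1
        v2 = ((1.0 - r1) * (Va - m2[:, None]) ** 2).sum(axis=1) / s2
        fl = floor_sd[active]
        mu[active, 0], mu[active, 1] = m1, m2
        sd[active, 0] = np.maximum(np.sqrt(v1), fl)
        sd[active, 1] = np.maximum(np.sqrt(v2), fl)
        pi[active, 0] = s1 / m
        pi[active, 1] = s2 / m

        loglik[active] = ll
        n_iter[active] = it + 1
        if trace is not None and active.size:
            trace.append(float(ll[0]))
        done = np.abs(ll - ll_prev[active]) < EM_TOL
        converged[active[done]] = True
        ll_prev[active] = ll
        active = active[~done]

    # order components by mean
    swap = mu[:, 0] > mu[:, 1]
    mu[swap] = mu[swap][:, ::-1]
    sd[swap] = sd[swap][:, ::-1]
    pi[swap] = pi[swap][:, ::-1]
    converged &= ~degenerate
    return {
        "mu1": mu[:, 0], "mu2": mu[:, 1],
        "sd1": sd[:, 0], "sd2": sd[:, 1],
        "pi1": pi[:, 0], "loglik": loglik,
        "converged": converged, "degenerate": degenerate,
        "n_iter": n_iter,
    }


def _as_values(values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return v


def fit_two_component_mixture(
    values: Sequence[float], trace: list | None = None
) -> MixtureFit:
    """EM fit of a two-component normal mixture, components sorted by mean.

    Constant input yields a flagged degenerate fit (no exception); fewer
    than 8 observations is an error.  ``trace``, if a list, collects the
    log-likelihood after each EM iteration.
    """
    v = _as_values(values)
    if v.size < 8:
        raise ValueError(f"need at least 8 values, got {v.size}")
    r = _em_batch(v[None, :], trace=trace)
    return MixtureFit(
        mu1=float(r["mu1"][0]), mu2=float(r["mu2"][0]),
        sd1=float(r["sd1"][0]), sd2=float(r["sd2"][0]),
        pi1=float(r["pi1"][0]), loglik=float(r["loglik"][0]),
        converged=bool(r["converged"][0]),
        degenerate=bool(r["degenerate"][0]),
        n_iter=int(r["n_iter"][0]),
    )


def single_normal_loglik(values) -> float:
    """Maximised log-likelihood of a single normal (MLE mean and variance)."""
    v = _as_values(values)
    sd = max(v.std(), np.sqrt(1e-300))
    return float(np.sum(_norm_logpdf(v, v.mean(), sd)))


def mixture_test_statistic(values, fit2: MixtureFit | None = None) -> float:
    """Two-vs-one-component likelihood-ratio statistic, clipped at zero.

    Computes ``2 * (ll_mixture - ll_single_normal)`` with the EM variance
    floor guarding against degenerate spikes.  Larger values indicate
    stronger bimodality; a degenerate fit returns 0.
    """
    v = _as_values(values)
    if fit2 is None:
        fit2 = fit_two_component_mixture(v)
    if fit2.degenerate or not np.isfinite(fit2.loglik):
        return 0.0
    return float(max(0.0, 2.0 * (fit2.loglik - single_normal_loglik(v))))


def ashman_d(fit: MixtureFit) -> float:
    """Ashman's D = sqrt(2) |mu1 - mu2| / sqrt(sd1^2 + sd2^2).

    Measures the separation of the two mixture modes; D > 2 indicates a
    clearly bimodal distribution.  Degenerate fits give 0.
    """
    if fit.degenerate:
        return 0.0
    denom = np.sqrt(fit.sd1 ** 2 + fit.sd2 ** 2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(2.0) * abs(fit.mu1 - fit.mu2) / denom)


def _ks_batch(V: np.ndarray):
    """Row-wise two-sided KS test against N(mean(row), var(row)).

    Uses the population variance so the matched normal has exactly the
    sample moments; p-values use the exact one-sample distribution.
    """
    V = np.asarray(V, dtype=float)
    n, m = V.shape
    mean = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, keepdims=True)
    bad = (np.ptp(V, axis=1) == 0) | ~(sd[:, 0] > 0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = np.sort((V - mean) / sd, axis=1)
    cdf = special.ndtr(Z)
    i = np.arange(1, m + 1) / m
    d_plus = (i - cdf).max(axis=1)
    d_minus = (cdf - (np.arange(m) / m)).max(axis=1)
    d = np.maximum(d_plus, d_minus)
    p = stats.kstwo.sf(np.clip(d, 0, 1), m)
    d[bad] = 0.0
    p[bad] = 1.0
    return np.clip(d, 0.0, 1.0), np.clip(p, 0.0, 1.0), bad


def ks_against_matched_normal(values) -> tuple[float, float]:
    """KS statistic and p-value of the data against its moment-matched normal.

    Small statistics / large p-values are the signature of complex traits
    (many small additive effects); bimodal panels deviate strongly.
    Zero-variance input is flagged degenerate and returns (0, 1).
    """
    v = _as_values(values)
    if v.size < 8:
        raise ValueError(f"need at least 8 values, got {v.size}")
    d, p, _ = _ks_batch(v[None, :])
    return float(d[0]), float(p[0])


def tetrad_segregation_profile(panel: TetradPanel | np.ndarray) -> np.ndarray:
    """Frequencies of tetrads with 0-4 spores above the panel mean.

    Spores count as "above" only if strictly greater than the mean of all
    segregants, so a constant panel yields (1, 0, 0, 0, 0).  A noiseless
    monogenic (2:2) panel yields (0, 0, 1, 0, 0).
    """
    values = panel.values if isinstance(panel, TetradPanel) else np.asarray(panel)
    if values.ndim != 2 or values.shape[1] != 4:
        raise ValueError("expected an (n_tetrads, 4) matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("incomplete tetrads: non-finite phenotypes present")
    if np.ptp(values) == 0:
        counts = np.zeros(values.shape[0], dtype=int)  # ties are "not above"
    else:
        counts = (values > values.mean()).sum(axis=1)
    freq = np.bincount(counts, minlength=5) / values.shape[0]
    return freq


def _feature_block(V: np.ndarray) -> np.ndarray:
    """Feature matrix for a (n_panels, n_tetrads*4) block of panel values."""
    n, m = V.shape
    if m % 4:
        raise ValueError("panel values must be a multiple of 4 (full tetrads)")
    out = np.empty((n, len(FEATURE_NAMES)))
    out[:, :11] = np.quantile(V, QUANTILE_LEVELS, axis=1).T

    em = _em_batch(V)
    deg = em["degenerate"]
    out[:, 11] = em["mu1"]
    out[:, 12] = em["mu2"]
    out[:, 13] = np.where(deg, 0.0, em["sd1"])
    out[:, 14] = np.where(deg, 0.0, em["sd2"])

    # two-vs-one LRT
    sd0 = np.maximum(V.std(axis=1), np.sqrt(1e-300))
    ll1 = -m * (np.log(sd0) + _LOG_SQRT_2PI + 0.5)
    lrt = 2.0 * (em["loglik"] - ll1)
    out[:, 15] = np.where(deg, 0.0, np.maximum(lrt, 0.0))

    denom = np.sqrt(em["sd1"] ** 2 + em["sd2"] ** 2)
    denom = np.where(denom > 0, denom, 1.0)
    out[:, 16] = np.where(
        deg, 0.0, np.sqrt(2.0) * np.abs(em["mu1"] - em["mu2"]) / denom
    )

    d, p, _ = _ks_batch(V)
    out[:, 17] = d
    out[:, 18] = p

    tet = V.reshape(n, -1, 4)
    counts = (tet > V.mean(axis=1)[:, None, None]).sum(axis=2)
    counts[np.ptp(V, axis=1) == 0] = 0  # all-equal rows: ties are "not above"
    for k in range(5):
        out[:, 19 + k] = (counts == k).mean(axis=1)
    return out


def extract_features(panel: TetradPanel) -> pd.Series:
    """The 24-feature vector of one panel, indexed by canonical name.

    Deterministic given the panel; degenerate sub-computations produce
    flagged sentinel values (0 for statistics, 1 for p-values) so every
    entry is finite.
    """
    v = panel.segregants
    if not np.all(np.isfinite(v)):
        raise ValueError("panel contains non-finite phenotypes")
    row = _feature_block(v[None, :])[0]
    return pd.Series(row, index=list(FEATURE_NAMES))


def feature_matrix(panels: Sequence[TetradPanel], chunk_size: int = 5_000) -> pd.DataFrame:
    """Feature matrix for many panels (rows follow the input order).

    Batches the EM and KS computations across panels; equivalent to calling
    :func:`extract_features` per panel. Panels must share one tetrad count.
    """
    if not panels:
        return pd.DataFrame(columns=list(FEATURE_NAMES))
    blocks = []
    for start in range(0, len(panels), chunk_size):
        chunk = panels[start : start + chunk_size]
        V = np.stack([p.segregants for p in chunk])
        if not np.all(np.isfinite(V)):
            raise ValueError("panels contain non-finite phenotypes")
        blocks.append(_feature_block(V))
    return pd.DataFrame(np.vstack(blocks), columns=list(FEATURE_NAMES))
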