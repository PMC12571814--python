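"""Measurement stack: spectral band power, phase statistics, lag/correlation
comparison, GLM, ICA, connectivity, and run-level feature extraction.

Band power uses the Welch periodogram (2 s Hann segments, 50% overlap at
fs = 100 Hz) integrated over the band.  Instantaneous phase comes from a
4th-order zero-phase band-pass followed by the analytic-signal angle.  Phase
locking between two phase series is PLV = |⟨e^{iΔφ}⟩|, and angular samples
are summarized by the circular mean direction and circular standard
deviation √(−2 ln R̄).  The GLM is ordinary least squares (statsmodels),
ICA is FastICA (scikit-learn) on standardized signals, and group comparison
mirrors uncorrected one-way ANOVA plus pairwise t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal as sps
from scipy import stats
from sklearn.decomposition import FastICA

__all__ = [
    "BandSpec",
    "ALPHA_BAND",
    "BETA_BAND",
    "GlmResult",
    "CircularSummary",
    "band_power",
    "instantaneous_phase",
    "plv",
    "circular_stats",
    "phase_lag",
    "glm_fit",
    "ica_decompose",
    "correlation_matrix",
    "extract_features",
    "group_compare",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"require 0 < low < high, got ({self.low}, {self.high})")


ALPHA_BAND = BandSpec("alpha", 8.0, 12.0)
BETA_BAND = BandSpec("beta", 13.0, 30.0)


@dataclass
class GlmResult:
    """Ordinary-least-squares fit summary."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    rsquared: float
    resid: np.ndarray
    names: list[str]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            },
            index=self.names,
        )


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean direction (radians in (−π, π]) and circular std."""

    mean_direction: float
    circular_std: float
    resultant_length: float
    undefined_direction: bool = False


def band_power(x: np.ndarray, fs: float, band: BandSpec, nperseg_s: float = 2.0) -> float:
    """Welch power integrated over [band.low, band.high] (a.u.)."""
    x = np.asarray(x, float)
    if fs <= 2 * band.high:
        raise ValueError(f"fs={fs} must exceed twice the band top {band.high} Hz")
    nperseg = int(round(nperseg_s * fs))
    if len(x) < nperseg:
        raise ValueError(f"series of {len(x)} samples is shorter than one {nperseg}-sample segment")
    f, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    mask = (f >= band.low) & (f <= band.high)
    return float(np.trapezoid(pxx[mask], f[mask]))


def _bandpass(x: np.ndarray, fs: float, band: BandSpec, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def instantaneous_phase(x: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    """Band-limited instantaneous phase: zero-phase band-pass, then the angle
    of the analytic signal.  Values lie in (−π, π]."""
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        raise ValueError("phase of a constant signal is undefined")
    return np.angle(sps.hilbert(_bandpass(x, fs, band)))


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase locking value |⟨e^{i(φ_a − φ_b)}⟩| in [0, 1]."""
    phase_a = np.asarray(phase_a, float)
    phase_b = np.asarray(phase_b, float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    if phase_a.size < 2:
        raise ValueError("need at least two samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


def circular_stats(angles: np.ndarray) -> CircularSummary:
    """Circular mean direction and circular standard deviation √(−2 ln R̄)."""
    angles = np.asarray(angles, float)
    if angles.size < 1:
        raise ValueError("need at least one angle")
    z = np.mean(np.exp(1j * angles))
    rbar = float(np.abs(z))
    if rbar < 1e-12:
        return CircularSummary(0.0, float("inf"), rbar, undefined_direction=True)
    cstd = float(np.sqrt(-2.0 * np.log(rbar))) if rbar < 1.0 else 0.0
    return CircularSummary(float(np.angle(z)), cstd, rbar)


def phase_lag(a: np.ndarray, b: np.ndarray, fs: float, max_lag: float = 2.0) -> float:
    """Lag (s) maximizing the normalized cross-correlation of a and b.

    Positive lag means b trails a (b is a delayed copy of a).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("cross-correlation of a constant series is undefined")
    max_shift = int(round(max_lag * fs))
    if max_shift >= len(a) // 2:
        raise ValueError("max_lag must be below half the series duration")
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    full = sps.correlate(bz, az, mode="full") / len(a)
    lags = sps.correlation_lags(len(bz), len(az), mode="full")
    keep = np.abs(lags) <= max_shift
    best = lags[keep][np.argmax(full[keep])]
    return float(best / fs)


def glm_fit(y: np.ndarray, regressors, add_intercept: bool = True, names=None) -> GlmResult:
    """OLS fit of y on the given regressors with per-coefficient t and p."""
    y = np.asarray(y, float)
    X = np.column_stack([np.asarray(r, float) for r in regressors])
    if X.shape[0] <= X.shape[1] + int(add_intercept):
        raise ValueError("more regressors than samples")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
        names = ["const"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T if add_intercept else X.T)
        bad = [
            (names[i + add_intercept], names[j + add_intercept])
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    return GlmResult(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        rsquared=float(fit.rsquared),
        resid=np.asarray(fit.resid),
        names=names,
    )


def ica_decompose(
    signals: np.ndarray, k: int, seed: int = 0, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, bool]:
    """FastICA into k components; returns (components k×time, mixing
    channel×k, converged).

    Signals are standardized per channel first.  Components have unit
    variance, are ordered by the variance they explain in the input, and
    their sign is fixed so each component's largest-magnitude sample is
    positive.
    """
    signals = np.asarray(signals, float)
    n_channels = signals.shape[0]
    if k > n_channels:
        raise ValueError(f"k={k} exceeds channel count {n_channels}")
    std = signals.std(axis=1, keepdims=True)
    if np.any(std == 0):
        raise ValueError("constant channel cannot be standardized")
    X = ((signals - signals.mean(axis=1, keepdims=True)) / std).T  # time × channel
    import warnings

    ica = FastICA(n_components=k, random_state=seed, max_iter=max_iter, whiten="unit-variance")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(X)  # time × k
        converged = not any("did not converge" in str(w.message) for w in caught)
    comps = sources.T
    mixing = ica.mixing_  # channel × k
    explained = (mixing**2).sum(axis=0)
    order = np.argsort(explained)[::-1]
    comps, mixing = comps[order], mixing[:, order]
    flips = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    comps *= flips[:, None]
    mixing *= flips[None, :]
    return comps, mixing, converged


def correlation_matrix(signals: np.ndarray, names=None) -> np.ndarray:
    """Pairwise Pearson correlations of channel × time signals."""
    signals = np.asarray(signals, float)
    std = signals.std(axis=1)
    if np.any(std == 0):
        bad = [int(i) if names is None else names[i] for i in np.flatnonzero(std == 0)]
        raise ValueError(f"constant channel(s): {bad}")
    return np.corrcoef(signals)


def extract_features(
    R: np.ndarray, E: np.ndarray, reference: np.ndarray, fs: float
) -> dict[str, float]:
    """Run-level features: mean_R, std_E, corr_R (Pearson of R vs the
    reference) and phase_lag (s) of R against the reference."""
    R = np.asarray(R, float)
    E = np.asarray(E, float)
    reference = np.asarray(reference, float)
    if not (len(R) == len(E) == len(reference)):
        raise ValueError("series must be aligned")
    if np.ptp(R) == 0 or np.ptp(reference) == 0:
        corr = float("nan")
        lag = 0.0 if np.array_equal(R, reference) else float("nan")
    else:
        corr = float(stats.pearsonr(R, reference).statistic)
        lag = phase_lag(reference, R, fs, max_lag=min(2.0, 0.4 * len(R) / fs))
    return {"mean_R": float(np.mean(R)), "std_E": float(np.std(E)), "corr_R": corr, "phase_lag": lag}


def group_compare(groups) -> dict:
    """One-way ANOVA plus uncorrected pairwise two-sample t-tests.

    Returns {"F", "p", "pairwise": DataFrame(i, j, t, p)}.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in every group")
    F, p = stats.f_oneway(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, pt = stats.ttest_ind(groups[i], groups[j])
            rows.append({"group_a": i, "group_b": j, "t": float(t), "p": float(pt)})
    return {"F": float(F), "p": float(p), "pairwise": pd.DataFrame(rows)}
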