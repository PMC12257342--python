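"""Half-life and component-fraction recovery from ROI count series.

Two fit models, matching how mixed decay curves are analysed in gamma
spectroscopy:

* **mono-exponential** — rate(t) = a exp(-lambda t) + b, reported as the
  *effective half-life* ln2/lambda.  For a multi-component curve this is a
  window-dependent summary, not a physical constant: longer fitting
  windows weight the slower components more and push the effective
  half-life up.
* **fixed mixture** — amplitudes on the exponential basis
  {exp(-lambda_j t)} with half-lives frozen at catalog values, solved as a
  non-negative least-squares problem.  Freezing the decay constants is
  what makes the decomposition well-posed; free multi-exponential fitting
  is notoriously ill-conditioned.

Both models fit *expected counts per interval* (the exact time integral of
the rate over each bin, not the rate at the bin centre), so noiseless
synthetic series are recovered exactly.  Poisson weighting uses
var = counts with a floor of 1 for empty bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model
from scipy.optimize import nnls

from .nuclear_data import Nuclide
from .spectro import CountTimeSeries

__all__ = [
    "DecayFitResult",
    "FitError",
    "fit_monoexponential",
    "fit_fixed_mixture",
    "goodness_of_fit",
    "restrict_window",
]

LN2 = math.log(2.0)


class FitError(RuntimeError):
    """Fit could not be performed or did not converge."""


@dataclass(frozen=True)
class DecayFitResult:
    """Outcome of a decay-curve fit.

    ``fractions`` are shares of the initial activity (mixture model only);
    ``half_life_min`` the effective half-life (mono model only).  The
    fitted expectation ``predicted`` is kept so diagnostics can be
    recomputed against the series.
    """

    model: str  # "mono" | "fixed_mixture"
    half_life_min: float | None = None
    half_life_se: float | None = None
    amplitude_cpm: float | None = None
    fractions: dict = field(default_factory=dict)  # name -> (value, se)
    amplitudes: dict = field(default_factory=dict)  # name -> cpm
    background_cpm: float = 0.0
    background_se: float | None = None
    r_squared: float = float("nan")
    n_points: int = 0
    predicted: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.half_life_min is not None and self.half_life_min <= 0:
            raise FitError("fitted half-life must be > 0")
        if self.fractions:
            total = sum(v for v, _ in self.fractions.values())
            if abs(total - 1.0) > 1e-6:
                raise FitError(f"fractions sum to {total}")

    def fraction_of(self, name: str) -> float:
        return self.fractions[name][0]


def _counts_and_weights(series: CountTimeSeries, weighting: str) -> tuple[np.ndarray, np.ndarray]:
    y = series.counts.astype(float)
    if weighting == "poisson":
        var = np.maximum(y, 1.0)  # empty bins floored at variance 1
    elif weighting == "uniform":
        var = np.ones_like(y)
    else:
        raise FitError(f"unknown weighting {weighting!r}")
    return y, 1.0 / var


def _binned_exp(t: np.ndarray, d: np.ndarray, lam: float) -> np.ndarray:
    """Integral of exp(-lam u) over each bin [t, t+d], in minutes."""
    return (np.exp(-lam * t) - np.exp(-lam * (t + d))) / lam


def fit_monoexponential(
    series: CountTimeSeries,
    weighting: str = "poisson",
    fit_background: bool = True,
) -> DecayFitResult:
    """Weighted mono-exponential fit; reports the effective half-life.

    Expected counts per bin: a * int_bin exp(-lambda u) du + b * width,
    with a, b in counts per minute.  Standard errors come from the
    covariance of the weighted least squares; R-squared is on the weighted
    scale.
    """
    if len(series) < 4:
        raise FitError("need at least 4 points for a mono-exponential fit")
    y, w = _counts_and_weights(series, weighting)
    if y.sum() == 0:
        raise FitError("all-zero series")
    t = series.times_min
    d = series.bin_widths_min

    # initial guesses from a crude log-linear regression on the rates
    rate = np.maximum(series.cpm, 1e-12)
    b0 = float(rate[-max(1, len(series) // 10):].mean()) if fit_background else 0.0
    net = np.maximum(rate - b0, rate.max() * 1e-6)
    slope = np.polyfit(t + 0.5 * d, np.log(net), 1)[0]
    hl0 = LN2 / max(-slope, 1e-6)
    hl0 = min(max(hl0, 1e-3), 1e7)
    a0 = max(float(rate[0]), 1e-9)

    def model_counts(t, half_life, amplitude, background):
        lam = LN2 / half_life
        return amplitude * _binned_exp(t, d, lam) + background * d

    m = Model(model_counts, independent_vars=["t"])
    params = m.make_params(half_life=hl0, amplitude=a0, background=b0)
    params["half_life"].set(min=1e-6)
    params["amplitude"].set(min=0.0)
    params["background"].set(min=0.0, vary=fit_background)

    fit = m.fit(y, params, t=t, weights=np.sqrt(w))
    hl = fit.params["half_life"]
    if not np.isfinite(hl.value) or hl.value <= 0:
        raise FitError(f"non-finite optimum; lmfit message: {fit.message}")
    predicted = fit.best_fit
    return DecayFitResult(
        model="mono",
        half_life_min=float(hl.value),
        half_life_se=float(hl.stderr) if hl.stderr is not None else None,
        amplitude_cpm=float(fit.params["amplitude"].value),
        background_cpm=float(fit.params["background"].value),
        background_se=(
            float(fit.params["background"].stderr)
            if fit_background and fit.params["background"].stderr is not None
            else None
        ),
        r_squared=_weighted_r2(y, predicted, w),
        n_points=len(series),
        predicted=predicted,
        weights=w,
    )


def fit_fixed_mixture(
    series: CountTimeSeries,
    candidates: list[Nuclide],
    allow_background: bool = True,
    weighting: str = "poisson",
) -> DecayFitResult:
    """Decompose a count series onto exponentials with frozen half-lives.

    Solves non-negative least squares for the amplitudes a_j of
    sum_j a_j exp(-lambda_j t) (+ constant background), with the lambda_j
    fixed at the candidates' catalog values.  Fractions are the normalized
    amplitudes.  Exact on noiseless data generated from any sub-mixture of
    the candidates.
    """
    if not candidates:
        raise FitError("no candidate nuclides")
    if len(series) < len(candidates) + 2:
        raise FitError(f"need at least {len(candidates) + 2} points for {len(candidates)} candidates")
    hls = [n.half_life_min for n in candidates]
    for i in range(len(hls)):
        for j in range(i + 1, len(hls)):
            if abs(hls[i] - hls[j]) / max(hls[i], hls[j]) < 1e-3:
                raise FitError(
                    f"degenerate basis: {candidates[i].name} and {candidates[j].name} "
                    "half-lives within 0.1%"
                )
    y, w = _counts_and_weights(series, weighting)
    if y.sum() == 0:
        raise FitError("all-zero series")
    t = series.times_min
    d = series.bin_widths_min

    cols = [_binned_exp(t, d, n.decay_constant_per_min) for n in candidates]
    if allow_background:
        cols.append(d.astype(float))
    a_mat = np.column_stack(cols)
    sw = np.sqrt(w)
    amps, _ = nnls(a_mat * sw[:, None], y * sw)

    n_cand = len(candidates)
    cand_amps = amps[:n_cand]
    total_amp = cand_amps.sum()
    if total_amp <= 0:
        raise FitError("all amplitudes zero: series carries no decaying signal")
    predicted = a_mat @ amps

    # covariance of the unconstrained weighted LS at the NNLS solution
    try:
        cov = np.linalg.pinv((a_mat * w[:, None]).T @ a_mat)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((amps.size, amps.size), np.nan)
    # delta method for fractions p_j = a_j / sum(a)
    grad = (np.eye(n_cand) * total_amp - cand_amps[:, None]) / total_amp**2
    frac_cov = grad @ cov[:n_cand, :n_cand] @ grad.T
    frac_se = np.sqrt(np.clip(np.diag(frac_cov), 0.0, None))

    fractions = {
        n.name: (float(cand_amps[j] / total_amp), float(frac_se[j]))
        for j, n in enumerate(candidates)
    }
    amplitudes = {n.name: float(cand_amps[j]) for j, n in enumerate(candidates)}
    bg = float(amps[n_cand]) if allow_background else 0.0
    bg_se = float(np.sqrt(max(cov[n_cand, n_cand], 0.0))) if allow_background else None
    return DecayFitResult(
        model="fixed_mixture",
        fractions=fractions,
        amplitudes=amplitudes,
        background_cpm=bg,
        background_se=bg_se,
        r_squared=_weighted_r2(y, predicted, w),
        n_points=len(series),
        predicted=predicted,
        weights=w,
    )


def _weighted_r2(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    ybar = np.average(y, weights=w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot == 0:
        return float("nan")
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class FitDiagnostics:
    r_squared: float
    standardized_residuals: np.ndarray


def goodness_of_fit(series: CountTimeSeries, fit: DecayFitResult) -> FitDiagnostics:
    """Weighted R-squared and standardized residuals for a fitted series.

    R^2 = 1 - SS_res/SS_tot on the weighted scale; residuals are
    (y - yhat) * sqrt(w), unit-variance under the fitted model.
    """
    if fit.predicted is None or fit.weights is None:
        raise FitError("fit result carries no prediction for this series")
    y = series.counts.astype(float)
    if y.size != fit.predicted.size:
        raise FitError("fit result does not match this series")
    w = fit.weights
    ybar = np.average(y, weights=w)
    if np.allclose(y, ybar):
        raise FitError("zero-variance series: R-squared undefined")
    resid = (y - fit.predicted) * np.sqrt(w)
    return FitDiagnostics(_weighted_r2(y, fit.predicted, w), resid)


def restrict_window(series: CountTimeSeries, t_max_min: float) -> CountTimeSeries:
    """Sub-series with interval start times strictly below ``t_max_min``."""
    mask = series.times_min < t_max_min
    if mask.sum() < 2:
        raise FitError("window leaves fewer than 2 points")
    return CountTimeSeries(
        series.times_min[mask], series.counts[mask], series.live_times_s[mask], series.roi_kev
    )
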