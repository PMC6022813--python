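"""Fitting-anomaly detection via sparse Gaussian-process regression.

A working hearing aid should engage its directional microphone mode more,
the louder its surroundings: mean input SPL (dB) and fraction of time in
directional mode are strongly coupled.  The analysis models mean input SPL
``y`` as a function of fraction-of-time-directional ``x`` in [0, 1] with a
Gaussian-process regression, then scores every snapshot by

    z = (v - mu(x)) / sigma(x)

where ``mu`` and ``sigma`` are the model's *predictive* mean and standard
deviation (observation noise included, since observed values are scored).
Snapshots outside the central 0.1%--99.9% band of the predictive
distribution, i.e. ``|z| > Phi^-1(0.999) ~ 3.09``, are flagged as possible
fitting or device anomalies.  Under the model, such points arise at a rate
of 0.2%; |z| > 5 has two-sided normal tail probability below one in a
million, so a visible population out there indicates genuinely abnormal
fittings rather than chance.

To scale past tens of thousands of snapshots, the GP is a *sparse*
variational regression (collapsed Titsias bound) with 100 inducing points
and a kernel summing linear, squared-exponential and bias (offset)
components.  The bound, its prediction equations and the numerically stable
Cholesky formulation follow the standard sparse-GP literature; kernel and
noise hyperparameters are optimized by L-BFGS-B on the negative bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.stats import norm

from .datalog_model import Dataset, DegenerateDataError, SPL_BIN_REPRESENTATIVES, SPL_COLUMNS

__all__ = [
    "Z_BAND_999",
    "GPAnomalyModel",
    "ZScoreResult",
    "mean_input_spl",
    "mean_input_spl_frame",
    "fit_gp",
    "zscores",
    "zscore_histogram",
    "simulate_from_model",
]

#: Phi^-1(0.999): the z magnitude delimiting the 0.1%-99.9% predictive band.
Z_BAND_999: float = float(norm.ppf(0.999))


# ---------------------------------------------------------------------------
# Mean input SPL from the stored histogram
# ---------------------------------------------------------------------------


def mean_input_spl(hist) -> float:
    """Proportion-weighted mean input level (dB SPL) of a 12-bin histogram.

    Bin representatives are 37.5, 42.5, ..., 87.5, 92.5 dB; the weighted
    mean is renormalized by the proportion sum, which must be at least 0.9
    (primary cleaning guarantees this).
    """
    p = hist.values if hasattr(hist, "values") else np.asarray(hist, dtype=float)
    s = p.sum()
    if not s >= 0.9:
        raise ValueError(f"histogram proportion sum {s:.3f} < 0.9; clean the data first")
    return float((p @ SPL_BIN_REPRESENTATIVES) / s)


def mean_input_spl_frame(frame) -> np.ndarray:
    """Vectorized :func:`mean_input_spl` over a dataset frame."""
    p = frame[list(SPL_COLUMNS)].to_numpy(dtype=float)
    s = p.sum(axis=1)
    if not (s >= 0.9).all():
        raise ValueError("some histogram proportion sums < 0.9; clean the data first")
    return (p @ SPL_BIN_REPRESENTATIVES) / s


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


def _kernel(xa: np.ndarray, xb: np.ndarray, p: dict) -> np.ndarray:
    """linear + squared-exponential + bias kernel on 1-D inputs."""
    xa = xa[:, None]
    xb = xb[None, :]
    d2 = (xa - xb) ** 2
    return (
        p["lin_var"] * (xa * xb)
        + p["rbf_var"] * np.exp(-0.5 * d2 / p["lengthscale"] ** 2)
        + p["bias_var"]
    )


def _kernel_diag(x: np.ndarray, p: dict) -> np.ndarray:
    return p["lin_var"] * x**2 + p["rbf_var"] + p["bias_var"]


_PARAM_NAMES = ("lin_var", "rbf_var", "lengthscale", "bias_var", "noise_var")


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class GPAnomalyModel:
    """A fitted sparse GP regression of mean input SPL on directionality.

    Holds the inducing inputs, optimized hyperparameters (all strictly
    positive), the training-data offset, cached Cholesky factors for
    prediction, and a training summary.
    """

    inducing_points: np.ndarray
    params: dict
    y_offset: float
    elbo: float
    n_iterations: int
    n_training: int
    _L: np.ndarray = field(repr=False, default=None)
    _LB: np.ndarray = field(repr=False, default=None)
    _c: np.ndarray = field(repr=False, default=None)

    def predict(self, x_new: np.ndarray, include_noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and standard deviation at ``x_new``.

        With ``include_noise`` (default) the variance includes the
        observation-noise term, i.e. the distribution of an observed value
        rather than of the latent function.
        """
        x_new = np.asarray(x_new, dtype=float)
        p = self.params
        Kus = _kernel(self.inducing_points, x_new, p)
        tmp1 = solve_triangular(self._L, Kus, lower=True)
        tmp2 = solve_triangular(self._LB, tmp1, lower=True)
        mean = tmp2.T @ self._c + self.y_offset
        var = _kernel_diag(x_new, p) - (tmp1**2).sum(axis=0) + (tmp2**2).sum(axis=0)
        var = np.maximum(var, 1e-12)
        if include_noise:
            var = var + p["noise_var"]
        return mean, np.sqrt(var)


def _choose_inducing(x: np.ndarray, m: int) -> np.ndarray:
    """Equally spaced quantiles of x, deduplicated, within the observed range."""
    q = np.quantile(x, (np.arange(m) + 0.5) / m)
    z = np.unique(np.round(q, 8))
    if len(z) < m:
        extra = np.linspace(x.min(), x.max(), m)
        z = np.unique(np.round(np.concatenate([z, extra]), 8))[:m]
    return z


def _elbo_and_cache(x, y, Z, p):
    """Collapsed variational bound; returns (bound, L, LB, c)."""
    n = len(y)
    sigma2 = p["noise_var"]
    Kuu = _kernel(Z, Z, p)
    jitter = 1e-8 * np.mean(np.diag(Kuu)) + 1e-12
    L = cholesky(Kuu + jitter * np.eye(len(Z)), lower=True)
    Kuf = _kernel(Z, x, p)
    A = solve_triangular(L, Kuf, lower=True) / np.sqrt(sigma2)
    AAT = A @ A.T
    LB = cholesky(np.eye(len(Z)) + AAT, lower=True)
    Aerr = A @ y
    c = solve_triangular(LB, Aerr, lower=True) / np.sqrt(sigma2)
    bound = (
        -0.5 * n * np.log(2 * np.pi)
        - np.log(np.diag(LB)).sum()
        - 0.5 * n * np.log(sigma2)
        - 0.5 * (y @ y) / sigma2
        + 0.5 * (c @ c)
        - 0.5 * _kernel_diag(x, p).sum() / sigma2
        + 0.5 * np.trace(AAT)
    )
    return bound, L, LB, c


def fit_gp(
    x: np.ndarray,
    y: np.ndarray,
    m: int = 100,
    seed: int = 0,
    max_iter: int = 100,
) -> GPAnomalyModel:
    """Fit the sparse GP by maximizing the collapsed variational bound.

    Inducing inputs sit at equally spaced quantiles of ``x``; the five
    hyperparameters (linear/RBF/bias variances, RBF lengthscale, noise
    variance) are optimized in log space with L-BFGS-B.  Deterministic given
    the data (``seed`` is recorded for provenance; the optimizer itself is
    deterministic).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < m:
        raise ValueError(f"need at least m={m} training points, got {len(x)}")
    y_std = float(np.std(y))
    if y_std == 0:
        raise DegenerateDataError("y has zero variance; nothing to model")

    y_offset = float(np.mean(y))
    yc = y - y_offset
    Z = _choose_inducing(x, m)
    var0 = float(np.var(yc))
    theta0 = np.log([0.5 * var0, 0.5 * var0, 0.2, 0.1 * var0 + 1e-6, 0.1 * var0])
    bounds = [(-15.0, 15.0)] * 5
    bounds[2] = (np.log(0.01), np.log(10.0))

    def unpack(theta):
        return dict(zip(_PARAM_NAMES, np.exp(theta)))

    def neg_bound(theta):
        try:
            bound, *_ = _elbo_and_cache(x, yc, Z, unpack(theta))
        except np.linalg.LinAlgError:
            return 1e12
        return -bound

    res = minimize(
        neg_bound,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-9},
    )
    params = unpack(res.x)
    bound, L, LB, c = _elbo_and_cache(x, yc, Z, params)
    return GPAnomalyModel(
        inducing_points=Z,
        params=params,
        y_offset=y_offset,
        elbo=float(bound),
        n_iterations=int(res.nit),
        n_training=len(x),
        _L=L,
        _LB=LB,
        _c=c,
    )


# ---------------------------------------------------------------------------
# z-scores and flagging
# ---------------------------------------------------------------------------


@dataclass
class ZScoreResult:
    """Per-snapshot z-scores against the fitted predictive distribution."""

    x: np.ndarray
    value: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    z: np.ndarray
    flagged: np.ndarray
    z_band: float

    def __len__(self) -> int:
        return len(self.z)

    @property
    def flag_rate(self) -> float:
        return float(self.flagged.mean())


def zscores(
    model: GPAnomalyModel,
    dataset: Dataset | None = None,
    x: np.ndarray | None = None,
    value: np.ndarray | None = None,
    use_logged_mean_spl: bool = False,
    z_band: float = Z_BAND_999,
    exclude_zero_directionality: bool = False,
) -> ZScoreResult:
    """Score snapshots as ``z = (v - mu)/sigma`` under the predictive model.

    Either pass a ``dataset`` (x = fraction_directional; v = mean input SPL
    derived from the stored histogram, or the logged field when
    ``use_logged_mean_spl``), or raw ``x``/``value`` arrays.  A snapshot is
    flagged iff ``|z| > z_band`` (default the 0.1%--99.9% band).  Zero-
    directionality snapshots are retained unless excluded explicitly.
    """
    if dataset is not None:
        f = dataset.frame
        x = f["fraction_directional"].to_numpy(dtype=float)
        if use_logged_mean_spl:
            value = f["mean_input_spl"].to_numpy(dtype=float)
        else:
            value = mean_input_spl_frame(f)
        if exclude_zero_directionality:
            keep = x > 0
            x, value = x[keep], value[keep]
    if x is None or value is None:
        raise ValueError("pass either a dataset or x and value arrays")
    x = np.asarray(x, dtype=float)
    value = np.asarray(value, dtype=float)
    mu, sd = model.predict(x, include_noise=True)
    z = (value - mu) / sd
    return ZScoreResult(
        x=x, value=value, mu=mu, sd=sd, z=z, flagged=np.abs(z) > z_band, z_band=z_band
    )


def zscore_histogram(
    result: ZScoreResult, clip: float = 10.0, bins: int = 81
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of z-scores with end bins absorbing values beyond ``+-clip``.

    Returns ``(counts, edges)``; counts sum to the number of snapshots.
    """
    if len(result) == 0:
        raise ValueError("empty z-score result")
    z = np.clip(result.z, -clip, clip)
    counts, edges = np.histogram(z, bins=bins, range=(-clip, clip))
    return counts, edges


def simulate_from_model(
    model: GPAnomalyModel, x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw observations from the fitted predictive distribution at ``x``.

    Used for self-calibration checks: z-scores of such draws are standard
    normal by construction, so the expected flag rate equals the band mass.
    """
    mu, sd = model.predict(np.asarray(x, dtype=float), include_noise=True)
    return mu + sd * rng.standard_normal(len(mu))
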