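"""Temperature-compensated Stern-Volmer calibration.

The phosphorescence lifetime of an oxygen-quenched porphyrin follows

    tau(pO2, T) = tau0 / (1 + (k0 + kT*(T - TC)) * pO2) + f

where ``tau0`` is the unquenched lifetime, ``k0`` the quenching constant at
the calibration room temperature ``TC``, ``kT`` its linear temperature
coefficient, and ``f`` a lifetime-scale offset from non-oxygen-dependent
background phosphorescence.  Oxygen tension is recovered from a measured
lifetime by the closed-form inverse

    pO2 = (tau0/(tau - f) - 1) / (k0 + kT*(T - TC)).

``SternVolmerCalibration`` is the model object (built from arrays or a
DataFrame); ``fit()`` returns a ``SternVolmerResults`` carrying the
estimates, their covariance, confidence intervals, prediction intervals and
a ``summary()`` table.  Thin module-level functions (``fit_stern_volmer_1d``,
``predict_lifetime``, ``invert_pO2``, ...) expose the same operations
functionally.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SternVolmerModel",
    "CalibrationPoint",
    "AgreementStats",
    "ScheduleStep",
    "SternVolmerCalibration",
    "SternVolmerResults",
    "InvalidRegimeError",
    "make_schedule",
    "fit_stern_volmer_1d",
    "fit_stern_volmer_2d",
    "predict_lifetime",
    "invert_pO2",
    "prediction_interval",
    "bland_altman",
    "relative_error_profile",
    "DWELL_S",
    "REFERENCE_CADENCE_S",
]

DWELL_S = 300.0  # chamber equilibration dwell per setpoint (5 min)
REFERENCE_CADENCE_S = 3.0  # reference oximeter sampling interval


class InvalidRegimeError(ValueError):
    """Effective quenching constant is non-positive: the model is outside
    the physically meaningful quenching regime at this temperature."""


@dataclass(frozen=True)
class SternVolmerModel:
    """Parameters of the temperature-compensated Stern-Volmer relation.

    Attributes
    ----------
    tau0_s : float
        Unquenched (zero-oxygen) lifetime, seconds.
    k0_per_mmHg : float
        Quenching constant at the calibration temperature, 1/mmHg.
    kT_per_mmHg_c : float
        Temperature coefficient of the quenching constant, 1/(mmHg*degC).
    f_s : float
        Non-oxygen-dependent background lifetime offset, seconds.
    tc_c : float
        Calibration room temperature, degC.
    """

    tau0_s: float
    k0_per_mmHg: float
    kT_per_mmHg_c: float = 0.0
    f_s: float = 0.0
    tc_c: float = 24.0

    def __post_init__(self) -> None:
        if not self.tau0_s > 0:
            raise ValueError("tau0_s must be positive")
        if not self.k0_per_mmHg > 0:
            raise ValueError("k0_per_mmHg must be positive")
        if self.f_s < 0:
            raise ValueError("f_s must be >= 0")

    def quench_constant(self, temp_c: float):
        """Effective quenching constant K(T) = k0 + kT*(T - TC), 1/mmHg."""
        return self.k0_per_mmHg + self.kT_per_mmHg_c * (np.asarray(temp_c, float) - self.tc_c)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SternVolmerModel":
        return cls(**{k: d[k] for k in ("tau0_s", "k0_per_mmHg", "kT_per_mmHg_c", "f_s", "tc_c")})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SternVolmerModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration reading: reference pO2, measured lifetime, temperature."""

    pO2_mmHg: float
    lifetime_s: float
    temp_c: float
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        if self.pO2_mmHg < 0:
            raise ValueError("pO2_mmHg must be >= 0")
        if not self.lifetime_s > 0:
            raise ValueError("lifetime_s must be positive")


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between two pO2 measurement methods (mmHg)."""

    bias: float
    loa_low: float
    loa_high: float
    n: int
    sd_diff: float = 0.0


@dataclass(frozen=True)
class ScheduleStep:
    """One gas-mixer setpoint with its dwell and reference-sampling cadence."""

    pO2_mmHg: float
    dwell_s: float = DWELL_S
    cadence_s: float = REFERENCE_CADENCE_S


# ---------------------------------------------------------------------------
# forward model / inverse


def predict_lifetime(model: SternVolmerModel, pO2_mmHg, temp_c):
    """Evaluate tau = tau0/(1 + K(T)*pO2) + f.  Vectorized in pO2/temp."""
    K = model.quench_constant(temp_c)
    if np.any(K <= 0):
        raise InvalidRegimeError(
            f"effective quenching constant {np.min(K):.3g}/mmHg is not positive"
        )
    p = np.asarray(pO2_mmHg, float)
    out = model.tau0_s / (1.0 + K * p) + model.f_s
    return float(out) if np.isscalar(pO2_mmHg) and np.isscalar(temp_c) else out


def invert_pO2(model: SternVolmerModel, lifetime_s: float, temp_c: float) -> Tuple[float, str]:
    """Closed-form inverse pO2 = (tau0/(tau - f) - 1)/K with feasibility flag.

    Returns ``(pO2, flag)`` where flag is ``"ok"``, ``"clamped"`` (a small
    negative inverse from measurement noise was clamped to 0) or
    ``"infeasible"`` (tau <= f: below the background lifetime, no oxygen
    tension can produce it; the numeric slot is NaN).
    """
    K = float(model.quench_constant(temp_c))
    if K <= 0:
        raise InvalidRegimeError(f"effective quenching constant {K:.3g}/mmHg is not positive")
    if lifetime_s <= model.f_s:
        return math.nan, "infeasible"
    p = (model.tau0_s / (lifetime_s - model.f_s) - 1.0) / K
    if p < 0:
        return 0.0, "clamped"
    return p, "ok"


# ---------------------------------------------------------------------------
# model / results objects


def _as_frame(points) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of CalibrationPoint."""
    if isinstance(points, pd.DataFrame):
        df = points.copy()
        if "pO2_ref_mmHg" in df.columns and "pO2_mmHg" not in df.columns:
            df = df.rename(columns={"pO2_ref_mmHg": "pO2_mmHg"})
        missing = {"pO2_mmHg", "lifetime_s"} - set(df.columns)
        if missing:
            raise ValueError(f"calibration data missing columns: {sorted(missing)}")
        if "temp_c" not in df.columns:
            df["temp_c"] = np.nan
        return df
    pts = list(points)
    return pd.DataFrame(
        {
            "pO2_mmHg": [p.pO2_mmHg for p in pts],
            "lifetime_s": [p.lifetime_s for p in pts],
            "temp_c": [p.temp_c for p in pts],
            "timestamp_s": [p.timestamp_s for p in pts],
        }
    )


class SternVolmerCalibration:
    """Stern-Volmer calibration model for a set of benchtop readings.

    Parameters
    ----------
    lifetime_s, pO2_mmHg : array-like
        Measured lifetimes (seconds) and reference oxygen tensions (mmHg).
    temp_c : array-like, optional
        Chamber temperature per reading; required for the
        temperature-compensated (2-D) fit.
    tc_c : float, optional
        Calibration room temperature TC at which the temperature term
        vanishes.  Defaults to the minimum observed temperature, the usual
        room-temperature leg of the protocol.
    """

    PARAM_NAMES_1D = ("tau0_s", "k0_per_mmHg", "f_s")
    PARAM_NAMES_2D = ("tau0_s", "k0_per_mmHg", "kT_per_mmHg_c", "f_s")

    def __init__(self, lifetime_s, pO2_mmHg, temp_c=None, tc_c: Optional[float] = None):
        self.lifetime_s = np.asarray(lifetime_s, float)
        self.pO2_mmHg = np.asarray(pO2_mmHg, float)
        if self.lifetime_s.shape != self.pO2_mmHg.shape or self.lifetime_s.ndim != 1:
            raise ValueError("lifetime_s and pO2_mmHg must be equal-length 1-D arrays")
        if np.any(self.lifetime_s <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(self.pO2_mmHg < 0):
            raise ValueError("pO2 must be >= 0")
        if temp_c is None:
            self.temp_c = None
        else:
            self.temp_c = np.broadcast_to(np.asarray(temp_c, float), self.lifetime_s.shape).copy()
        if tc_c is not None:
            self.tc_c = float(tc_c)
        elif self.temp_c is not None and np.isfinite(self.temp_c).all():
            self.tc_c = float(np.min(self.temp_c))
        else:
            self.tc_c = 24.0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, tc_c: Optional[float] = None) -> "SternVolmerCalibration":
        """Build from a calibration table with columns
        ``lifetime_s``, ``pO2_mmHg`` (or ``pO2_ref_mmHg``) and optionally
        ``temp_c``."""
        frame = _as_frame(df)
        temp = frame["temp_c"].to_numpy() if frame["temp_c"].notna().all() else None
        return cls(frame["lifetime_s"].to_numpy(), frame["pO2_mmHg"].to_numpy(), temp, tc_c=tc_c)

    @classmethod
    def from_points(cls, points: Iterable[CalibrationPoint], tc_c: Optional[float] = None):
        return cls.from_dataframe(_as_frame(points), tc_c=tc_c)

    # -- internals ---------------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.lifetime_s.size

    def n_distinct_temps(self) -> int:
        if self.temp_c is None:
            return 1
        return np.unique(self.temp_c).size

    def _check_spread(self, min_points: int) -> None:
        if self.nobs < min_points:
            raise ValueError(f"need at least {min_points} points, got {self.nobs}")
        if np.unique(self.pO2_mmHg).size < 3:
            raise ValueError(
                "degenerate pO2 spread: need readings at >= 3 distinct oxygen tensions"
            )

    def _initial_guess(self, temperature_compensated: bool) -> np.ndarray:
        """Deterministic data-driven start values.

        f from the smallest lifetime at the highest pO2 (most-quenched
        reading), tau0 from the zero-/lowest-oxygen lifetime minus f, k0
        from an ordinary linear Stern-Volmer fit of tau0/(tau - f) - 1
        against pO2, kT = 0.
        """
        p, tau = self.pO2_mmHg, self.lifetime_s
        f0 = float(np.min(tau[p == p.max()]))
        # keep the start strictly below every lifetime so the linear fit is finite
        f0 = min(f0, float(np.min(tau))) * 0.9
        tau0_0 = max(float(np.mean(tau[p == p.min()])) - f0, 1e-9)
        mask = tau - f0 > 1e-12
        x = p[mask]
        y = tau0_0 / (tau[mask] - f0) - 1.0
        denom = float(x @ x)
        k0_0 = float(x @ y) / denom if denom > 0 else 0.01
        k0_0 = max(k0_0, 1e-6)
        if temperature_compensated:
            return np.array([tau0_0, k0_0, 0.0, f0])
        return np.array([tau0_0, k0_0, f0])

    def _predict_params(self, params: np.ndarray, p, T, temperature_compensated: bool):
        if temperature_compensated:
            tau0, k0, kT, f = params
            K = k0 + kT * (T - self.tc_c)
        else:
            tau0, k0, f = params
            K = k0
        return tau0 / (1.0 + K * p) + f

    def fit(self, temperature_compensated: Optional[bool] = None) -> "SternVolmerResults":
        """Nonlinear least squares on the lifetime scale (unweighted).

        With ``temperature_compensated=None`` the temperature term is
        included whenever readings at two or more distinct temperatures are
        present.
        """
        if temperature_compensated is None:
            temperature_compensated = self.n_distinct_temps() >= 2
        if temperature_compensated:
            if self.temp_c is None or self.n_distinct_temps() < 2:
                raise ValueError(
                    "temperature-compensated fit needs readings at >= 2 distinct "
                    "temperatures; use the 1-D fit (temperature_compensated=False) "
                    "for single-temperature data"
                )
            self._check_spread(min_points=5)
            names = self.PARAM_NAMES_2D
            lb = np.array([1e-12, 1e-12, -np.inf, 0.0])
        else:
            self._check_spread(min_points=4)
            names = self.PARAM_NAMES_1D
            lb = np.array([1e-12, 1e-12, 0.0])
        ub = np.full(len(names), np.inf)

        p = self.pO2_mmHg
        T = self.temp_c if self.temp_c is not None else np.zeros_like(p) + self.tc_c
        y = self.lifetime_s

        def resid(params):
            return self._predict_params(params, p, T, temperature_compensated) - y

        x0 = np.clip(self._initial_guess(temperature_compensated), lb, ub)
        sol = optimize.least_squares(
            resid, x0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        if not sol.success:
            raise RuntimeError(f"Stern-Volmer fit did not converge: {sol.message}")
        return SternVolmerResults(self, sol, tuple(names), temperature_compensated)


class SternVolmerResults:
    """Fitted Stern-Volmer calibration.

    Attributes
    ----------
    params : ndarray
        Point estimates in the order of ``param_names``.
    sv : SternVolmerModel
        The fitted parameters as a model object (kT = 0 for the 1-D fit).
    bse : ndarray
        Standard errors from the Jacobian-based covariance.
    sigma : float
        Residual standard deviation (seconds) with n - p degrees of freedom.
    """

    def __init__(self, model: SternVolmerCalibration, sol, param_names, temperature_compensated):
        self.model = model
        self.param_names = param_names
        self.temperature_compensated = bool(temperature_compensated)
        self.params = sol.x.copy()
        self.resid = sol.fun.copy()
        self.nobs = model.nobs
        self.df_resid = self.nobs - len(param_names)
        self.rss = float(self.resid @ self.resid)
        self.sigma = math.sqrt(self.rss / self.df_resid) if self.df_resid > 0 else 0.0
        J = sol.jac
        JtJ = J.T @ J
        try:
            self.cov_unscaled = np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            self.cov_unscaled = np.linalg.pinv(JtJ)
        self.cov_params = self.sigma**2 * self.cov_unscaled
        self.bse = np.sqrt(np.diag(self.cov_params))

        if self.temperature_compensated:
            tau0, k0, kT, f = self.params
        else:
            tau0, k0, f = self.params
            kT = 0.0
        self.sv = SternVolmerModel(
            tau0_s=tau0, k0_per_mmHg=k0, kT_per_mmHg_c=kT, f_s=f, tc_c=model.tc_c
        )

    # -- inference ---------------------------------------------------------

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided t-based confidence intervals for the parameters."""
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(self.param_names))

    def predict(self, pO2_mmHg, temp_c=None):
        """Predicted lifetime (seconds) at the given oxygen tension(s)."""
        temp = self.model.tc_c if temp_c is None else temp_c
        return predict_lifetime(self.sv, pO2_mmHg, temp)

    def invert(self, lifetime_s: float, temp_c: Optional[float] = None) -> Tuple[float, str]:
        """Oxygen tension (mmHg, with feasibility flag) for one lifetime."""
        temp = self.model.tc_c if temp_c is None else temp_c
        return invert_pO2(self.sv, lifetime_s, temp)

    def _pred_gradient(self, p, T):
        """Gradient of the predicted lifetime w.r.t. the parameters."""
        K = self.sv.quench_constant(T)
        denom = 1.0 + K * p
        d_tau0 = 1.0 / denom
        d_k0 = -self.sv.tau0_s * p / denom**2
        d_f = np.ones_like(denom)
        if self.temperature_compensated:
            d_kT = d_k0 * (np.asarray(T, float) - self.model.tc_c)
            return np.stack([d_tau0, d_k0, d_kT, d_f], axis=-1)
        return np.stack([d_tau0, d_k0, d_f], axis=-1)

    def prediction_interval(self, pO2_mmHg, temp_c=None, level: float = 0.95) -> pd.DataFrame:
        """Prediction band for a new single lifetime reading, mapped to pO2.

        On the lifetime scale the band is the t-based linearization
        ``tau_hat +/- t * sigma * sqrt(1 + g' (J'J)^-1 g)`` with n - p
        degrees of freedom (the +1 accounts for the new observation's own
        noise).  The lifetime bounds are then pushed through the closed-form
        inverse: because lifetime decreases with oxygen, the upper lifetime
        bound gives the lower pO2 bound and vice versa.  Infeasible or
        negative inversions are clamped to the physical domain.

        Returns a DataFrame with columns ``pO2_mmHg, tau_hat_s, tau_lo_s,
        tau_hi_s, pO2_lo_mmHg, pO2_hi_mmHg``.
        """
        if self.df_resid < 2:
            raise ValueError("too few points for a prediction interval")
        temp = self.model.tc_c if temp_c is None else temp_c
        p = np.atleast_1d(np.asarray(pO2_mmHg, float))
        T = np.broadcast_to(np.asarray(temp, float), p.shape)
        tau_hat = np.atleast_1d(predict_lifetime(self.sv, p, T))
        G = self._pred_gradient(p, T)
        lev = np.einsum("ij,jk,ik->i", G, self.cov_unscaled, G)
        q = stats.t.ppf(0.5 + level / 2.0, self.df_resid)
        half = q * self.sigma * np.sqrt(1.0 + lev)
        tau_lo, tau_hi = tau_hat - half, tau_hat + half

        def safe_invert(tau, t_c, fallback):
            val, flag = invert_pO2(self.sv, float(tau), float(t_c))
            if flag == "infeasible":
                return fallback
            return val

        pO2_lo = np.array(
            [safe_invert(th, t_c, 0.0) for th, t_c in zip(tau_hi, T)]
        )
        pO2_hi = np.array(
            [safe_invert(tl, t_c, math.inf) for tl, t_c in zip(tau_lo, T)]
        )
        return pd.DataFrame(
            {
                "pO2_mmHg": p,
                "tau_hat_s": tau_hat,
                "tau_lo_s": tau_lo,
                "tau_hi_s": tau_hi,
                "pO2_lo_mmHg": pO2_lo,
                "pO2_hi_mmHg": pO2_hi,
            }
        )

    def summary(self) -> str:
        """Plain-text fit summary (parameters, SEs, 95% CIs, residual SD)."""
        ci = self.conf_int()
        lines = [
            "Stern-Volmer calibration fit",
            "=" * 64,
            f"model: {'temperature-compensated (2-D)' if self.temperature_compensated else '1-D (fixed temperature)'}",
            f"nobs: {self.nobs}    df_resid: {self.df_resid}    TC: {self.model.tc_c:g} degC",
            f"residual SD: {self.sigma:.4e} s    RSS: {self.rss:.4e} s^2",
            "-" * 64,
            f"{'param':<16}{'estimate':>14}{'std err':>12}{'[0.025':>12}{'0.975]':>12}",
        ]
        for i, name in enumerate(self.param_names):
            lines.append(
                f"{name:<16}{self.params[i]:>14.6g}{self.bse[i]:>12.3g}"
                f"{ci['lower'].iloc[i]:>12.6g}{ci['upper'].iloc[i]:>12.6g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_calibration(self, ax=None, n_grid: int = 200):
        """Calibration curve with the 95% prediction band (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.model.pO2_mmHg
        grid = np.linspace(p.min(), p.max(), n_grid)
        band = self.prediction_interval(grid)
        ax.plot(p, self.model.lifetime_s * 1e6, ".", alpha=0.4, label="calibration points")
        ax.plot(grid, band["tau_hat_s"] * 1e6, "-", label="Stern-Volmer fit")
        ax.plot(grid, band["tau_lo_s"] * 1e6, "g-", lw=0.8, label="95% prediction interval")
        ax.plot(grid, band["tau_hi_s"] * 1e6, "g-", lw=0.8)
        ax.set_xlabel("pO2 (mmHg)")
        ax.set_ylabel("lifetime (us)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional surface


def make_schedule(p_min: float, p_max: float) -> list:
    """Gas-mixer setpoint schedule for a calibration run.

    Ascending setpoints with the protocol's range-dependent step sizes:
    5 mmHg below 20, 10 mmHg between 20 and 60, 20 mmHg above 60; each
    setpoint dwells 5 min with the reference oximeter sampling every 3 s.
    The endpoint is always included.
    """
    if not (0 <= p_min < p_max):
        raise ValueError("require 0 <= p_min < p_max")
    setpoints = [float(p_min)]
    p = float(p_min)
    while p < p_max:
        step = 5.0 if p < 20 else 10.0 if p < 60 else 20.0
        p = min(p + step, float(p_max))
        setpoints.append(p)
    return [ScheduleStep(pO2_mmHg=sp) for sp in setpoints]


def fit_stern_volmer_1d(points, fixed_temp: float) -> SternVolmerResults:
    """Single-temperature fit over (tau0, k0, f); kT is fixed at 0 and the
    calibration temperature recorded as ``fixed_temp``."""
    frame = _as_frame(points)
    cal = SternVolmerCalibration(
        frame["lifetime_s"].to_numpy(),
        frame["pO2_mmHg"].to_numpy(),
        temp_c=np.full(len(frame), float(fixed_temp)),
        tc_c=float(fixed_temp),
    )
    return cal.fit(temperature_compensated=False)


def fit_stern_volmer_2d(points, tc_c: float) -> SternVolmerResults:
    """Temperature-compensated fit over (tau0, k0, kT, f) with TC fixed."""
    frame = _as_frame(points)
    if frame["temp_c"].isna().any():
        raise ValueError("temperature-compensated fit needs a temperature for every point")
    cal = SternVolmerCalibration(
        frame["lifetime_s"].to_numpy(),
        frame["pO2_mmHg"].to_numpy(),
        temp_c=frame["temp_c"].to_numpy(),
        tc_c=float(tc_c),
    )
    return cal.fit(temperature_compensated=True)


def prediction_interval(results: SternVolmerResults, pO2_mmHg, temp_c=None, level: float = 0.95):
    """Module-level alias for :meth:`SternVolmerResults.prediction_interval`."""
    return results.prediction_interval(pO2_mmHg, temp_c=temp_c, level=level)


def bland_altman(measured, reference) -> AgreementStats:
    """Bland-Altman agreement: bias and 1.96-SD limits of agreement.

    ``bias = mean(measured - reference)``; the limits use the sample
    (n-1 denominator) standard deviation of the differences.
    """
    m = np.asarray(measured, float)
    r = np.asarray(reference, float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("measured and reference must be equal-length 1-D arrays")
    if m.size < 2:
        raise ValueError("need at least 2 paired readings")
    d = m - r
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=int(m.size), sd_diff=sd
    )


def relative_error_profile(
    model: Union[SternVolmerModel, SternVolmerResults],
    dataset,
    lo: float,
    hi: float,
) -> pd.Series:
    """Relative pO2 error profile over a reference range.

    For every calibration point with reference pO2 in ``[lo, hi]`` (and
    strictly positive, so the ratio is defined), the measured lifetime is
    inverted through the model and ``|predicted - reference| / reference``
    recorded.  Returns a Series with ``n``, ``median``, ``mean``, ``p95``
    and ``max`` of the relative errors (fractions, not percent).
    """
    sv = model.sv if isinstance(model, SternVolmerResults) else model
    frame = _as_frame(dataset)
    sel = frame[(frame["pO2_mmHg"] >= lo) & (frame["pO2_mmHg"] <= hi) & (frame["pO2_mmHg"] > 0)]
    if sel.empty:
        raise ValueError(f"no calibration points with reference pO2 in [{lo}, {hi}]")
    errs = []
    for _, row in sel.iterrows():
        temp = row["temp_c"] if np.isfinite(row.get("temp_c", np.nan)) else sv.tc_c
        pred, flag = invert_pO2(sv, row["lifetime_s"], temp)
        if flag == "infeasible":
            pred = math.inf
        errs.append(abs(pred - row["pO2_mmHg"]) / row["pO2_mmHg"])
    errs = np.asarray(errs)
    return pd.Series(
        {
            "n": float(errs.size),
            "median": float(np.median(errs)),
            "mean": float(np.mean(errs)),
            "p95": float(np.percentile(errs, 95)),
            "max": float(np.max(errs)),
        }
    )
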