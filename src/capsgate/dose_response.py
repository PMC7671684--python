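"""Concentration-response (Hill) fitting, tail-current OFF rates, and
macroscopic-to-Po normalization.

Activation curves are fitted to R(c) = max / (1 + (EC50/c)^K) and inhibition
curves to R(i) = max / (1 + (i/IC50)^K), with K the Hill coefficient. The
fit is performed on log-concentration internally (the midpoint parameter is
log10 EC50) for numerical conditioning; reported parameters and standard
errors are on the linear scale.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .channel import Recording
from .errors import FitError, ParameterError


@dataclass
class DoseResponseCurve:
    """Concentration-response data: concentration in µM, response with SE, n patches."""

    concentration_uM: np.ndarray
    response: np.ndarray
    se: np.ndarray | None = None
    n: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.concentration_uM = np.asarray(self.concentration_uM, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration_uM.size != self.response.size:
            raise ParameterError("concentration and response must match in length")
        if self.concentration_uM.size == 0:
            raise ParameterError("empty concentration list")
        if np.any(self.concentration_uM <= 0):
            raise ParameterError("concentrations must be positive")
        if np.any(np.diff(self.concentration_uM) <= 0):
            raise ParameterError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ParameterError("responses must be finite")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        if self.n is not None:
            self.n = np.asarray(self.n)

    def __len__(self):
        return self.concentration_uM.size

    def to_csv(self, path_or_buf=None):
        df = pd.DataFrame({
            "concentration_uM": self.concentration_uM,
            "response": self.response,
            "se": self.se if self.se is not None else np.nan,
            "n": self.n if self.n is not None else 0,
        })
        return df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "DoseResponseCurve":
        df = pd.read_csv(path_or_buf)
        se = df["se"].to_numpy() if "se" in df else None
        n = df["n"].to_numpy() if "n" in df else None
        if se is not None and np.all(np.isnan(se)):
            se = None
        return cls(df["concentration_uM"].to_numpy(), df["response"].to_numpy(),
                   se=se, n=n)


def _hill(logc, log_mid, k, rmax, direction):
    if direction == "activation":
        return rmax / (1.0 + 10.0 ** (k * (log_mid - logc)))
    return rmax / (1.0 + 10.0 ** (k * (logc - log_mid)))


class HillModel:
    """Hill-equation model of a concentration-response curve.

    Parameters
    ----------
    curve : DoseResponseCurve
        Data; at least 4 distinct concentrations spanning the inflection.
    direction : {"activation", "inhibition"}
        Whether the midpoint is an EC50 (rising curve) or IC50 (falling).
    weights : {"none", "1/se2"}
        Optional inverse-variance weighting using the curve's SEs.
    """

    def __init__(self, curve: DoseResponseCurve,
                 direction: str = "activation", weights: str = "none"):
        if direction not in ("activation", "inhibition"):
            raise ParameterError(f"unknown direction {direction!r}")
        if len(curve) < 4:
            raise FitError("insufficient data: need at least 4 concentrations")
        self.curve = curve
        self.direction = direction
        self.logc = np.log10(curve.concentration_uM)
        if weights == "1/se2":
            if curve.se is None or np.any(~np.isfinite(curve.se)) or np.any(curve.se <= 0):
                raise ParameterError("1/se2 weighting requires positive finite SEs")
            self.w = 1.0 / curve.se
        elif weights == "none":
            self.w = np.ones(len(curve))
        else:
            raise ParameterError(f"unknown weighting {weights!r}")

    # -- initial guesses: midpoint at the half-range crossing, K = 1 --------

    def _theta0(self):
        r = self.curve.response
        rmax0 = r.max()
        half = (r.max() + r.min()) / 2.0
        if self.direction == "activation":
            idx = np.nonzero(r >= half)[0]
        else:
            idx = np.nonzero(r <= half)[0]
        mid0 = self.logc[idx[0]] if idx.size else np.median(self.logc)
        return np.array([mid0, 1.0, max(rmax0, 1e-12)])

    def fit(self) -> "HillResults":
        r = self.curve.response
        if r.max() - r.min() < 1e-12 * max(abs(r.max()), 1.0):
            raise FitError("flat response: no concentration dependence to fit")

        def resid(theta):
            return self.w * (_hill(self.logc, theta[0], theta[1], theta[2],
                                   self.direction) - r)

        sol = least_squares(
            resid, self._theta0(),
            bounds=([-np.inf, 1e-6, 1e-12], [np.inf, 50.0, np.inf]),
        )
        if not sol.success:
            raise FitError(f"Hill fit did not converge: {sol.message}")
        log_mid, k, rmax = sol.x
        mid = 10.0 ** log_mid
        span = (self.curve.concentration_uM.min() / 10.0,
                self.curve.concentration_uM.max() * 10.0)
        if not (span[0] <= mid <= span[1]):
            raise FitError(
                f"fitted midpoint {mid:.3g} µM lies more than 10x outside the "
                f"sampled concentration range"
            )
        dof = max(len(self.curve) - 3, 1)
        s2 = float(np.sum(sol.fun ** 2)) / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        mid_se = mid * np.log(10.0) * se[0]  # delta method off the log scale
        fitted = _hill(self.logc, log_mid, k, rmax, self.direction)
        return HillResults(
            model=self, midpoint=mid, midpoint_se=mid_se, K=k, K_se=se[1],
            rmax=rmax, rmax_se=se[2], residuals=r - fitted, fitted=fitted,
        )


@dataclass
class HillResults:
    """Fitted Hill parameters with asymptotic standard errors."""

    model: HillModel
    midpoint: float
    midpoint_se: float
    K: float
    K_se: float
    rmax: float
    rmax_se: float
    residuals: np.ndarray
    fitted: np.ndarray

    @property
    def direction(self) -> str:
        return self.model.direction

    @property
    def ec50(self) -> float:
        if self.direction != "activation":
            raise AttributeError("inhibition fit: use ic50")
        return self.midpoint

    @property
    def ec50_se(self) -> float:
        if self.direction != "activation":
            raise AttributeError("inhibition fit: use ic50_se")
        return self.midpoint_se

    @property
    def ic50(self) -> float:
        if self.direction != "inhibition":
            raise AttributeError("activation fit: use ec50")
        return self.midpoint

    @property
    def ic50_se(self) -> float:
        if self.direction != "inhibition":
            raise AttributeError("activation fit: use ec50_se")
        return self.midpoint_se

    @property
    def params(self) -> dict:
        key = "EC50" if self.direction == "activation" else "IC50"
        return {key: self.midpoint, "K": self.K, "max": self.rmax}

    @property
    def bse(self) -> dict:
        key = "EC50" if self.direction == "activation" else "IC50"
        return {key: self.midpoint_se, "K": self.K_se, "max": self.rmax_se}

    def predict(self, concentration_uM):
        c = np.asarray(concentration_uM, dtype=float)
        return _hill(np.log10(c), np.log10(self.midpoint), self.K, self.rmax,
                     self.direction)

    def bootstrap_se(self, n_boot: int = 200, seed: int | None = None) -> dict:
        """Residual-resampling bootstrap SEs for the three parameters.

        Residuals are inflated by sqrt(n/(n-p)) before resampling to undo
        the variance absorbed by the p = 3 fitted parameters.
        """
        rng = np.random.default_rng(seed)
        curve = self.model.curve
        n = len(curve)
        scaled = self.residuals * np.sqrt(n / max(n - 3, 1))
        mids, ks, maxes = [], [], []
        for _ in range(n_boot):
            resp = self.fitted + rng.choice(scaled, size=n, replace=True)
            try:
                boot = HillModel(
                    DoseResponseCurve(curve.concentration_uM, resp),
                    direction=self.direction,
                ).fit()
            except FitError:
                continue
            mids.append(boot.midpoint)
            ks.append(boot.K)
            maxes.append(boot.rmax)
        key = "EC50" if self.direction == "activation" else "IC50"
        return {key: float(np.std(mids, ddof=1)),
                "K": float(np.std(ks, ddof=1)),
                "max": float(np.std(maxes, ddof=1)),
                "n_success": len(mids)}

    def summary(self) -> str:
        key = "EC50" if self.direction == "activation" else "IC50"
        rss = float(np.sum(self.residuals ** 2))
        return "\n".join([
            f"Hill fit ({self.direction})",
            "=" * 43,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
            f"{key + ' (µM)':<14}{self.midpoint:>12.4g}{self.midpoint_se:>12.3g}",
            f"{'K (Hill)':<14}{self.K:>12.4g}{self.K_se:>12.3g}",
            f"{'max':<14}{self.rmax:>12.4g}{self.rmax_se:>12.3g}",
            "-" * 43,
            f"n = {len(self.model.curve)} concentrations, RSS = {rss:.3g}",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve.concentration_uM
        ax.semilogx(c, self.model.curve.response, "o", label="data")
        cc = np.logspace(np.log10(c.min()), np.log10(c.max()), 200)
        ax.semilogx(cc, self.predict(cc), "-", label="Hill fit")
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("response")
        ax.legend()
        return ax


def fit_hill(curve: DoseResponseCurve, direction: str = "activation",
             weights: str = "none") -> HillResults:
    """Convenience wrapper: ``HillModel(curve, direction).fit()``."""
    return HillModel(curve, direction, weights).fit()


# ---------------------------------------------------------------------------
# Tail-current OFF rate
# ---------------------------------------------------------------------------


class TailCurrentModel:
    """Single-exponential model of tail-current decay after agonist washout.

    I(t) = baseline + amplitude * exp(-(t - t0)/tau); the OFF rate is 1/tau.
    """

    def __init__(self, tail: Recording, window_ms: tuple | None = None):
        self.tail = tail
        t = tail.time_ms
        i = tail.current_pA
        if window_ms is not None:
            t0, t1 = window_ms
            if t0 < 0 or t1 > tail.duration_ms or t1 <= t0:
                raise ParameterError("fit window must lie within the trace")
            m = (t >= t0) & (t <= t1)
            t, i = t[m], i[m]
        if t.size < 5:
            raise FitError("too few samples in the fit window")
        self.t, self.i = t, i

    def fit(self) -> "TauResults":
        t, i = self.t, self.i
        base0 = float(np.mean(i[-max(t.size // 10, 1):]))
        amp0 = float(i[0] - base0)
        head = np.abs(i[: max(t.size // 3, 2)] - base0)
        # crude tau guess from the e-fold point of the early decay
        target = np.abs(amp0) / np.e
        below = np.nonzero(head <= target)[0]
        tau0 = t[below[0]] - t[0] if below.size else (t[-1] - t[0]) / 3.0
        tau0 = max(tau0, 2 * (t[1] - t[0]))

        def resid(theta):
            amp, tau, base = theta
            return base + amp * np.exp(-(t - t[0]) / tau) - i

        sol = least_squares(resid, [amp0, tau0, base0],
                            bounds=([-np.inf, 1e-9, -np.inf],
                                    [np.inf, np.inf, np.inf]))
        if not sol.success:
            raise FitError(f"exponential fit did not converge: {sol.message}")
        amp, tau, base = sol.x
        if abs(amp) < 1e-12 or tau > 100 * (t[-1] - t[0]):
            raise FitError("trace is not decaying: tau unbounded or amplitude zero")
        dof = max(t.size - 3, 1)
        s2 = float(np.sum(sol.fun ** 2)) / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        return TauResults(tau_ms=tau, tau_se=se[1], amplitude_pA=amp,
                          baseline_pA=base, residuals=sol.fun.copy())


@dataclass
class TauResults:
    """Single-exponential tail fit: time constant, amplitude, baseline."""

    tau_ms: float
    tau_se: float
    amplitude_pA: float
    baseline_pA: float
    residuals: np.ndarray

    @property
    def off_rate_per_ms(self) -> float:
        return 1.0 / self.tau_ms

    @property
    def params(self) -> dict:
        return {"tau_ms": self.tau_ms, "amplitude_pA": self.amplitude_pA,
                "baseline_pA": self.baseline_pA}

    def summary(self) -> str:
        return "\n".join([
            "Single-exponential tail fit",
            "=" * 40,
            f"tau       = {self.tau_ms:.4g} ± {self.tau_se:.3g} ms",
            f"OFF rate  = {self.off_rate_per_ms:.4g} /ms",
            f"amplitude = {self.amplitude_pA:.4g} pA",
            f"baseline  = {self.baseline_pA:.4g} pA",
        ])


def fit_off_rate(tail: Recording, window_ms: tuple | None = None) -> TauResults:
    """Convenience wrapper: ``TailCurrentModel(tail, window).fit()``."""
    return TailCurrentModel(tail, window_ms).fit()


# ---------------------------------------------------------------------------
# Macroscopic Po normalization
# ---------------------------------------------------------------------------


def normalize_to_po(test_max_current: float, ref_max_current: float,
                    ref_po: float, conductance_ratio: float = 1.0) -> float:
    """Convert a macroscopic maximal current to the open-probability scale.

    The test current is first corrected for any single-channel amplitude
    difference (``conductance_ratio`` = i_test / i_ref, 1.0 when equal — the
    shortened analog runs about 10% smaller), then scaled by the reference
    ligand's saturating Po:

        Po = (test / conductance_ratio) / ref * ref_po
    """
    if ref_max_current <= 0:
        raise ParameterError("reference maximal current must be positive")
    if not (0 < ref_po <= 1):
        raise ParameterError("reference Po must lie in (0, 1]")
    if conductance_ratio <= 0:
        raise ParameterError("conductance ratio must be positive")
    po = (test_max_current / conductance_ratio) / ref_max_current * ref_po
    if po > 1.0:
        warnings.warn(
            f"normalized Po = {po:.3f} exceeds 1; reporting clipped value",
            UserWarning, stacklevel=2,
        )
        po = 1.0
    return po
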