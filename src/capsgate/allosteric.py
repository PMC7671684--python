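"""Three-state allosteric gating analysis.

The channel is modelled as C <-> C.L <-> O.L: ligand binding (dissociation
constant K_D) followed by a concerted opening step of the liganded channel
(equilibrium constant L = [O.L]/[C.L]). Unliganded openings are rare for this
channel and are neglected, so the model has exactly two free parameters.

At equilibrium the open probability is

    Po(c) = L * (c/K_D) / (1 + (c/K_D) * (1 + L))

which is exactly a Hill function with unit slope, half-activation
concentration EC50 = K_D / (1 + L) and ceiling Po_max = L / (1 + L).
Inverting those two relations gives the standard two-step estimator

    L   = Po_max / (1 - Po_max)        (from saturating agonist)
    K_D = EC50 * (1 + L)               (from the dose-response midpoint)

which becomes unreliable as Po_max -> 1 (the (1 - Po_max) denominator
vanishes); a background mutation that lowers Po_max to ~0.5 restores
identifiability, which is the strategy supported here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .channel import ChannelModel, DEFAULT_TEMPERATURE_K
from .errors import IdentifiabilityError, IdentifiabilityWarning, ParameterError

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.98720425e-3
#: Boltzmann / Planck ratio, 1/(s*K): attempt frequency prefactor kB*T/h.
KB_OVER_H = 2.083661912e10


@dataclass(frozen=True)
class GatingEstimate:
    """Binding and gating constants decomposed from Po_max and EC50."""

    L: float
    L_se: float
    K_D: float
    K_D_se: float
    po_max: float = np.nan
    po_max_se: float = np.nan
    ec50: float = np.nan
    ec50_se: float = np.nan
    ligand: str = ""

    def as_model(self, g: float = 100.0, E_rev: float = 0.0) -> ChannelModel:
        return ChannelModel(K_D=self.K_D, L=self.L, g=g, E_rev=E_rev)


def estimate_L(po_max: float, se: float = 0.0) -> tuple[float, float]:
    """Gating constant from the saturating open probability.

    L = po_max / (1 - po_max); the first-order (delta-method) standard error
    is se / (1 - po_max)**2.
    """
    if po_max >= 1.0:
        raise IdentifiabilityError(
            "Po_max >= 1: the denominator (1 - Po_max) becomes very small at "
            "saturating ligand concentrations and L cannot be estimated; use "
            "a reduced-Po_max background (e.g. I574A) instead"
        )
    if po_max <= 0.0:
        raise ParameterError(f"po_max must lie in (0, 1), got {po_max}")
    if se < 0:
        raise ParameterError("se must be non-negative")
    L = po_max / (1.0 - po_max)
    L_se = se / (1.0 - po_max) ** 2
    return L, L_se


def estimate_KD(ec50: float, L: float, ec50_se: float = 0.0,
                L_se: float = 0.0) -> tuple[float, float]:
    """Dissociation constant from the midpoint and the gating constant.

    K_D = EC50 * (1 + L); the delta-method SE assumes independent errors:
    SE^2 = ((1+L)*se_EC50)^2 + (EC50*se_L)^2.
    """
    if ec50 <= 0:
        raise ParameterError(f"EC50 must be positive, got {ec50}")
    if L < 0:
        raise ParameterError(f"L must be non-negative, got {L}")
    K_D = ec50 * (1.0 + L)
    K_D_se = np.hypot((1.0 + L) * ec50_se, ec50 * L_se)
    return K_D, K_D_se


def decompose(po_max: float, ec50: float, po_max_se: float = 0.0,
              ec50_se: float = 0.0, ligand: str = "") -> GatingEstimate:
    """Full two-step decomposition Po_max, EC50 -> (L, K_D) with SEs."""
    L, L_se = estimate_L(po_max, po_max_se)
    K_D, K_D_se = estimate_KD(ec50, L, ec50_se, L_se)
    return GatingEstimate(L=L, L_se=L_se, K_D=K_D, K_D_se=K_D_se,
                          po_max=po_max, po_max_se=po_max_se,
                          ec50=ec50, ec50_se=ec50_se, ligand=ligand)


def predict_po(model: ChannelModel, c):
    """Equilibrium open probability of the three-state model at concentration c (µM)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ParameterError("concentration must be non-negative")
    x = c / model.K_D
    po = model.L * x / (1.0 + x * (1.0 + model.L))
    return po if po.ndim else float(po)


class ThreeStateModel:
    """Direct least-squares fit of (K_D, L) to an open-probability curve.

    An alternative to the two-step estimator when the curve itself is on the
    Po scale. Parameters are optimized on a log scale for conditioning.

    Parameters
    ----------
    concentration_uM, po : array-like
        Dose-response data on the absolute open-probability scale.
    """

    def __init__(self, concentration_uM, po):
        self.c = np.asarray(concentration_uM, dtype=float)
        self.po = np.asarray(po, dtype=float)
        if self.c.size != self.po.size:
            raise ParameterError("concentration and po must have equal length")
        if self.c.size < 3:
            raise ParameterError("need at least 3 points to fit (K_D, L)")
        if np.any(self.c <= 0):
            raise ParameterError("concentrations must be positive")
        span = self.po.max() - self.po.min()
        if span < 1e-3 or self.po.max() < 1e-3:
            raise IdentifiabilityError(
                "curve is flat (all-saturated or all-zero); K_D and L are not "
                "identifiable from it"
            )

    def _residuals(self, theta):
        kd, L = 10.0 ** theta
        m = ChannelModel(K_D=kd, L=L)
        return predict_po(m, self.c) - self.po

    def fit(self, ridge_po_max: float = 0.98) -> "ThreeStateResults":
        po_max0 = min(self.po.max(), 0.99)
        L0 = po_max0 / (1.0 - po_max0)
        # midpoint guess: concentration where po first crosses half its max
        half = self.po.max() / 2.0
        above = np.nonzero(self.po >= half)[0]
        ec50_0 = self.c[above[0]] if above.size else np.median(self.c)
        kd0 = ec50_0 * (1.0 + L0)
        theta0 = np.log10([kd0, L0])
        sol = least_squares(self._residuals, theta0, method="lm")
        if not sol.success:
            raise IdentifiabilityError(f"three-state fit failed: {sol.message}")
        kd, L = 10.0 ** sol.x
        # asymptotic covariance on the log10 scale from the Jacobian
        dof = max(self.c.size - 2, 1)
        s2 = float(np.sum(sol.fun ** 2)) / dof
        JTJ = sol.jac.T @ sol.jac
        try:
            cov_log = s2 * np.linalg.inv(JTJ)
            se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        except np.linalg.LinAlgError:
            se_log = np.full(2, np.nan)
        ln10 = np.log(10.0)
        kd_se, L_se = kd * ln10 * se_log[0], L * ln10 * se_log[1]
        po_max_hat = L / (1.0 + L)
        ridge = po_max_hat > ridge_po_max
        if ridge:
            warnings.warn(
                f"fitted Po_max = {po_max_hat:.3f} > {ridge_po_max}: the fit "
                "lies on the flat L-K_D ridge; L and K_D are poorly "
                "identifiable (consider a reduced-Po_max background)",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        return ThreeStateResults(
            model=self, K_D=kd, K_D_se=kd_se, L=L, L_se=L_se,
            residuals=sol.fun.copy(), on_ridge=ridge,
        )


@dataclass
class ThreeStateResults:
    """Result of :meth:`ThreeStateModel.fit`."""

    model: ThreeStateModel
    K_D: float
    K_D_se: float
    L: float
    L_se: float
    residuals: np.ndarray
    on_ridge: bool

    @property
    def params(self) -> dict:
        return {"K_D": self.K_D, "L": self.L}

    @property
    def bse(self) -> dict:
        return {"K_D": self.K_D_se, "L": self.L_se}

    @property
    def po_max(self) -> float:
        return self.L / (1.0 + self.L)

    @property
    def ec50(self) -> float:
        return self.K_D / (1.0 + self.L)

    def as_channel_model(self, g: float = 100.0, E_rev: float = 0.0) -> ChannelModel:
        return ChannelModel(K_D=self.K_D, L=self.L, g=g, E_rev=E_rev)

    def predict(self, c):
        return predict_po(ChannelModel(K_D=self.K_D, L=self.L), c)

    def summary(self) -> str:
        lines = [
            "Three-state allosteric gating fit",
            "=" * 41,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}",
            f"{'K_D (µM)':<12}{self.K_D:>12.4g}{self.K_D_se:>12.3g}",
            f"{'L':<12}{self.L:>12.4g}{self.L_se:>12.3g}",
            "-" * 41,
            f"implied Po_max = {self.po_max:.4g}, EC50 = {self.ec50:.4g} µM",
        ]
        if self.on_ridge:
            lines.append("WARNING: fit on the flat L-K_D ridge (Po_max near 1)")
        return "\n".join(lines)


@dataclass
class EnergyProfile:
    """Relative free energies of the gating states at a given ligand dose.

    Energies are in kcal/mol with the unliganded closed state C as the zero
    of energy:

        G(C.L) = -RT ln(c / K_D)          (binding step at concentration c)
        G(O.L) = G(C.L) - RT ln(L)        (gating step)

    so the open state lies below the bound-closed state iff L > 1. When an
    OFF rate is supplied, the unbinding barrier height above C.L follows from
    transition-state theory, dG = RT ln(kB*T / (h * k_off)), with unit
    transmission coefficient.
    """

    states: tuple
    energies_kcal: np.ndarray
    concentration_uM: float
    temperature_K: float
    barrier_kcal: float | None = None
    meta: dict = field(default_factory=dict)

    def in_kT(self) -> np.ndarray:
        """Energies expressed in units of kB*T (i.e. divided by RT)."""
        return self.energies_kcal / (R_KCAL * self.temperature_K)

    def as_dict(self) -> dict:
        d = dict(zip(self.states, map(float, self.energies_kcal)))
        d.update(
            concentration_uM=self.concentration_uM,
            temperature_K=self.temperature_K,
        )
        if self.barrier_kcal is not None:
            d["unbinding_barrier_kcal"] = self.barrier_kcal
        return d

    def plot(self, ax=None):
        """Quick-look staircase rendering of the profile."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, (s, g) in enumerate(zip(self.states, self.energies_kcal)):
            ax.hlines(g, i - 0.3, i + 0.3, lw=3)
            ax.annotate(s, (i, g), textcoords="offset points", xytext=(0, 6),
                        ha="center")
        ax.set_xticks(range(len(self.states)))
        ax.set_xticklabels(self.states)
        ax.set_ylabel("G (kcal/mol)")
        ax.set_xlabel("state")
        return ax


def eyring_profile(est: GatingEstimate | ChannelModel, c: float,
                   T: float = DEFAULT_TEMPERATURE_K,
                   off_rate_per_ms: float | None = None) -> EnergyProfile:
    """Free-energy profile of C -> C.L -> O.L at ligand concentration c (µM)."""
    if c <= 0:
        raise ParameterError(
            "c must be positive: at c = 0 the binding free energy diverges"
        )
    if T <= 0:
        raise ParameterError("temperature must be positive")
    K_D = est.K_D
    L = est.L
    RT = R_KCAL * T
    g_cl = -RT * np.log(c / K_D)
    g_ol = g_cl - RT * np.log(L) if L > 0 else np.inf
    barrier = None
    if off_rate_per_ms is not None:
        if off_rate_per_ms <= 0:
            raise ParameterError("off rate must be positive")
        k_off_s = off_rate_per_ms * 1e3
        barrier = RT * np.log(KB_OVER_H * T / k_off_s)
    return EnergyProfile(
        states=("C", "CL", "OL"),
        energies_kcal=np.array([0.0, g_cl, g_ol]),
        concentration_uM=c,
        temperature_K=T,
        barrier_kcal=barrier,
        meta={
            "note": (
                "three-state model implies unit Hill slope; empirical Hill "
                "coefficients above 1 are not used by this estimator, which "
                "relies on Po_max and EC50 only"
            )
        },
    )
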