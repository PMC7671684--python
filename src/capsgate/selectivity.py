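"""Reversal potentials and GHK permeability ratios.

The constant-field (Goldman-Hodgkin-Katz) flux for species s with valence z,
relative permeability P and concentrations c_in / c_out is proportional to

    phi_s(u) = P * z^2 * u * (c_in - c_out * exp(-z u)) / (1 - exp(-z u)),

with u = V*F/(R*T) the reduced membrane potential. The reversal potential is
the root of sum_s phi_s(u) = 0; for mixtures containing divalents this
extended equation has no closed form and is solved numerically. For the
bi-ionic arrangement used experimentally (divalent X inside only, monovalent
M outside only) the root condition factorises into the Fatt-Ginsborg form

    P_X / P_M = [M]_o * exp(-u) * (1 + exp(-u)) / (4 [X]_i),

which this module provides as a closed-form inverse cross-checked against the
numeric root.

Concentrations are used as activities (no activity-coefficient correction);
buffers and chloride are treated as impermeant for this cation channel.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .channel import Ion, IonConditions
from .errors import (
    AmbiguousReversalError,
    CapsgateError,
    NoReversalError,
    ParameterError,
)

F = 96485.33212  # C/mol
R_J = 8.31446261815  # J/(mol*K)


class RampIV:
    """Current-voltage relation from a voltage-ramp recording.

    Voltage in mV (strictly monotone over the ramp), current in pA.
    """

    def __init__(self, voltage_mV, current_pA, meta=None):
        self.voltage_mV = np.asarray(voltage_mV, dtype=float)
        self.current_pA = np.asarray(current_pA, dtype=float)
        if self.voltage_mV.shape != self.current_pA.shape:
            raise ParameterError("voltage and current must have equal length")
        dv = np.diff(self.voltage_mV)
        if dv.size and not (np.all(dv > 0) or np.all(dv < 0)):
            raise ParameterError("voltage must be strictly monotone over the ramp")
        self.meta = dict(meta or {})

    def to_tsv(self, path_or_buf=None):
        import io

        import pandas as pd

        buf = io.StringIO()
        for k, v in self.meta.items():
            buf.write(f"# {k}={v}\n")
        pd.DataFrame(
            {"voltage_mV": self.voltage_mV, "current_pA": self.current_pA}
        ).to_csv(buf, sep="\t", index=False, float_format="%.6g")
        text = buf.getvalue()
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)
        return None

    @classmethod
    def from_tsv(cls, path_or_buf) -> "RampIV":
        import io

        import pandas as pd

        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta, body = {}, []
        for line in text.splitlines():
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
            elif line.strip():
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
        return cls(df["voltage_mV"].to_numpy(), df["current_pA"].to_numpy(), meta)


def _ghk_flux_sum(u: float, perm_ratios: dict, ions: IonConditions) -> float:
    """Sum of GHK fluxes at reduced potential u (positive = outward)."""
    total = 0.0
    for ion in ions:
        P = perm_ratios.get(ion.name, 0.0)
        if P == 0.0:
            continue
        z = ion.valence
        zu = z * u
        if abs(zu) < 1e-9:
            # limit u -> 0 of z^2 u (c_in - c_out e^{-zu})/(1 - e^{-zu})
            term = z * (ion.conc_in_mM - ion.conc_out_mM) \
                + z * zu * (ion.conc_in_mM + ion.conc_out_mM) / 2.0
        else:
            em = np.exp(-zu)
            term = z * zu * (ion.conc_in_mM - ion.conc_out_mM * em) / (1.0 - em)
        total += P * term
    return total


def ghk_erev(perm_ratios: dict, ions: IonConditions,
             v_range_mV: tuple = (-200.0, 200.0)) -> float:
    """Reversal potential (mV) of the extended GHK equation.

    ``perm_ratios`` maps species name to relative permeability (any common
    scale); the root of the summed flux is located by bisection within
    ``v_range_mV``.
    """
    if not any(p > 0 for p in perm_ratios.values()):
        raise ParameterError("at least one species must have nonzero permeability")
    RT_F = R_J * ions.temperature_K / F  # volts
    lo, hi = (v * 1e-3 / RT_F for v in v_range_mV)
    f_lo, f_hi = _ghk_flux_sum(lo, perm_ratios, ions), _ghk_flux_sum(hi, perm_ratios, ions)
    if f_lo == 0.0:
        return v_range_mV[0]
    if f_hi == 0.0:
        return v_range_mV[1]
    if np.sign(f_lo) == np.sign(f_hi):
        raise CapsgateError(
            f"no GHK reversal potential in [{v_range_mV[0]}, {v_range_mV[1]}] mV"
        )
    u = brentq(_ghk_flux_sum, lo, hi, args=(perm_ratios, ions), xtol=1e-12)
    return u * RT_F * 1e3


def ghk_permeability_ratio(e_rev_mV: float, ions: IonConditions,
                           pair: tuple[str, str]) -> float:
    """Permeability ratio P_test/P_ref from a measured reversal potential.

    The bi-ionic divalent-inside / monovalent-outside arrangement (the
    selectivity protocol here) uses the closed Fatt-Ginsborg form; a
    monovalent/monovalent bi-ionic uses the Nernst-type form; any other
    invertible configuration falls back to a numeric 1-D search that
    round-trips through :func:`ghk_erev`.
    """
    test_name, ref_name = pair
    by_name = {i.name: i for i in ions}
    try:
        test, ref = by_name[test_name], by_name[ref_name]
    except KeyError as e:
        raise ParameterError(f"species {e} not present in the ionic conditions")
    u = e_rev_mV * 1e-3 * F / (R_J * ions.temperature_K)

    bi_ionic = (
        len(ions.ions) == 2
        and test.conc_out_mM == 0 and ref.conc_in_mM == 0
        and test.conc_in_mM > 0 and ref.conc_out_mM > 0
    )
    if bi_ionic and test.valence == 2 and ref.valence == 1:
        em = np.exp(-u)
        ratio = ref.conc_out_mM * em * (1.0 + em) / (4.0 * test.conc_in_mM)
    elif bi_ionic and test.valence == 1 and ref.valence == 1:
        ratio = ref.conc_out_mM * np.exp(-u) / test.conc_in_mM
    else:
        ratio = _numeric_ratio(e_rev_mV, ions, test_name, ref_name)
    if ratio <= 0:
        raise CapsgateError("non-invertible configuration: ratio not positive")
    return float(ratio)


def _numeric_ratio(e_rev_mV, ions, test_name, ref_name):
    """Invert the flux-sum condition for the test species' permeability.

    At fixed reversal potential the GHK flux sum is linear in each
    permeability, so with the reference (and any other) species at
    relative permeability 1 the test permeability is
    r = -(sum of other fluxes) / (test flux term).
    """
    u = e_rev_mV * 1e-3 * F / (R_J * ions.temperature_K)
    others = {i.name: 1.0 for i in ions if i.name != test_name}
    other_sum = _ghk_flux_sum(u, others, ions)
    test_term = _ghk_flux_sum(u, {test_name: 1.0}, ions)
    if test_term == 0.0:
        raise CapsgateError(
            "numeric permeability-ratio inversion failed: the test species "
            "carries no flux at this potential"
        )
    return -other_sum / test_term


def extract_erev(iv: RampIV, window_mV: float = 10.0, degree: int = 3) -> float:
    """Reversal potential from a ramp I-V by local polynomial root finding.

    A polynomial of ``degree`` is fitted to the points within ``window_mV``
    of each zero crossing of the current; the real root inside the window is
    returned. Multiple distinct crossings raise an ambiguity error listing
    the candidates.
    """
    v, i = iv.voltage_mV, iv.current_pA
    if v[0] > v[-1]:
        v, i = v[::-1], i[::-1]
    sign = np.sign(i)
    nz = sign != 0
    crossings = np.nonzero(np.diff(sign[nz]) != 0)[0]
    v_nz = v[nz]
    if crossings.size == 0:
        raise NoReversalError("current does not change sign within the ramp")
    cross_vs = []
    for k in crossings:
        vc = 0.5 * (v_nz[k] + v_nz[k + 1])
        if not any(abs(vc - x) < window_mV / 2 for x in cross_vs):
            cross_vs.append(vc)

    roots = []
    for vc in cross_vs:
        m = np.abs(v - vc) <= window_mV
        if m.sum() <= degree:
            m = np.abs(v - vc) <= 3 * window_mV
        deg = min(degree, m.sum() - 1)
        coef = np.polynomial.polynomial.polyfit(v[m] - vc, i[m], deg)
        rr = np.polynomial.polynomial.polyroots(coef)
        rr = rr[np.abs(rr.imag) < 1e-8].real + vc
        rr = rr[(rr >= v[m].min()) & (rr <= v[m].max())]
        if rr.size:
            # root nearest the sign change
            roots.append(float(rr[np.argmin(np.abs(rr - vc))]))
    if not roots:
        raise NoReversalError("polynomial fit found no root near the sign change")
    uniq = []
    for r in roots:
        if not any(abs(r - x) < 0.5 for x in uniq):
            uniq.append(r)
    if len(uniq) > 1:
        raise AmbiguousReversalError(
            f"multiple zero crossings at {[round(x, 2) for x in uniq]} mV", uniq
        )
    return uniq[0]


__all__ = [
    "RampIV", "ghk_erev", "ghk_permeability_ratio", "extract_erev",
    "Ion", "IonConditions", "F", "R_J",
]
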