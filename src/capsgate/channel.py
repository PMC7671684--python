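"""Core data containers for gating analysis.

Units follow patch-clamp convention throughout the package: time in ms,
current in pA, voltage in mV, conductance in pS, concentration in µM,
temperature in K.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError

#: Methods-standard acquisition: 10 kHz sampling, 2.9 kHz low-pass corner,
#: +80 mV test potential, room temperature (~22 degC).
DEFAULT_SAMPLING_HZ = 10_000.0
DEFAULT_FILTER_HZ = 2_900.0
DEFAULT_VOLTAGE_MV = 80.0
DEFAULT_TEMPERATURE_K = 295.15


@dataclass(frozen=True)
class ChannelModel:
    """Three-state allosteric gating parameterization C <-> C.L <-> O.L.

    Parameters
    ----------
    K_D : float
        Dissociation constant of the ligand-binding step, µM.
    L : float
        Equilibrium constant of the liganded opening step (dimensionless);
        the maximal open probability is ``L / (1 + L)``.
    g : float
        Single-channel conductance, pS.
    E_rev : float
        Reversal potential, mV.
    """

    K_D: float
    L: float
    g: float = 100.0
    E_rev: float = 0.0

    def __post_init__(self):
        if not self.K_D > 0:
            raise ParameterError(f"K_D must be positive, got {self.K_D}")
        if self.L < 0:
            raise ParameterError(f"L must be non-negative, got {self.L}")
        if not self.g > 0:
            raise ParameterError(f"g must be positive, got {self.g}")

    @property
    def po_max(self) -> float:
        """Open probability at saturating ligand, L/(1+L)."""
        return self.L / (1.0 + self.L)

    @property
    def ec50(self) -> float:
        """Half-activation concentration of the three-state model, K_D/(1+L)."""
        return self.K_D / (1.0 + self.L)

    def unit_current(self, voltage_mV: float) -> float:
        """Single-channel current amplitude i = g*(V - E_rev), in pA."""
        return self.g * (voltage_mV - self.E_rev) * 1e-3


@dataclass(frozen=True)
class DwellSequence:
    """Ground-truth alternating open/closed dwell sequence.

    ``levels`` holds 0 (closed) / 1 (open) per dwell; ``durations_ms`` the
    matching dwell lengths. This is the exact Markov-chain trajectory before
    sampling, used as the oracle for idealization tests.
    """

    levels: np.ndarray
    durations_ms: np.ndarray
    total_duration_ms: float
    seed: int | None = None

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=np.int8)
        durations = np.asarray(self.durations_ms, dtype=float)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "durations_ms", durations)
        if levels.shape != durations.shape:
            raise ParameterError("levels and durations must have equal length")
        if durations.size and not np.all(durations > 0):
            raise ParameterError("dwell durations must be positive")

    @property
    def transition_times_ms(self) -> np.ndarray:
        """Times of state changes (cumulative dwell boundaries, excluding 0)."""
        return np.cumsum(self.durations_ms)[:-1]

    def open_probability(self) -> float:
        """Time-weighted open fraction of the exact trajectory."""
        open_time = float(self.durations_ms[self.levels == 1].sum())
        return open_time / float(self.durations_ms.sum())


@dataclass
class Recording:
    """A sampled current trace plus acquisition metadata.

    The time base is an implicit uniform grid ``t_k = k / sampling_hz``
    (stored in ms via the ``time_ms`` property).
    """

    current_pA: np.ndarray
    voltage_mV: float = DEFAULT_VOLTAGE_MV
    sampling_hz: float = DEFAULT_SAMPLING_HZ
    filter_hz: float = DEFAULT_FILTER_HZ
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.sampling_hz <= 0:
            raise ParameterError("sampling_hz must be positive")
        if self.filter_hz is not None and self.sampling_hz < 2.0 * self.filter_hz:
            raise ConfigurationError(
                f"sampling rate {self.sampling_hz} Hz must be at least twice "
                f"the filter corner {self.filter_hz} Hz"
            )

    @property
    def n_samples(self) -> int:
        return self.current_pA.size

    @property
    def dt_ms(self) -> float:
        return 1e3 / self.sampling_hz

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)

    # ---- TSV round trip: "# key=value" header then time_ms, current_pA ----

    def to_tsv(self, path_or_buf=None):
        """Serialize as TSV with a ``# key=value`` comment header."""
        header = {
            "voltage_mV": self.voltage_mV,
            "sampling_hz": self.sampling_hz,
            "filter_hz": self.filter_hz,
        }
        if self.seed is not None:
            header["seed"] = self.seed
        header.update(self.meta)
        buf = io.StringIO()
        for k, v in header.items():
            buf.write(f"# {k}={v}\n")
        pd.DataFrame(
            {"time_ms": self.time_ms, "current_pA": self.current_pA}
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
    def from_tsv(cls, path_or_buf) -> "Recording":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta = {}
        body_lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            elif line.strip():
                body_lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
        seed = meta.pop("seed", None)
        known = {
            "voltage_mV": float(meta.pop("voltage_mV", DEFAULT_VOLTAGE_MV)),
            "sampling_hz": float(meta.pop("sampling_hz", DEFAULT_SAMPLING_HZ)),
            "filter_hz": float(meta.pop("filter_hz", DEFAULT_FILTER_HZ)),
        }
        return cls(
            current_pA=df["current_pA"].to_numpy(),
            seed=None if seed is None else int(seed),
            meta=meta,
            **known,
        )


@dataclass(frozen=True)
class Ion:
    """One ionic species with inside/outside concentrations in mM."""

    name: str
    valence: int
    conc_in_mM: float
    conc_out_mM: float

    def __post_init__(self):
        if self.conc_in_mM < 0 or self.conc_out_mM < 0:
            raise ParameterError("concentrations must be non-negative")
        if self.valence == 0:
            raise ParameterError("valence must be a nonzero integer")


@dataclass(frozen=True)
class IonConditions:
    """Recording-solution composition on both membrane faces.

    Only species intended to be permeant are listed; buffers (EGTA, HEPES)
    and, for this cation channel, chloride are treated as impermeant and
    simply omitted.
    """

    ions: tuple
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        ions = tuple(self.ions)
        object.__setattr__(self, "ions", ions)
        if not ions:
            raise ParameterError("at least one ionic species is required")
        if self.temperature_K <= 0:
            raise ParameterError("temperature must be positive")
        if not any(i.conc_in_mM > 0 for i in ions):
            raise ParameterError("need at least one permeant species inside")
        if not any(i.conc_out_mM > 0 for i in ions):
            raise ParameterError("need at least one permeant species outside")

    def __iter__(self):
        return iter(self.ions)

    def swapped(self) -> "IonConditions":
        """Exchange inside and outside solutions (for antisymmetry checks)."""
        return IonConditions(
            tuple(
                Ion(i.name, i.valence, i.conc_out_mM, i.conc_in_mM)
                for i in self.ions
            ),
            self.temperature_K,
        )


def sodium_vs_divalent(divalent: str = "Ca", na_out_mM: float = 140.0,
                       div_in_mM: float = 70.0,
                       temperature_K: float = DEFAULT_TEMPERATURE_K) -> IonConditions:
    """Bi-ionic condition used for selectivity: 140 mM NaCl outside against
    70 mM CaCl2 (or MgCl2) inside, chloride impermeant."""
    return IonConditions(
        (
            Ion("Na", 1, 0.0, na_out_mM),
            Ion(divalent, 2, div_in_mM, 0.0),
        ),
        temperature_K,
    )
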