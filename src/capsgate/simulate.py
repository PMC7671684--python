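"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here under the
recording conditions of the study: two-state Markov gating rendered at
10 kHz with Gaussian noise and a 2.9 kHz low-pass emulation, three-state
Hill-shaped concentration-response curves, single-exponential tail currents,
GHK-governed ramp I-V under the 140 mM NaCl vs 70 mM divalent solutions, and
deterministic toy structures with analytically known geometry.

All generators take an explicit integer seed, use a single named
``numpy.random.Generator`` per call, record the seed in the output metadata,
and are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .allosteric import predict_po
from .channel import (
    ChannelModel,
    DEFAULT_FILTER_HZ,
    DEFAULT_SAMPLING_HZ,
    DEFAULT_VOLTAGE_MV,
    DwellSequence,
    IonConditions,
    Recording,
)
from .dose_response import DoseResponseCurve
from .errors import ConfigurationError, ParameterError
from .selectivity import RampIV, ghk_erev

#: Gaussian filter emulation of a single-pole-corner low-pass: a Gaussian
#: kernel with sigma_t = 0.1325 / f_c has a -3 dB corner at f_c.
GAUSSIAN_SIGMA_FC = 0.1325


def _filter_sigma_samples(filter_hz: float, sampling_hz: float) -> float:
    return GAUSSIAN_SIGMA_FC / filter_hz * sampling_hz


def simulate_dwells(open_rate_per_ms: float, close_rate_per_ms: float,
                    duration_ms: float, rng: np.random.Generator,
                    seed: int | None = None) -> DwellSequence:
    """Gillespie trajectory of a two-state (closed/open) Markov chain.

    Dwell durations are exponential with mean 1/close_rate (open) and
    1/open_rate (closed); the initial state is drawn from the stationary
    distribution, so the chain's long-run open probability is
    open_rate / (open_rate + close_rate).
    """
    po = open_rate_per_ms / (open_rate_per_ms + close_rate_per_ms)
    state = 1 if rng.random() < po else 0
    means = {0: 1.0 / open_rate_per_ms, 1: 1.0 / close_rate_per_ms}
    levels, durations = [], []
    t = 0.0
    # draw in blocks for speed; alternation makes the sequence deterministic
    while t < duration_ms:
        d = rng.exponential(means[state])
        if t + d > duration_ms:
            d = duration_ms - t
        levels.append(state)
        durations.append(d)
        t += d
        state = 1 - state
    return DwellSequence(np.array(levels, dtype=np.int8),
                         np.array(durations), duration_ms, seed=seed)


def render_dwells(dwells: DwellSequence, amplitude_pA: float,
                  sampling_hz: float = DEFAULT_SAMPLING_HZ) -> np.ndarray:
    """Noise-free sampled current of a dwell sequence.

    Closed maps to 0 pA, open to ``amplitude_pA``. A transition at time t is
    assigned to the sample containing t (floor convention): sample k reports
    the level active at t_k = k/fs.
    """
    dt_ms = 1e3 / sampling_hz
    n = int(np.floor(dwells.total_duration_ms / dt_ms))
    t = np.arange(n) * dt_ms
    edges = np.concatenate([[0.0], np.cumsum(dwells.durations_ms)])
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                  len(dwells.levels) - 1)
    return amplitude_pA * dwells.levels[idx].astype(float)


def simulate_single_channel(
    model: ChannelModel,
    open_rate_per_ms: float,
    close_rate_per_ms: float,
    duration_ms: float,
    voltage_mV: float = DEFAULT_VOLTAGE_MV,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
    sampling_hz: float = DEFAULT_SAMPLING_HZ,
    filter_hz: float | None = DEFAULT_FILTER_HZ,
) -> tuple[DwellSequence, Recording]:
    """Simulate a single-channel recording with exact dwell ground truth.

    The two-state chain is sampled by the Gillespie method, rendered on the
    sampling grid at unit amplitude i = g*(V - E_rev), white Gaussian noise
    of ``noise_sd_pA`` is added, and the stated low-pass corner is emulated
    with a Gaussian kernel.
    """
    if open_rate_per_ms <= 0 or close_rate_per_ms <= 0:
        raise ParameterError("transition rates must be positive")
    if duration_ms <= 0:
        raise ParameterError("duration must be positive")
    if noise_sd_pA < 0:
        raise ParameterError("noise SD must be non-negative")
    if filter_hz is not None and sampling_hz < 2.0 * filter_hz:
        raise ConfigurationError(
            "sampling rate must be at least twice the filter corner"
        )
    rng = np.random.default_rng(seed)
    dwells = simulate_dwells(open_rate_per_ms, close_rate_per_ms, duration_ms,
                             rng, seed=seed)
    amp = model.unit_current(voltage_mV)
    trace = render_dwells(dwells, amp, sampling_hz)
    if noise_sd_pA > 0:
        trace = trace + rng.normal(0.0, noise_sd_pA, size=trace.size)
    if filter_hz is not None:
        trace = gaussian_filter1d(
            trace, _filter_sigma_samples(filter_hz, sampling_hz), mode="nearest"
        )
    rec = Recording(
        current_pA=trace, voltage_mV=voltage_mV, sampling_hz=sampling_hz,
        filter_hz=filter_hz, seed=seed,
        meta={"open_rate_per_ms": open_rate_per_ms,
              "close_rate_per_ms": close_rate_per_ms,
              "amplitude_pA": amp},
    )
    return dwells, rec


def simulate_dose_response(model: ChannelModel, concentrations_uM,
                           noise_sd: float = 0.0,
                           seed: int = 0,
                           noise_mode: str = "proportional") -> DoseResponseCurve:
    """Three-state Po(c) evaluated at the given concentrations plus noise.

    ``noise_sd`` is a Gaussian noise fraction: by default proportional to the
    response (matching how the scatter of normalized current measurements
    scales with signal), i.e. ``Po * (1 + N(0, noise_sd))``; with
    ``noise_mode="additive"`` it is an absolute SD on the Po scale. With
    ``noise_sd = 0`` the output equals
    :func:`capsgate.allosteric.predict_po` exactly.
    """
    c = np.asarray(concentrations_uM, dtype=float)
    if c.size == 0:
        raise ParameterError("empty concentration list")
    if np.any(c <= 0):
        raise ParameterError("concentrations must be positive")
    if np.any(np.diff(c) <= 0):
        raise ParameterError("concentrations must be sorted ascending")
    if noise_sd < 0:
        raise ParameterError("noise SD must be non-negative")
    if noise_mode not in ("proportional", "additive"):
        raise ParameterError(f"unknown noise_mode {noise_mode!r}")
    po = predict_po(model, c)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=c.size)
        resp = po * (1.0 + eps) if noise_mode == "proportional" else po + eps
    else:
        resp = po
    return DoseResponseCurve(c, resp, meta={"seed": seed, "noise_sd": noise_sd,
                                            "noise_mode": noise_mode,
                                            "K_D": model.K_D, "L": model.L})


def simulate_tail_current(amplitude_pA: float, tau_ms: float, duration_ms: float,
                          noise_sd_pA: float = 0.0, seed: int = 0,
                          sampling_hz: float = DEFAULT_SAMPLING_HZ,
                          voltage_mV: float = DEFAULT_VOLTAGE_MV) -> Recording:
    """Single-exponential tail-current decay A*exp(-t/tau) with Gaussian noise."""
    if tau_ms <= 0:
        raise ParameterError("tau must be positive")
    if amplitude_pA == 0:
        raise ParameterError("amplitude must be nonzero")
    n = int(np.floor(duration_ms * sampling_hz / 1e3))
    if n == 0:
        raise ParameterError("duration too short: empty trace")
    t = np.arange(n) * 1e3 / sampling_hz
    trace = amplitude_pA * np.exp(-t / tau_ms)
    rng = np.random.default_rng(seed)
    if noise_sd_pA > 0:
        trace = trace + rng.normal(0.0, noise_sd_pA, size=n)
    return Recording(current_pA=trace, voltage_mV=voltage_mV,
                     sampling_hz=sampling_hz, filter_hz=None, seed=seed,
                     meta={"tau_ms": tau_ms, "amplitude_pA": amplitude_pA})


def simulate_ramp_iv(perm_ratios: dict, ions: IonConditions,
                     g_scale_pS: float = 100.0,
                     ramp: tuple = (-100.0, 100.0, 500.0),
                     noise_sd_pA: float = 0.0, seed: int = 0,
                     sampling_hz: float = DEFAULT_SAMPLING_HZ) -> RampIV:
    """Linearised ramp I-V whose zero crossing sits at the GHK reversal potential.

    I(V) = g_scale * (V - E_rev) with E_rev from the extended GHK voltage
    equation under ``ions``; the default ramp is -100 to +100 mV in 500 ms.
    """
    if not any(p > 0 for p in perm_ratios.values()):
        raise ParameterError("degenerate conductor: all permeabilities zero")
    v0, v1, dur_ms = ramp
    if dur_ms <= 0:
        raise ParameterError("ramp duration must be positive")
    e_rev = ghk_erev(perm_ratios, ions)
    n = int(np.floor(dur_ms * sampling_hz / 1e3))
    v = np.linspace(v0, v1, n)
    i = g_scale_pS * (v - e_rev) * 1e-3  # pS * mV -> pA
    rng = np.random.default_rng(seed)
    if noise_sd_pA > 0:
        i = i + rng.normal(0.0, noise_sd_pA, size=n)
    return RampIV(v, i, meta={"e_rev_mV": e_rev, "seed": seed,
                              "g_scale_pS": g_scale_pS})


def make_toy_structure(kind: str, **params):
    """Deterministic toy structures for the structural-metrics module.

    kinds
    -----
    ``helix``
        CA-trace alpha-helix with N/C/O backbone satellites; params:
        n_res (default 20), rise_A (1.5), twist_deg (100), radius_A (2.3),
        chain ("A").
    ``pore_ring_stack``
        Stacked rings of atoms around the z axis with analytically known
        pore radius per ring; params: rings = [(z_A, radius_A, n_atoms), ...],
        element ("C").
    ``duplicate_with_transform``
        Rigid copy of ``base``; params: base (StructureModel),
        rotation_deg, axis ("z"), translation_A (3-vector).
    """
    from .structure import StructureModel, make_helix, make_ring_stack

    if kind == "helix":
        return make_helix(**params)
    if kind == "pore_ring_stack":
        return make_ring_stack(**params)
    if kind == "duplicate_with_transform":
        base: StructureModel = params["base"]
        angle = np.deg2rad(params.get("rotation_deg", 0.0))
        axis = params.get("axis", "z")
        t = np.asarray(params.get("translation_A", (0.0, 0.0, 0.0)), float)
        c, s = np.cos(angle), np.sin(angle)
        rot = {
            "z": np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]),
            "y": np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]]),
            "x": np.array([[1, 0, 0], [0, c, -s], [0, s, c]]),
        }[axis]
        return base.transformed(rot, t)
    raise ParameterError(f"unknown toy-structure kind {kind!r}")
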