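"""Surrogate surface-EMG generator with known ground truth.

Real stump recordings behind this kind of analysis are rarely deposited, so
every downstream stage here is exercised on surrogate data whose correlation
groups and causal directions are planted and therefore recoverable.

The signal model treats surface EMG as a band-limited stochastic carrier
multiplied by a slow activation envelope:

* **Carrier.** White Gaussian noise band-pass filtered to ``band`` (default
  20-450 Hz).  Channels assigned to the same latent source share a carrier:
  ``carrier_c = g_c * S_c + (1 - g_c) * eps_c`` with mixing weight
  ``g_c = group_strength``, where the shared part ``S_c`` itself blends the
  channel's group source with one global source common to all channels
  (weight ``global_mix``).  The global component gives cross-group pairs a
  graded baseline dependence — real muscle networks are never block
  diagonal — while keeping both limiting cases exact: ``g_c = 0`` is fully
  independent and ``g_c = 1`` makes same-group channels identical.
* **Phase envelope.** Each movement repetition is lift (linear ramp up),
  hold (plateau) and lower (ramp down); rest periods between repetition
  blocks are omitted because they carry no analysis weight.
* **Slow modulation.** On top of the deterministic phase envelope each
  channel carries a slow (tick rate 20 Hz, smoothed) chaotic amplitude
  modulation built from logistic-map streams: a global stream shared by all
  channels, a per-group stream, and a per-channel private stream, mixed with
  the same weight ``g_c``.  This gives within-group envelope co-modulation
  on top of the shared carrier, and a graded baseline dependence between
  groups — both features of real multichannel EMG.
* **Planted causality.** A directed coupling ``driver -> target`` blends a
  chaotic-oscillator component (Roessler-type, natural frequency inside
  the EMG band) into each coupled channel's carrier while band-stopping
  the stochastic part over the chaos band, so the oscillator owns that
  band exclusively: the driver's oscillator runs free and the target's —
  detuned in frequency — receives a weak, lagged diffusive force from the
  driver's observable (lag default 5 ms).  Cross-mapping recovers the
  direction of such coupling robustly, whereas couplings planted in the
  amplitude envelope of a stochastic carrier are provably drowned by
  envelope-estimation noise at these recording lengths.  Coupled channels
  keep their group's slow co-modulation, so they stay embedded in the
  functional network.

Everything is drawn from a single seeded generator per call, so identical
configurations give bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as _signal

from .recording import EMGRecording, PhaseSpan, default_labels, PHASES

__all__ = [
    "SimConfig",
    "ChannelCoupling",
    "CouplingSpec",
    "TruthRecord",
    "ConfigurationError",
    "NumericalInstabilityError",
    "generate_recording",
    "generate_coupled_logistic",
    "area_group_assignment",
    "planted_sensor_scenario",
    "movement_condition_configs",
]

#: tick rate (Hz) of the slow modulation streams
MODULATION_TICK_HZ = 20.0
#: cutoff (Hz) of the smoothing filter applied to the upsampled modulation
MODULATION_SMOOTH_HZ = 8.0
#: logistic growth-rate range for free-running modulation streams
MODULATION_R_RANGE = (3.7, 3.9)
#: fraction of a channel's modulation depth applied to its chaotic
#: component (deep multiplicative modulation would mask the dynamics)
CHAOS_MOD_FRACTION = 0.45
#: chaotic-carrier (Roessler) parameters: base cycle frequency in Hz,
#: angular-speed factors for driver and successive targets, and the
#: classic (a, b, c) coefficients
CHAOS_BASE_HZ = 160.0
CHAOS_W_DRIVER = 1.0
CHAOS_W_TARGETS = (1.2, 1.3, 1.15, 1.25)
#: angular-speed factors cycled over free-running (uncoupled) chaotic
#: channels; detuned so no two oscillators share a frequency exactly
CHAOS_W_FREE = (0.9, 1.05, 0.85, 1.1, 0.95, 1.08, 0.88, 1.02)
CHAOS_ABC = (0.2, 0.2, 5.7)
#: amplitude weight of the chaotic component in a chaotic channel's carrier;
#: the remainder keeps the channel's ordinary group/private noise mix so
#: chaotic channels stay embedded in the functional network
CHAOS_MIX = 0.85
#: frequency band (Hz) occupied by the chaotic component — the causality
#: stage isolates this band before state-space reconstruction
CHAOS_BAND = (50.0, 320.0)
#: band-stop applied to a chaotic channel's stochastic carrier part so the
#: chaos band belongs to the oscillator alone (guard margins vs CHAOS_BAND)
CHAOS_NOTCH = (40.0, 360.0)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class NumericalInstabilityError(RuntimeError):
    """A generated trajectory left the valid (0, 1) interval."""


@dataclass(frozen=True)
class ChannelCoupling:
    """Planted directed influence of one channel's dynamics on another's.

    ``strength`` is the diffusive coupling coefficient of the target's
    chaotic carrier oscillator; weak values (around 0.1) give detectable
    unidirectional causality without synchronizing the pair.
    """

    driver: str
    target: str
    strength: float = 0.1

    def __post_init__(self) -> None:
        if self.driver == self.target:
            raise ConfigurationError("coupling driver and target must differ")
        if not 0.0 < self.strength <= 0.5:
            raise ConfigurationError(
                f"coupling strength {self.strength} outside (0, 0.5]"
            )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one surrogate recording.

    Defaults mirror the acquisition protocol the generator emulates:
    33 channels at 2000 Hz, ten repetitions of a 1.5 s / 1.0 s / 1.5 s
    lift-hold-lower movement.
    """

    n_channels: int = 33
    rate: float = 2000.0
    phase_durations: tuple[float, float, float] = (1.5, 1.0, 1.5)
    n_repetitions: int = 10
    condition: str = "appropriate"
    group_assignment: Mapping[str, int] | None = None
    group_strength: float | Mapping[str, float] = 0.5
    noise_sd: float = 1.0
    band: tuple[float, float] = (20.0, 450.0)
    global_mix: float = 0.6
    mod_depth: float = 0.5
    couplings: tuple[ChannelCoupling, ...] = ()
    chaotic_channels: tuple[str, ...] = ()
    coupling_lag: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("need at least 2 channels")
        low, high = self.band
        if not 0 < low < high:
            raise ConfigurationError(f"invalid band {self.band}")
        if self.rate <= 2 * high:
            raise ConfigurationError(
                f"rate {self.rate} Hz must exceed twice the band upper edge {high} Hz"
            )
        if any(d <= 0 for d in self.phase_durations):
            raise ConfigurationError("phase durations must be positive")
        if self.n_repetitions < 1:
            raise ConfigurationError("need at least one repetition")
        for g in self._strengths():
            if not 0.0 <= g <= 1.0:
                raise ConfigurationError("group_strength must lie in [0, 1]")
        if not 0.0 <= self.global_mix <= 1.0:
            raise ConfigurationError("global_mix must lie in [0, 1]")
        if not 0.0 <= self.mod_depth < 1.0:
            raise ConfigurationError("mod_depth must lie in [0, 1)")
        tgt = [c.target for c in self.couplings]
        if len(set(tgt)) != len(tgt):
            raise ConfigurationError("each channel may be the target of one coupling")
        if set(tgt) & {c.driver for c in self.couplings}:
            raise ConfigurationError("chained couplings (driver that is also a target) unsupported")

    # -- resolved views -------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return default_labels(self.n_channels)

    def groups(self) -> dict[str, int]:
        """Channel -> latent-source index; defaults to the six-area layout."""
        if self.group_assignment is not None:
            mapping = dict(self.group_assignment)
            missing = set(self.labels) - set(mapping)
            if missing:
                raise ConfigurationError(f"group_assignment misses channels {sorted(missing)}")
            return {lab: mapping[lab] for lab in self.labels}
        if self.n_channels == 33:
            return area_group_assignment()
        return {lab: i for i, lab in enumerate(self.labels)}

    def _strengths(self) -> list[float]:
        if isinstance(self.group_strength, Mapping):
            return [float(self.group_strength.get(lab, 0.5)) for lab in self.labels]
        return [float(self.group_strength)] * self.n_channels

    def strength_of(self, label: str) -> float:
        return self._strengths()[self.labels.index(label)]


def area_group_assignment(n_channels: int = 33) -> dict[str, int]:
    """Default latent-source layout: six electrode areas (two per surface).

    Front V1-V6 / V7-V12, back V13-V17 / V18-V23, side V24-V28 / V29-V33.
    """
    if n_channels != 33:
        raise ConfigurationError("area layout is defined for 33 channels")
    bounds = [(1, 6, 0), (7, 12, 1), (13, 17, 2), (18, 23, 3), (24, 28, 4), (29, 33, 5)]
    out: dict[str, int] = {}
    for lo, hi, gid in bounds:
        for i in range(lo, hi + 1):
            out[f"V{i}"] = gid
    return out


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth planted in one surrogate recording."""

    true_groups: Mapping[str, int]
    true_edges: tuple[tuple[str, str], ...]
    parameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = list(self.true_groups)
        if len(labels) != len(set(labels)):
            raise ValueError("every channel must appear exactly once in true_groups")


# ---------------------------------------------------------------------------
# recording generation
# ---------------------------------------------------------------------------


def _phase_counts(config: SimConfig) -> list[int]:
    return [int(round(d * config.rate)) for d in config.phase_durations]


def base_envelope(config: SimConfig) -> tuple[np.ndarray, tuple[PhaseSpan, ...]]:
    """Deterministic per-phase amplitude envelope and its span annotations.

    Lift ramps 0 -> 1, hold stays at 1, lower ramps 1 -> 0.
    """
    counts = _phase_counts(config)
    rep = np.concatenate(
        [
            np.linspace(0.0, 1.0, counts[0], endpoint=False),
            np.ones(counts[1]),
            np.linspace(1.0, 0.0, counts[2], endpoint=False),
        ]
    )
    env = np.tile(rep, config.n_repetitions)
    spans = []
    offset = 0
    for r in range(config.n_repetitions):
        for phase, cnt in zip(PHASES, counts):
            spans.append(PhaseSpan(repetition=r, phase=phase, start=offset, stop=offset + cnt))
            offset += cnt
    return env, tuple(spans)


def _bandlimited_noise(rng: np.random.Generator, n: int, sos: np.ndarray) -> np.ndarray:
    x = _signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _logistic_stream(rng: np.random.Generator, n: int, burn: int = 200) -> np.ndarray:
    """Free-running chaotic logistic map, values in (0, 1)."""
    r = rng.uniform(*MODULATION_R_RANGE)
    x = rng.uniform(0.2, 0.8)
    out = np.empty(n)
    for _ in range(burn):
        x = r * x * (1.0 - x)
    for k in range(n):
        x = r * x * (1.0 - x)
        out[k] = x
    return out


def _rossler_core(
    n: int,
    sub: int,
    h: float,
    w: float,
    a: float,
    b: float,
    c: float,
    k: float,
    drive: np.ndarray,
    state: np.ndarray,
) -> np.ndarray:
    """RK4 integration of a (possibly driven) Roessler oscillator.

    The drive observable is held constant within each output sample; the
    diffusive force ``k (drive - x)`` enters the x-equation.  Returns the
    x-observable at sample resolution.
    """
    out = np.empty(n)
    x, y, z = state[0], state[1], state[2]
    for i in range(n):
        d = drive[i]
        for _ in range(sub):
            k1x = -w * y - z + k * (d - x)
            k1y = w * x + a * y
            k1z = b + z * (x - c)
            x2 = x + 0.5 * h * k1x
            y2 = y + 0.5 * h * k1y
            z2 = z + 0.5 * h * k1z
            k2x = -w * y2 - z2 + k * (d - x2)
            k2y = w * x2 + a * y2
            k2z = b + z2 * (x2 - c)
            x3 = x + 0.5 * h * k2x
            y3 = y + 0.5 * h * k2y
            z3 = z + 0.5 * h * k2z
            k3x = -w * y3 - z3 + k * (d - x3)
            k3y = w * x3 + a * y3
            k3z = b + z3 * (x3 - c)
            x4 = x + h * k3x
            y4 = y + h * k3y
            z4 = z + h * k3z
            k4x = -w * y4 - z4 + k * (d - x4)
            k4y = w * x4 + a * y4
            k4z = b + z4 * (x4 - c)
            x = x + (h / 6.0) * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
            y = y + (h / 6.0) * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
            z = z + (h / 6.0) * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
        out[i] = x
    state[0], state[1], state[2] = x, y, z
    return out


try:  # numba gives a ~100x faster integrator; the pure-Python path is exact
    from numba import njit as _njit

    _rossler_core = _njit(cache=False)(_rossler_core)
except ImportError:  # pragma: no cover
    pass


def _chaotic_carrier(
    rng: np.random.Generator,
    total: int,
    rate: float,
    w: float,
    k: float = 0.0,
    drive: np.ndarray | None = None,
    burn: int = 2000,
) -> np.ndarray:
    """Roessler x-observable at sample resolution, standardized.

    ``w`` scales the angular speed (frequency detuning between driver and
    target prevents synchronization); ``drive`` is the driver's observable
    at sample resolution for diffusively forced targets.
    """
    a, b, c = CHAOS_ABC
    speed = 2.0 * np.pi * CHAOS_BASE_HZ / 6.0  # natural cycle ~6 time units
    dt = speed / rate
    sub = max(1, int(np.ceil(dt / 0.05)))
    h = dt / sub
    state = np.array([1.0, 1.0, 1.0]) + rng.uniform(-0.5, 0.5, 3)
    if drive is None:
        drive_full = np.zeros(total + burn)
        k = 0.0
    else:
        drive_full = np.concatenate([np.full(burn, drive[0]), drive])
    out = _rossler_core(total + burn, sub, h, w, a, b, c, k, drive_full, state)
    out = out[burn:]
    if not np.isfinite(out).all():
        raise NumericalInstabilityError(
            f"chaotic carrier diverged (w={w}, k={k}); reduce the coupling strength"
        )
    return out  # natural scale — drivers force targets on this scale


def _smooth_upsample(ticks: np.ndarray, hold: int, total: int, rate: float) -> np.ndarray:
    dense = np.repeat(ticks, hold)[:total]
    sos = _signal.butter(2, MODULATION_SMOOTH_HZ, btype="low", fs=rate, output="sos")
    return _signal.sosfiltfilt(sos, dense)


def generate_recording(config: SimConfig) -> tuple[EMGRecording, TruthRecord]:
    """Generate one surrogate recording plus its planted ground truth.

    Deterministic given ``config`` (all randomness flows from one generator
    seeded with ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    labels = config.labels
    groups = config.groups()
    strengths = dict(zip(labels, config._strengths()))
    counts = _phase_counts(config)
    total = sum(counts) * config.n_repetitions

    env, spans = base_envelope(config)
    sos_band = _signal.butter(4, config.band, btype="band", fs=config.rate, output="sos")

    # shared and private carriers (draw order is fixed: global source, then
    # sorted group ids, then channel order, so seeds reproduce bitwise)
    gamma = config.global_mix
    group_ids = sorted(set(groups.values()))
    global_carrier = _bandlimited_noise(rng, total, sos_band)
    shared = {
        gid: np.sqrt(1.0 - gamma**2) * _bandlimited_noise(rng, total, sos_band)
        + gamma * global_carrier
        for gid in group_ids
    }
    carriers = np.empty((total, config.n_channels))
    for j, lab in enumerate(labels):
        g = strengths[lab]
        own = _bandlimited_noise(rng, total, sos_band)
        carriers[:, j] = g * shared[groups[lab]] + (1.0 - g) * own

    # planted causality: coupled channels blend a chaotic-oscillator
    # component into their carrier; the driver's oscillator runs free, each
    # target's is weakly forced by the driver's lagged observable at a
    # detuned frequency (draw order: config order)
    lag_samples = max(1, int(round(config.coupling_lag * config.rate)))
    delta = CHAOS_MIX
    sos_notch = _signal.butter(6, CHAOS_NOTCH, btype="bandstop", fs=config.rate, output="sos")

    chaos_comp: dict[int, np.ndarray] = {}

    def _blend_chaos(j: int, chaos_raw: np.ndarray) -> None:
        # the chaos band is vacated in the stochastic part so that the
        # oscillator owns it exclusively; outside it the channel keeps its
        # ordinary group/private mix (and hence its network embedding)
        carriers[:, j] = np.sqrt(1.0 - delta**2) * _signal.sosfiltfilt(sos_notch, carriers[:, j])
        chaos = _signal.sosfiltfilt(sos_band, chaos_raw - chaos_raw.mean())
        sd = chaos.std()
        chaos_comp[j] = delta * (chaos / sd if sd > 0 else chaos)

    drivers = {cp.driver for cp in config.couplings}
    target_set = {cp.target for cp in config.couplings}
    for lab in set(config.chaotic_channels) | drivers | target_set:
        if lab not in labels:
            raise ConfigurationError(f"chaotic/coupling channel {lab!r} unknown")

    # free-running chaotic channels (including drivers), in label order for
    # reproducible draws; coupling targets are integrated afterwards so the
    # driver trajectories they are forced by already exist
    driver_out: dict[str, np.ndarray] = {}
    n_free = 0
    for lab in labels:
        if lab in target_set:
            continue
        if lab in drivers:
            driver_out[lab] = _chaotic_carrier(rng, total, config.rate, CHAOS_W_DRIVER)
            _blend_chaos(labels.index(lab), driver_out[lab])
        elif lab in config.chaotic_channels:
            w_f = CHAOS_W_FREE[n_free % len(CHAOS_W_FREE)]
            n_free += 1
            _blend_chaos(labels.index(lab), _chaotic_carrier(rng, total, config.rate, w_f))
    for t_idx, cp in enumerate(config.couplings):
        lagged = np.concatenate(
            [np.full(lag_samples, driver_out[cp.driver][0]), driver_out[cp.driver][:-lag_samples]]
        )
        w_t = CHAOS_W_TARGETS[t_idx % len(CHAOS_W_TARGETS)]
        target = _chaotic_carrier(rng, total, config.rate, w_t, k=cp.strength, drive=lagged)
        _blend_chaos(labels.index(cp.target), target)

    # slow modulation streams at the tick rate
    hold = max(1, int(round(config.rate / MODULATION_TICK_HZ)))
    n_ticks = total // hold + 2
    global_stream = _logistic_stream(rng, n_ticks)
    group_streams = {gid: _logistic_stream(rng, n_ticks) for gid in group_ids}
    mod_ticks = np.empty((n_ticks, config.n_channels))
    for j, lab in enumerate(labels):
        g = strengths[lab]
        own = _logistic_stream(rng, n_ticks)
        mod_ticks[:, j] = g * (0.5 * global_stream + 0.5 * group_streams[groups[lab]]) + (1.0 - g) * own


    # envelope multiplier (1 - depth) + 2 depth m keeps unit mean for m ~ 0.5;
    # larger depth makes shared slow modulation dominate pairwise dependence.
    # A chaotic component is modulated only shallowly: state-space
    # reconstruction tolerates the smooth repetition-locked amplitude
    # profile but degrades under deep multiplicative amplitude noise
    depth = config.mod_depth
    chaos_depth = CHAOS_MOD_FRACTION * depth
    data = np.empty((total, config.n_channels))
    for j in range(config.n_channels):
        mod = _smooth_upsample(mod_ticks[:, j], hold, total, config.rate)
        data[:, j] = config.noise_sd * env * ((1.0 - depth) + 2.0 * depth * mod) * carriers[:, j]
        if j in chaos_comp:
            data[:, j] += (
                config.noise_sd
                * env
                * ((1.0 - chaos_depth) + 2.0 * chaos_depth * mod)
                * chaos_comp[j]
            )

    truth = TruthRecord(
        true_groups=dict(groups),
        true_edges=tuple((cp.driver, cp.target) for cp in config.couplings),
        parameters={
            "group_strength": dict(strengths),
            "coupling_strengths": {f"{c.driver}->{c.target}": c.strength for c in config.couplings},
            "coupling_lag_s": config.coupling_lag,
            "seed": config.seed,
        },
    )
    rec = EMGRecording(
        data=data,
        rate=config.rate,
        labels=labels,
        condition=config.condition,
        spans=spans,
        meta={
            "seed": config.seed,
            "truth": {
                "true_groups": dict(groups),
                "true_edges": [list(e) for e in truth.true_edges],
            },
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# canonical coupled dynamical system
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingSpec:
    """Unidirectionally (or bidirectionally) coupled logistic map pair.

    Dynamics::

        x[t+1] = x[t] * (r_x - r_x x[t] - beta_xy y[t])
        y[t+1] = y[t] * (r_y - r_y y[t] - beta_yx x[t])

    so ``beta_yx > 0`` makes *x* drive *y*.
    """

    r_x: float = 3.8
    r_y: float = 3.5
    beta_xy: float = 0.0
    beta_yx: float = 0.32
    length: int = 1000
    burn_in: int = 100
    init: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= self.burn_in:
            raise ConfigurationError(
                f"length ({self.length}) must exceed burn_in ({self.burn_in})"
            )
        if self.beta_xy < 0 or self.beta_yx < 0:
            raise ConfigurationError("coupling strengths must be >= 0")
        if self.init is not None and not all(0 < v < 1 for v in self.init):
            raise ConfigurationError("initial values must lie in (0, 1)")


def generate_coupled_logistic(spec: CouplingSpec) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled map pair, discard burn-in, return ``(x, y)``."""
    rng = np.random.default_rng(spec.seed)
    if spec.init is not None:
        x, y = spec.init
    else:
        x, y = rng.uniform(0.2, 0.8, size=2)
    n = spec.length
    xs = np.empty(n)
    ys = np.empty(n)
    for t in range(n + spec.burn_in):
        x_next = x * (spec.r_x - spec.r_x * x - spec.beta_xy * y)
        y_next = y * (spec.r_y - spec.r_y * y - spec.beta_yx * x)
        if not (0.0 < x_next < 1.0 and 0.0 < y_next < 1.0):
            raise NumericalInstabilityError(
                "trajectory left (0,1) at step "
                f"{t} (r_x={spec.r_x}, r_y={spec.r_y}, "
                f"beta_xy={spec.beta_xy}, beta_yx={spec.beta_yx})"
            )
        x, y = x_next, y_next
        if t >= spec.burn_in:
            xs[t - spec.burn_in] = x
            ys[t - spec.burn_in] = y
    return xs, ys


def planted_sensor_scenario(seed: int = 0, condition: str = "appropriate") -> SimConfig:
    """Canonical sensor-recovery scenario.

    The side surface (V24-V33) forms one strongly coupled muscle group
    (``group_strength`` 0.8) whose channels carry chaotic carrier dynamics;
    channel V28 is the planted information source, driving V24 and V31 with
    a weak lagged force.  The remaining surfaces form loosely coupled
    groups.  Under the default pipeline this plants two recoverable facts:
    the side group sits inside the key-node set, and V28 heads the
    information-flow ranking.
    """
    side = tuple(f"V{i}" for i in range(24, 34))
    groups: dict[str, int] = {}
    for i in range(1, 13):
        groups[f"V{i}"] = 0 if i <= 6 else 1
    for i in range(13, 24):
        groups[f"V{i}"] = 2 if i <= 17 else 3
    for lab in side:
        groups[lab] = 4
    strengths = {f"V{i}": 0.3 for i in range(1, 24)}
    strengths.update({lab: 0.8 for lab in side})
    return SimConfig(
        seed=seed,
        condition=condition,
        group_assignment=groups,
        group_strength=strengths,
        global_mix=0.8,
        mod_depth=0.8,
        chaotic_channels=side,
        couplings=(
            ChannelCoupling("V28", "V24", 0.1),
            ChannelCoupling("V28", "V31", 0.1),
        ),
    )


def movement_condition_configs(
    seed: int = 0,
    scale: Mapping[str, float] | None = None,
) -> dict[str, SimConfig]:
    """Three-condition study design with graded muscle coordination.

    Each movement condition shares the six-area group layout, with the side
    surface most strongly coordinated (the pattern the sensor-selection
    analysis is built around).  ``scale`` multiplies every group strength
    per condition; the default makes the unconstrained movement the most
    coordinated and the restrained one markedly weaker, so the restrained
    condition separates in feature space.
    """
    if scale is None:
        scale = {"appropriate": 1.0, "excessive": 0.9, "too_small": 0.7}
    out: dict[str, SimConfig] = {}
    for idx, (cond, s) in enumerate(scale.items()):
        cfg = planted_sensor_scenario(seed=seed + 1000 * idx, condition=cond)
        strengths = {
            lab: (min(0.95, 0.8 * s) if g == 0.8 else g)
            for lab, g in dict(cfg.group_strength).items()
        }
        out[cond] = replace(cfg, group_strength=strengths)
    return out
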