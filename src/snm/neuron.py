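"""Single-neuron membrane dynamics and spike-train utilities.

Two neuron models are provided. The leaky integrate-and-fire (LIF) neuron
integrates

    dv/dt = -v / tau_m + I(t)

and emits a spike when v crosses its firing threshold, after which v is reset.
The Izhikevich neuron is the standard two-variable model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with spike cutoff at v_peak, reset v <- c, u <- u + d. Both are advanced with
forward Euler; the per-neuron firing threshold (``theta``) is mutable state so
that homeostatic / unlearning mechanisms can adjust it.

All quantities are dimensionless except time, which is in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DynamicsError

LIF = "lif"
IZHIKEVICH = "izhikevich"


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters.

    tau_m : membrane time constant in ms (> 0).
    v_thresh : baseline firing threshold (dimensionless potential units).
    v_reset : post-spike reset potential; must lie below v_thresh.
    """

    tau_m: float = 10.0
    v_thresh: float = 0.5
    v_reset: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be > 0, got {self.tau_m}")
        if not self.v_reset < self.v_thresh:
            raise ValueError("v_reset must be strictly below v_thresh")


@dataclass(frozen=True)
class IzhikevichParams:
    """Izhikevich model coefficients.

    Defaults are the regular-spiking cortical parameter set
    (a=0.02, b=0.2, c=-65, d=8) with a spike cutoff of v_peak=30.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if not self.c < self.v_peak:
            raise ValueError("reset potential c must be below v_peak")

    def resting_state(self) -> tuple[float, float]:
        """Stable fixed point (v, u) of the zero-input dynamics.

        Solves 0.04 v^2 + (5 - b) v + 140 = 0 with u = b v and returns the
        lower (stable) root; falls back to (c, b*c) when no real root exists.
        """
        disc = (5.0 - self.b) ** 2 - 4.0 * 0.04 * 140.0
        if disc < 0:
            return self.c, self.b * self.c
        v = (-(5.0 - self.b) - np.sqrt(disc)) / (2.0 * 0.04)
        return float(v), float(self.b * v)


@dataclass
class NeuronState:
    """Mutable per-neuron state.

    v : membrane potential.
    theta : current effective firing threshold (initially the model baseline;
        unlearning may move it).
    u : recovery variable (Izhikevich only; unused for LIF).
    model_kind : "lif" or "izhikevich".
    """

    v: float
    theta: float
    model_kind: str = LIF
    u: float = 0.0

    @classmethod
    def from_lif(cls, params: LIFParams) -> "NeuronState":
        return cls(v=params.v_reset, theta=params.v_thresh, model_kind=LIF)

    @classmethod
    def from_izhikevich(cls, params: IzhikevichParams) -> "NeuronState":
        v, u = params.resting_state()
        return cls(v=v, theta=params.v_peak, model_kind=IZHIKEVICH, u=u)


# ---------------------------------------------------------------------------
# Integration steps
# ---------------------------------------------------------------------------


def _check_finite(*values: float) -> None:
    for x in values:
        if not np.isfinite(x):
            raise DynamicsError(f"non-finite value {x} in neuron dynamics")


def lif_step(
    state: NeuronState, params: LIFParams, input_current: float, dt: float
) -> tuple[NeuronState, bool]:
    """Advance a LIF neuron one forward-Euler step of length dt (ms).

    Returns the new state and whether a spike was registered; on a spike the
    membrane potential is reset to ``params.v_reset``. Threshold comparison is
    >= against the state's (possibly adapted) ``theta``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.model_kind != LIF:
        raise ValueError(f"lif_step applied to a {state.model_kind} state")
    _check_finite(state.v, input_current)
    v = state.v + dt * (-state.v / params.tau_m + input_current)
    _check_finite(v)
    spiked = bool(v >= state.theta)
    if spiked:
        v = params.v_reset
    return NeuronState(v=v, theta=state.theta, model_kind=LIF, u=state.u), spiked


def izhikevich_step(
    state: NeuronState, params: IzhikevichParams, input_current: float, dt: float
) -> tuple[NeuronState, bool]:
    """Advance an Izhikevich neuron one forward-Euler step of length dt (ms)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.model_kind != IZHIKEVICH:
        raise ValueError(f"izhikevich_step applied to a {state.model_kind} state")
    _check_finite(state.v, state.u, input_current)
    v, u = state.v, state.u
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + input_current)
    u_new = u + dt * params.a * (params.b * v - u)
    _check_finite(v_new, u_new)
    spiked = bool(v_new >= state.theta)
    if spiked:
        v_new = params.c
        u_new = u_new + params.d
    return (
        NeuronState(v=v_new, theta=state.theta, model_kind=IZHIKEVICH, u=u_new),
        spiked,
    )


# Vectorised kernels used by the network simulator; semantics are identical to
# the scalar step functions above but operate on per-layer arrays in place.


def lif_step_arr(
    v: np.ndarray, theta: np.ndarray, input_current: np.ndarray, params: LIFParams, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    v_new = v + dt * (-v / params.tau_m + input_current)
    spiked = v_new >= theta
    v_new = np.where(spiked, params.v_reset, v_new)
    return v_new, spiked


def izhikevich_step_arr(
    v: np.ndarray,
    u: np.ndarray,
    theta: np.ndarray,
    input_current: np.ndarray,
    params: IzhikevichParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + input_current)
    u_new = u + dt * params.a * (params.b * v - u)
    spiked = v_new >= theta
    v_new = np.where(spiked, params.c, v_new)
    u_new = np.where(spiked, u_new + params.d, u_new)
    return v_new, u_new, spiked


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


@dataclass
class SpikeTrain:
    """An ordered sequence of spike event times (ms) for one neuron.

    Times are strictly increasing, lie in [0, duration], and consecutive
    events are separated by at least one integration step dt.
    """

    spike_times: np.ndarray
    duration: float
    dt: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        t = self.spike_times
        if t.size:
            if np.any(t < 0) or np.any(t > self.duration + 1e-9):
                raise ValueError("spike times must lie in [0, duration]")
            if t.size > 1 and np.any(np.diff(t) < self.dt - 1e-9):
                raise ValueError("consecutive spike times must differ by >= dt")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def binned(self, dt: float | None = None) -> np.ndarray:
        """Per-bin spike counts S(t) on a grid of width dt (default self.dt)."""
        dt = self.dt if dt is None else dt
        n_bins = int(round(self.duration / dt))
        if n_bins == 0:
            return np.zeros(0)
        idx = np.floor(self.spike_times / dt + 1e-9).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        return np.bincount(idx, minlength=n_bins).astype(float)

    @classmethod
    def from_binned(cls, counts: np.ndarray, dt: float) -> "SpikeTrain":
        counts = np.asarray(counts)
        times = np.flatnonzero(counts > 0) * dt
        return cls(spike_times=times, duration=len(counts) * dt, dt=dt)


def binned_derivative(counts: np.ndarray) -> np.ndarray:
    """First discrete difference of a binned spike-count signal.

    out[0] = 0 and out[t] = counts[t] - counts[t-1]; the output telescopes so
    that its sum equals counts[-1] - counts[0].
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        return counts.copy()
    return np.diff(counts, prepend=counts[:1])


def spike_derivative(train: SpikeTrain, dt: float | None = None) -> np.ndarray:
    """Per-bin rate of change dS/dt of a spike train's binned count signal."""
    return binned_derivative(train.binned(dt))


def save_spike_trains(trains, path, delimiter: str = "\t") -> None:
    """Write a collection of spike trains as two-column (neuron_id, time_ms)
    delimited text, one event per line."""
    with open(path, "w") as fh:
        fh.write(f"# neuron_id{delimiter}time_ms\n")
        for i, tr in enumerate(trains):
            for t in tr.spike_times:
                fh.write(f"{i}{delimiter}{t:.6f}\n")


def load_spike_trains(path, duration: float, dt: float, n_neurons: int | None = None,
                      delimiter: str = "\t") -> list:
    """Read two-column (neuron_id, time_ms) text back into SpikeTrains."""
    events: dict[int, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i_str, t_str = line.split(delimiter)
            events.setdefault(int(i_str), []).append(float(t_str))
    n = n_neurons if n_neurons is not None else (max(events) + 1 if events else 0)
    return [
        SpikeTrain(np.sort(events.get(i, [])), duration=duration, dt=dt)
        for i in range(n)
    ]
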