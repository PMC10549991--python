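"""Sinusoidal piston kinematics and time discretisation.

The bioreactor piston compresses the scaffold vertically following a
1 - cos waveform: displacement and velocity both start at zero, the piston
reaches its lowest position (full amplitude A = a_c * H) at half period and
returns to the start at the end of each cycle.  Amplitudes are expressed as
a fraction of the original scaffold height (1%-10% in the reference
stimulation protocol, at 1 Hz).

Also provides the dynamic-mesh time-step criterion dt < ds / v_max used to
pick a stable coupling time step for a moving-mesh flow solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LoadProtocol",
    "TimestepCheck",
    "piston_displacement",
    "piston_velocity",
    "phase",
    "check_timestep",
    "time_grid",
]


@dataclass(frozen=True)
class LoadProtocol:
    """Sinusoidal compression protocol.

    Parameters
    ----------
    frequency : float
        Loading frequency f in Hz.
    amplitude_fraction : float
        Peak compression as a fraction of scaffold height, in (0, 0.2].
    scaffold_height : float
        Original scaffold height H in mm.
    dt : float
        Simulation time step in s (default 0.004 s, the adopted "large"
        step of the time-step study).
    n_cycles : int
        Number of loading cycles simulated (default 1; the material is not
        viscoelastic so further cycles repeat the first).
    """

    frequency: float = 1.0
    amplitude_fraction: float = 0.10
    scaffold_height: float = 4.8
    dt: float = 0.004
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if not 0 < self.amplitude_fraction <= 0.2:
            raise ValueError(
                f"amplitude_fraction must lie in (0, 0.2], got {self.amplitude_fraction}"
            )
        if self.scaffold_height <= 0:
            raise ValueError("scaffold_height must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dt > 1.0 / (4 * self.frequency):
            raise ValueError(
                f"dt={self.dt} too coarse: need at least 4 samples per cycle "
                f"(dt <= {1.0 / (4 * self.frequency)})"
            )
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def amplitude(self) -> float:
        """Peak piston travel A = a_c * H in mm."""
        return self.amplitude_fraction * self.scaffold_height

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def t_end(self) -> float:
        return self.n_cycles / self.frequency


def _check_window(t: np.ndarray, protocol: LoadProtocol) -> None:
    tol = 1e-12
    if np.any(t < -tol) or np.any(t > protocol.t_end + tol):
        raise ValueError(
            f"time outside simulated window [0, {protocol.t_end}] s"
        )


def piston_displacement(t, protocol: LoadProtocol):
    """Vertical piston displacement y(t) in mm (downward negative).

    y(t) = -(A/2) (1 - cos(2 pi f t)); zero at cycle start and end, minimum
    -A at half period.
    """
    t = np.asarray(t, dtype=float)
    _check_window(t, protocol)
    A = protocol.amplitude
    y = -(A / 2.0) * (1.0 - np.cos(2 * np.pi * protocol.frequency * t))
    return y if y.ndim else float(y)


def piston_velocity(t, protocol: LoadProtocol):
    """Piston velocity v(t) = dy/dt in mm/s.

    v(t) = -A pi f sin(2 pi f t); zero at the start, the lowest position and
    the end of each cycle, extreme magnitude A pi f at quarter periods.
    """
    t = np.asarray(t, dtype=float)
    _check_window(t, protocol)
    A, f = protocol.amplitude, protocol.frequency
    v = -A * np.pi * f * np.sin(2 * np.pi * f * t)
    return v if v.ndim else float(v)


def max_piston_speed(protocol: LoadProtocol) -> float:
    """Peak piston speed A pi f in mm/s."""
    return protocol.amplitude * np.pi * protocol.frequency


def phase(t, protocol: LoadProtocol):
    """Stroke phase at time t: ``"downward"`` or ``"upward"``.

    The piston moves down for t mod T in [0, T/2) and up otherwise; the
    turning point t = T/2 (zero velocity) is assigned to the upward stroke,
    so the upward-stroke stimulus peak is sought from the lowest position on.
    """
    t = np.asarray(t, dtype=float)
    _check_window(t, protocol)
    frac = np.mod(t, protocol.period) * protocol.frequency
    out = np.where(frac < 0.5, "downward", "upward")
    return out if out.ndim else str(out)


@dataclass(frozen=True)
class TimestepCheck:
    """Result of the moving-mesh time-step criterion."""

    dt: float
    bound: float
    passed: bool


def check_timestep(dt: float, min_element_length: float, v_max: float) -> TimestepCheck:
    """Dynamic-mesh stability criterion: dt < ds / v_max (strict).

    ``min_element_length`` ds in mm, ``v_max`` in mm/s.  A step equal to the
    bound fails.
    """
    if min_element_length <= 0:
        raise ValueError("min_element_length must be > 0")
    if v_max <= 0:
        raise ValueError("v_max must be > 0")
    bound = min_element_length / v_max
    return TimestepCheck(dt=dt, bound=bound, passed=dt < bound)


def time_grid(protocol: LoadProtocol) -> np.ndarray:
    """Uniform time grid over the simulated cycles, endpoints included."""
    n = int(round(protocol.t_end / protocol.dt))
    return np.linspace(0.0, protocol.t_end, n + 1)
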