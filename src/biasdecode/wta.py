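"""Biased winner-take-all (WTA) circuit model.

A mean-rate attractor network decides between a left and a right choice
unit (x_L, x_R) that excite themselves and inhibit each other through a
shared inhibitory unit h.  A pointer ("bias") unit p_i is bidirectionally
coupled to each choice unit; once its input b_i exceeds the activation
threshold it raises that choice unit's effective gain, so a transient
bias present at competition onset can decide the winner even against a
larger sensory input on the other side.

Dynamics (half-wave rectified, f(z) = max(0, z)):

    tau dx_i/dt + G x_i = f(I_i + alpha x_i + delta p_i - beta1 h - T)
    tau dh/dt   + G h   = f(beta2 (x_L + x_R) - T)
    tau dp_i/dt + G p_i = f(delta x_i + b_i - T)

Steady state of the winner with an active bias unit:

    x_w = (I_w + delta (b_w - T) + T (beta1 - 1))
          / (1 - alpha + beta1 beta2 - delta^2)

reducing at delta = 0 to x_w = (I_w + T (beta1 - 1)) / (1 - alpha + beta1 beta2).

The full 11-unit variant adds reward-size bias units q_lo/q_hi and four
gate units d that convert a reward bias into a side bias only after cue
onset (enforced by the high d-threshold T_d plus a cue-gating input).

Integration is forward Euler with step ``dt`` (default 0.01 s = tau, so
the default update is the discrete map u <- f(drive - T); a smaller dt
recovers the continuous-time flow and is exercised in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CircuitParams",
    "InputSchedule",
    "Trajectory",
    "step",
    "simulate",
    "simulate_full",
    "steady_state_biased",
    "steady_state_unbiased",
    "phase_space_scan",
    "separatrix_kink",
    "winner_of",
]

REDUCED_UNITS = ("x_L", "x_R", "h", "p_L", "p_R")
FULL_UNITS = REDUCED_UNITS + ("q_lo", "q_hi",
                              "d_loL", "d_loR", "d_hiL", "d_hiR")


@dataclass(frozen=True)
class CircuitParams:
    tau: float = 0.01     # membrane time constant, s
    G: float = 1.0        # load
    T: float = 1.0        # activation threshold of x, h, p (and q) units
    alpha: float = 1.5    # choice-unit self-excitation
    beta1: float = 3.0    # inhibition h -> x
    beta2: float = 0.4    # excitation x -> h
    delta: float = 0.1    # bias <-> choice coupling
    dt: float = 0.001     # Euler step, s (see module docstring)
    # full-model extension
    delta_q: float = 5.0  # q -> d coupling
    delta_d: float = 0.1  # d <-> x coupling
    T_d: float = 8.0      # gate-unit threshold
    v_gate: float = 4.0   # amplitude of the cue-gating input v

    @property
    def denom_biased(self) -> float:
        return 1.0 - self.alpha + self.beta1 * self.beta2 - self.delta ** 2

    @property
    def denom_unbiased(self) -> float:
        return 1.0 - self.alpha + self.beta1 * self.beta2

    def validate(self):
        if self.denom_biased <= 0:
            raise ValueError(
                "unstable parameterization: 1 - alpha + beta1*beta2 - "
                f"delta^2 = {self.denom_biased:.3g} must be positive")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        return self


@dataclass
class InputSchedule:
    """Piecewise-constant input time courses.

    Each entry maps an input name (``I_L``, ``I_R``, ``b_L``, ``b_R``,
    and for the full model ``c_lo``, ``c_hi``, ``v_hiL``, ``v_hiR``) to a
    list of ``(t_on, t_off, value)`` segments; values add where segments
    overlap.  Times in seconds.
    """

    segments: dict = field(default_factory=dict)

    @classmethod
    def constant(cls, **values):
        return cls({k: [(0.0, np.inf, v)] for k, v in values.items()})

    def add(self, name, t_on, t_off, value):
        self.segments.setdefault(name, []).append((t_on, t_off, value))
        return self

    def at(self, name: str, t: float) -> float:
        return sum(v for (a, b, v) in self.segments.get(name, ())
                   if a <= t < b)

    def last_transition(self) -> float:
        """Latest finite switch-on/off time across all inputs."""
        ts = [0.0]
        for segs in self.segments.values():
            for a, b, _ in segs:
                ts.append(a)
                if np.isfinite(b):
                    ts.append(b)
        return max(ts)


def _f(z):
    return np.maximum(0.0, z)


def step(state: dict, params: CircuitParams, inputs: dict) -> dict:
    """One forward-Euler update of the reduced 5-unit circuit.

    ``u <- u + (dt/tau) * (f(drive - T) - G u)``; with the default
    dt = tau, G = 1 this is the discrete map ``u <- f(drive - T)``.
    """
    if not all(np.isfinite(v) for v in state.values()):
        raise FloatingPointError(f"non-finite circuit state: {state}")
    p = params
    xL, xR, h = state["x_L"], state["x_R"], state["h"]
    pL, pR = state["p_L"], state["p_R"]
    drive = {
        "x_L": inputs.get("I_L", 0.0) + p.alpha * xL + p.delta * pL
               - p.beta1 * h - p.T,
        "x_R": inputs.get("I_R", 0.0) + p.alpha * xR + p.delta * pR
               - p.beta1 * h - p.T,
        "h": p.beta2 * (xL + xR) - p.T,
        "p_L": p.delta * xL + inputs.get("b_L", 0.0) - p.T,
        "p_R": p.delta * xR + inputs.get("b_R", 0.0) - p.T,
    }
    r = p.dt / p.tau
    return {k: state[k] + r * (_f(drive[k]) - p.G * state[k])
            for k in REDUCED_UNITS}


@dataclass
class Trajectory:
    """Time-by-unit activity table plus convergence metadata."""

    frame: pd.DataFrame
    converged: bool
    winner: str | None      # "L", "R", or None (tie / undecided)

    def final(self) -> pd.Series:
        return self.frame.iloc[-1]


def winner_of(xL: float, xR: float, atol: float = 1e-6) -> str | None:
    """Winner at convergence: the choice unit that stays positive while
    the other is (numerically) zero.  Exact symmetry -> no winner."""
    if xL > atol and xR <= atol:
        return "L"
    if xR > atol and xL <= atol:
        return "R"
    return None


def _simulate_units(units, drive_fn, params, schedule, duration,
                    initial_state, conv_tol, conv_window):
    params.validate()
    n_steps = int(round(duration / params.dt))
    if n_steps < 1:
        raise ValueError("duration must cover at least one Euler step")
    state = np.zeros(len(units))
    if initial_state:
        for i, u in enumerate(units):
            state[i] = initial_state.get(u, 0.0)
    r = params.dt / params.tau
    hist = np.empty((n_steps + 1, len(units)))
    hist[0] = state
    converged = False
    # a zero plateau before the inputs switch on must not count as converged
    first_check = int(np.ceil(schedule.last_transition() / params.dt)) \
        + conv_window
    for s in range(1, n_steps + 1):
        t = (s - 1) * params.dt
        drive = drive_fn(state, t)
        state = state + r * (_f(drive) - params.G * state)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"non-finite circuit state at t={t:.3f}")
        hist[s] = state
        if s >= max(conv_window, first_check):
            delta = np.abs(hist[s - conv_window:s + 1]
                           - hist[s]).max()
            if delta < conv_tol:
                hist = hist[:s + 1]
                converged = True
                break
    frame = pd.DataFrame(hist, columns=list(units))
    frame.insert(0, "time", np.arange(len(frame)) * params.dt)
    return frame, converged


def simulate(params: CircuitParams, schedule: InputSchedule,
             duration: float = 2.0, initial_state: dict | None = None,
             conv_tol: float = 1e-9, conv_window: int = 10) -> Trajectory:
    """Integrate the reduced 5-unit circuit.

    Convergence is declared when the maximum per-unit change over
    ``conv_window`` steps drops below ``conv_tol``; otherwise the full
    trajectory is returned with ``converged=False``.
    """
    p = params

    def drive_fn(st, t):
        xL, xR, h, pL, pR = st
        return np.array([
            schedule.at("I_L", t) + p.alpha * xL + p.delta * pL
            - p.beta1 * h - p.T,
            schedule.at("I_R", t) + p.alpha * xR + p.delta * pR
            - p.beta1 * h - p.T,
            p.beta2 * (xL + xR) - p.T,
            p.delta * xL + schedule.at("b_L", t) - p.T,
            p.delta * xR + schedule.at("b_R", t) - p.T,
        ])

    frame, conv = _simulate_units(REDUCED_UNITS, drive_fn, p, schedule,
                                  duration, initial_state, conv_tol,
                                  conv_window)
    last = frame.iloc[-1]
    return Trajectory(frame, conv, winner_of(last.x_L, last.x_R))


def simulate_full(params: CircuitParams, schedule: InputSchedule,
                  duration: float = 2.0, initial_state: dict | None = None,
                  conv_tol: float = 1e-9, conv_window: int = 10) -> Trajectory:
    """Integrate the full 11-unit circuit (spatial + reward biases).

    The reward-bias units q_lo/q_hi receive inputs c_lo/c_hi; the four
    gate units d convert an active reward bias into a side bias only
    once one of the cue-gating inputs v_hiL / v_hiR turns on (exactly
    one may be active at a time), since the reward-to-side mapping is
    unknown before the cue.
    """
    p = params
    for t_probe in np.arange(0.0, duration, p.dt):
        if (schedule.at("v_hiL", t_probe) > 0
                and schedule.at("v_hiR", t_probe) > 0):
            raise ValueError("both cue gates on at t=%.3f" % t_probe)

    def drive_fn(st, t):
        xL, xR, h, pL, pR, qlo, qhi, dloL, dloR, dhiL, dhiR = st
        vL = schedule.at("v_hiL", t)
        vR = schedule.at("v_hiR", t)
        return np.array([
            schedule.at("I_L", t) + p.alpha * xL + p.delta * pL
            + p.delta_d * (dloL + dhiL) - p.beta1 * h - p.T,
            schedule.at("I_R", t) + p.alpha * xR + p.delta * pR
            + p.delta_d * (dloR + dhiR) - p.beta1 * h - p.T,
            p.beta2 * (xL + xR) - p.T,
            p.delta * xL + schedule.at("b_L", t) - p.T,
            p.delta * xR + schedule.at("b_R", t) - p.T,
            schedule.at("c_lo", t) - p.T,
            schedule.at("c_hi", t) - p.T,
            p.delta_q * qlo + vR + p.delta_d * xL - p.T_d,   # d_loL
            p.delta_q * qlo + vL + p.delta_d * xR - p.T_d,   # d_loR
            p.delta_q * qhi + vL + p.delta_d * xL - p.T_d,   # d_hiL
            p.delta_q * qhi + vR + p.delta_d * xR - p.T_d,   # d_hiR
        ])

    frame, conv = _simulate_units(FULL_UNITS, drive_fn, p, schedule,
                                  duration, initial_state, conv_tol,
                                  conv_window)
    last = frame.iloc[-1]
    return Trajectory(frame, conv, winner_of(last.x_L, last.x_R))


def steady_state_biased(I_w: float, b_w: float,
                        params: CircuitParams = CircuitParams()) -> float:
    """Closed-form steady activity of the winning choice unit when its
    bias unit is active: (I_w + delta (b_w - T) + T (beta1 - 1)) /
    (1 - alpha + beta1 beta2 - delta^2)."""
    p = params.validate()
    if I_w <= 0:
        raise ValueError("winner input I_w must be positive")
    x = (I_w + p.delta * (b_w - p.T) + p.T * (p.beta1 - 1)) / p.denom_biased
    if p.delta * x + b_w - p.T <= 0:
        raise ValueError("bias input too weak to activate the bias unit; "
                         "use steady_state_unbiased")
    return x


def steady_state_unbiased(I_w: float,
                          params: CircuitParams = CircuitParams()) -> float:
    """Winner steady state of the plain WTA (inactive / absent bias unit):
    (I_w + T (beta1 - 1)) / (1 - alpha + beta1 beta2)."""
    p = params
    if p.denom_unbiased <= 0:
        raise ValueError("unstable parameterization")
    return (I_w + p.T * (p.beta1 - 1)) / p.denom_unbiased


def _simulate_grid(params, bL, dI, I_R, b_R, onset, duration):
    """Vectorized Euler integration over a (b_L, dI) grid; returns winner
    codes (+1 L, -1 R, 0 none) per cell."""
    p = params
    shape = np.broadcast(bL, dI).shape
    bL = np.broadcast_to(bL, shape).astype(float)
    dI = np.broadcast_to(dI, shape).astype(float)
    xL = np.zeros(shape)
    xR = np.zeros(shape)
    h = np.zeros(shape)
    pL = np.zeros(shape)
    pR = np.zeros(shape)
    r = p.dt / p.tau
    n_steps = int(round(duration / p.dt))
    tail_start = max(1, int(0.8 * n_steps))   # average over the final 20%
    sumL = np.zeros(shape)
    sumR = np.zeros(shape)
    n_tail = 0
    for s in range(n_steps):
        t = s * p.dt
        on = 1.0 if t >= onset else 0.0
        I_L = (I_R + dI) * on
        I_Rt = I_R * on
        nxL = xL + r * (_f(I_L + p.alpha * xL + p.delta * pL
                           - p.beta1 * h - p.T) - p.G * xL)
        nxR = xR + r * (_f(I_Rt + p.alpha * xR + p.delta * pR
                           - p.beta1 * h - p.T) - p.G * xR)
        nh = h + r * (_f(p.beta2 * (xL + xR) - p.T) - p.G * h)
        npL = pL + r * (_f(p.delta * xL + bL - p.T) - p.G * pL)
        npR = pR + r * (_f(p.delta * xR + b_R - p.T) - p.G * pR)
        xL, xR, h, pL, pR = nxL, nxR, nh, npL, npR
        if s >= tail_start:
            sumL += xL
            sumR += xR
            n_tail += 1
    mL = sumL / n_tail
    mR = sumR / n_tail
    atol = 1e-6
    win = np.zeros(shape, dtype=int)
    win[(mL > atol) & (mR <= atol)] = 1
    win[(mR > atol) & (mL <= atol)] = -1
    return win


def phase_space_scan(b_L_grid, dI_grid,
                     params: CircuitParams = CircuitParams(),
                     I_R: float = 2.0, b_R: float = 0.0,
                     onset: float = 0.0, duration: float = 2.0):
    """Winner map over a (b_L, I_L - I_R) grid plus the separatrix.

    The bias input b_L is on from t = 0; the sensory inputs switch on at
    ``onset``.  Returns ``(winner_map, separatrix)``: ``winner_map`` is a
    DataFrame (rows b_L, columns dI, entries "L"/"R"/"none") and
    ``separatrix`` a DataFrame with, per b_L, the critical I_L - I_R at
    which the winner flips from R to L (NaN when it never flips in the
    scanned range).  The separatrix is constant below the bias-unit
    activation threshold and linear in b_L above it.
    """
    params.validate()
    b_L_grid = np.asarray(b_L_grid, dtype=float)
    dI_grid = np.asarray(dI_grid, dtype=float)
    win = _simulate_grid(params, b_L_grid[:, None], dI_grid[None, :],
                         I_R, b_R, onset, duration)
    labels = np.array(["R", "none", "L"])[win + 1]
    winner_map = pd.DataFrame(labels, index=pd.Index(b_L_grid, name="b_L"),
                              columns=pd.Index(dI_grid, name="dI"))
    crit = np.full(b_L_grid.size, np.nan)
    for i in range(b_L_grid.size):
        left_wins = win[i] == 1
        j = np.argmax(left_wins) if left_wins.any() else None
        if j is not None:
            crit[i] = dI_grid[j]
    separatrix = pd.DataFrame({"b_L": b_L_grid, "critical_dI": crit})
    return winner_map, separatrix


def separatrix_kink(separatrix: pd.DataFrame, dI_step: float) -> float:
    """b_L at which the separatrix first departs from its constant
    low-b_L level (by more than one dI grid step)."""
    crit = separatrix.critical_dI.to_numpy()
    base = crit[0]
    # any change at grid resolution counts as a departure; half a step
    # separates real movement from floating-point noise on a flat level
    off = np.flatnonzero(np.abs(crit - base) > dI_step * 0.5)
    if off.size == 0:
        raise ValueError("separatrix never departs from its base level "
                         "within the scanned b_L range")
    return float(separatrix.b_L.to_numpy()[off[0]])
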