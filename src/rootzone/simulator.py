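"""Multicellular simulation of the two root cell files.

The state holds two parallel ordered files (epidermis and cortex) of
``window`` cells each, indexed outward from the quiescent centre.  Between
discrete events the per-cell pools evolve by the coupled ODEs of
:mod:`rootzone.model`; events are (in order per step) zone transitions
(meristem cells whose relative auxin crosses the regime-dependent
threshold enter the elongation zone), divisions (division factor above
threshold and length above the minimum; daughters split all amounts
50/50), and window advection (cells pushed past the window are dropped and
their auxin is booked to the ledger).

A cumulative auxin mass ledger (source input, degradation, outer-boundary
efflux, advection loss) is integrated with the same scheme as the state,
so mass balance closes to rounding error at every step.

``steady_state_profile`` solves the auxin/PIN2 subsystem on a static file
directly (growth and division do not feed back on it); it is the
steady-state prediction used by the inference and synthetic-data modules.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from ._kernels import HAVE_NUMBA, integrate_batch, subsystem_gauss_seidel
from .model import CORTEX, EPIDERMIS, FACES, SourceConfig, logistic
from .params import ModelParameters, NitrogenRegime

__all__ = [
    "RootState", "Trajectory", "SummaryStatistics", "initial_state", "step",
    "run", "summarize", "steady_state_profile", "solve_subsystem",
    "StabilityError",
]

_FACE_KEYS = ("apical", "basal", "outer", "inner")


class StabilityError(RuntimeError):
    """Raised when dt violates the explicit-integration stability bound."""


@dataclass
class FileArrays:
    """Per-file state arrays, index 0 = QC-adjacent cell (i = 1)."""

    A: np.ndarray
    PINc: np.ndarray
    Pm: Dict[str, np.ndarray]
    DIV: np.ndarray
    L: np.ndarray
    elong: np.ndarray          # bool; True once in the elongation zone
    lineage: np.ndarray        # int ids

    def copy(self) -> "FileArrays":
        return FileArrays(self.A.copy(), self.PINc.copy(),
                          {f: v.copy() for f, v in self.Pm.items()},
                          self.DIV.copy(), self.L.copy(),
                          self.elong.copy(), self.lineage.copy())

    @property
    def n(self) -> int:
        return self.A.size

    def total_membrane_pin(self) -> np.ndarray:
        return sum(self.Pm.values())


_LEDGER_KEYS = ("source_in", "degraded", "outer_efflux", "advected")


@dataclass
class RootState:
    epidermis: FileArrays
    cortex: FileArrays
    time: float = 0.0
    ledger: Dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(_LEDGER_KEYS, 0.0))
    division_log: Dict[Tuple[str, int], int] = field(default_factory=dict)
    initial_auxin: float = 0.0

    def files(self):
        return ((EPIDERMIS, self.epidermis), (CORTEX, self.cortex))

    def file(self, name: str) -> FileArrays:
        return self.epidermis if name == EPIDERMIS else self.cortex

    def total_auxin(self) -> float:
        return float(self.epidermis.A.sum() + self.cortex.A.sum())

    def ledger_residual(self) -> float:
        """Relative auxin mass-balance error (should be ~rounding)."""
        expected = (self.initial_auxin + self.ledger["source_in"]
                    - self.ledger["degraded"] - self.ledger["outer_efflux"]
                    - self.ledger["advected"])
        scale = max(abs(self.ledger["source_in"]), self.total_auxin(), 1.0)
        return abs(self.total_auxin() - expected) / scale

    def copy(self) -> "RootState":
        return RootState(self.epidermis.copy(), self.cortex.copy(), self.time,
                         dict(self.ledger), dict(self.division_log),
                         self.initial_auxin)

    def max_meristem_auxin(self) -> float:
        vals = [f.A[~f.elong] for _, f in self.files()]
        vals = np.concatenate([v for v in vals if v.size] or [np.zeros(1)])
        return float(vals.max()) if vals.size else 0.0

    def max_auxin(self) -> float:
        """Maximum auxin over all window cells of both files.

        This is the normalization of the *relative auxin level* used by the
        elongation threshold and the reported profiles, mirroring the
        per-root normalization of the ratiometric reporter (the meristem-only
        maximum normalizes the division-factor equation instead)."""
        return float(max(self.epidermis.A.max(), self.cortex.A.max()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, fa in self.files():
            for k in range(fa.n):
                rows.append({
                    "time": self.time, "file": name, "i": k + 1,
                    "length": fa.L[k],
                    "zone": "elongation" if fa.elong[k] else "meristem",
                    "A": fa.A[k], "PINc": fa.PINc[k],
                    **{f"PINm_{f}": fa.Pm[f][k] for f in _FACE_KEYS},
                    "DIV": fa.DIV[k],
                })
        return pd.DataFrame(rows)


def initial_state(params: ModelParameters, length: float = 10.0,
                  pinc: Optional[float] = None) -> RootState:
    """Uniform naive initial state: meristematic cells of equal length,
    no auxin or membrane PIN2, cytoplasmic PIN2 at its auxin-free balance."""
    n = params.window
    if pinc is None:
        pinc = params.m_p / params.d_p

    def fresh(offset):
        return FileArrays(
            A=np.zeros(n), PINc=np.full(n, float(pinc)),
            Pm={f: np.zeros(n) for f in _FACE_KEYS},
            DIV=np.zeros(n), L=np.full(n, float(length)),
            elong=np.zeros(n, dtype=bool),
            lineage=np.arange(offset, offset + n))

    return RootState(fresh(0), fresh(n))


# ---------------------------------------------------------------------------
# right-hand side (vectorized; formulas mirror rootzone.model exactly)
# ---------------------------------------------------------------------------

def _pin_rates(A, PINc, idx, N, p: ModelParameters):
    """Trafficking total and membrane turnover rate for a file."""
    base = N * p.tr_n + (1 - N) * p.tr_wn
    lg = logistic(p.tr_a * A + p.tr_i * idx)
    total = PINc * base * lg
    turnover = p.d_p * (1.0 + A / p.q_p)
    return total, turnover, base * lg


def _rhs(state: RootState, N: int, src_e: np.ndarray, p: ModelParameters,
         y: Optional[list] = None):
    """Derivatives for [per-file pools] + ledger.  ``y`` optionally overrides
    the pool arrays (RK4 stage evaluation) in the order produced by _pack."""
    e, c = state.epidermis, state.cortex
    if y is None:
        y = _pack(state)
    (A_e, PINc_e, Pa_e, Pb_e, Po_e, Pi_e, DIV_e, L_e,
     A_c, PINc_c, Pa_c, Pb_c, Po_c, Pi_c, DIV_c, L_c, _led) = y
    n = A_e.size
    idx = np.arange(1, n + 1, dtype=float)
    lat = p.l_n * N

    out = []
    # --- epidermis PIN pools
    T_e, to_e, _ = _pin_rates(A_e, PINc_e, idx, N, p)
    T_c, to_c, _ = _pin_rates(A_c, PINc_c, idx, N, p)
    literal = p.literal_equations

    dPINc_e = p.m_p - p.d_p * PINc_e * (1.0 + A_e / p.q_p) - (0 if literal else T_e)
    dPINc_c = p.m_p - p.d_p * PINc_c * (1.0 + A_c / p.q_p) - (0 if literal else T_c)
    decay_e = 0.0 if literal else to_e
    decay_c = 0.0 if literal else to_c
    # allocation: apical gets 1-l_n*N; exchange face gets l_n*N
    dPa_e = (1.0 - lat) * T_e - decay_e * Pa_e
    dPb_e = -decay_e * Pb_e
    dPo_e = -decay_e * Po_e            # epidermal outer face: sink-facing
    dPi_e = lat * T_e - decay_e * Pi_e  # epidermal inner face -> cortex
    dPa_c = (1.0 - lat) * T_c - decay_c * Pa_c
    dPb_c = -decay_c * Pb_c
    dPo_c = lat * T_c - decay_c * Po_c  # cortex outer face -> epidermis
    dPi_c = -decay_c * Pi_c

    # --- auxin transport
    ka = p.k_a
    up_e = ka * A_e * Pa_e      # shootward flux out of each epidermal cell
    dn_e = ka * A_e * Pb_e      # rootward
    up_c = ka * A_c * Pa_c
    dn_c = ka * A_c * Pb_c
    lat_ec = ka * A_e * Pi_e + p.k_d * A_e       # epidermis -> cortex
    lat_ce = ka * A_c * Po_c + p.k_d * A_c       # cortex -> epidermis
    sink_e = ka * A_e * Po_e                     # epidermis -> root surface

    def file_dA(src, up, dn, lat_out, lat_in, sink):
        # top-of-window apical efflux (up[-1]) has no receiving cell: it
        # leaves with the advected column and is booked to the ledger.
        # The basal face of cell 1 is closed; allocation never targets it.
        dA = src - up - dn - lat_out + lat_in - sink
        dA[1:] += up[:-1]      # influx from below (apical of i-1)
        dA[:-1] += dn[1:]      # influx from above (basal of i+1)
        return dA

    dA_e = file_dA(src_e, up_e, dn_e, lat_ec, lat_ce, sink_e) - p.d_a * A_e
    dA_c = file_dA(np.zeros(n), up_c, dn_c, lat_ce, lat_ec, 0.0) - p.d_a * A_c

    # --- division factor
    if isinstance(p.maxA_mode, str):   # dynamic
        mer = np.concatenate([A_e[~e.elong], A_c[~c.elong]])
        maxA = float(mer.max()) if mer.size else 0.0
        if maxA <= 0.0:  # empty or auxin-free meristem: fall back to global
            maxA = float(max(A_e.max(), A_c.max()))
        maxA = max(maxA, 1e-12)
    else:
        maxA = float(p.maxA_mode)
    gate = 1.0 / (1.0 + np.exp(idx * p.t_v))

    def div_rhs(A, L, DIV):
        synth = p.k_v0 * p.k_v1 * (A / maxA + L / p.maxL) * gate
        degr = DIV * p.k_v2 * (1.0 + (A / p.k_v3) ** p.h1) \
            / (1.0 + (A / p.k_v4) ** p.h2)
        return synth - degr

    dDIV_e = div_rhs(A_e, L_e, DIV_e)
    dDIV_c = div_rhs(A_c, L_c, DIV_c)

    # --- growth
    def grow(A, L, elong):
        kl = np.where(elong, p.k_l_elongation, p.k_l_meristem)
        ml = np.where(elong, p.m_l_elongation, p.m_l_meristem)
        rate = kl * A / (A + 1.0) * L * (1.0 - L / ml)
        return np.clip(rate, 0.0, None)

    dL_e = grow(A_e, L_e, e.elong)
    dL_c = grow(A_c, L_c, c.elong)

    # --- ledger (auxin bookkeeping): top-of-window apical efflux leaves
    # with the advected cell column
    dled = np.array([
        src_e.sum(),
        p.d_a * (A_e.sum() + A_c.sum()),
        sink_e.sum(),
        up_e[-1] + up_c[-1],
    ])
    return [dA_e, dPINc_e, dPa_e, dPb_e, dPo_e, dPi_e, dDIV_e, dL_e,
            dA_c, dPINc_c, dPa_c, dPb_c, dPo_c, dPi_c, dDIV_c, dL_c, dled]


def _pack(state: RootState) -> list:
    e, c = state.epidermis, state.cortex
    return [e.A, e.PINc, e.Pm["apical"], e.Pm["basal"], e.Pm["outer"],
            e.Pm["inner"], e.DIV, e.L,
            c.A, c.PINc, c.Pm["apical"], c.Pm["basal"], c.Pm["outer"],
            c.Pm["inner"], c.DIV, c.L,
            np.array([state.ledger[k] for k in _LEDGER_KEYS])]


def _unpack(state: RootState, y: list) -> None:
    e, c = state.epidermis, state.cortex
    (e.A, e.PINc, e.Pm["apical"], e.Pm["basal"], e.Pm["outer"], e.Pm["inner"],
     e.DIV, e.L,
     c.A, c.PINc, c.Pm["apical"], c.Pm["basal"], c.Pm["outer"], c.Pm["inner"],
     c.DIV, c.L, led) = y
    state.ledger = dict(zip(_LEDGER_KEYS, (float(v) for v in led)))


def _param_vector(p: ModelParameters) -> np.ndarray:
    maxA_fixed = -1.0 if isinstance(p.maxA_mode, str) else float(p.maxA_mode)
    return np.array([
        p.k_a, p.d_a, p.m_p, p.d_p, p.q_p, p.l_n, p.tr_n, p.tr_wn, p.tr_a,
        p.tr_i, p.k_v0, p.k_v1, p.k_v2, p.k_v3, p.k_v4, p.t_v, p.h1, p.h2,
        p.k_l_meristem, p.k_l_elongation, p.m_l_meristem, p.m_l_elongation,
        p.maxL, p.k_d, 1.0 if p.literal_equations else 0.0, maxA_fixed,
    ])


_Y_ROWS = ("A", "PINc", "apical", "basal", "outer", "inner", "DIV", "L")


def _state_to_Y(state: RootState) -> np.ndarray:
    n = state.epidermis.n
    Y = np.empty((16, n))
    for f, fa in enumerate((state.epidermis, state.cortex)):
        o = 8 * f
        Y[o + 0] = fa.A
        Y[o + 1] = fa.PINc
        for j, face in enumerate(_FACE_KEYS):
            Y[o + 2 + j] = fa.Pm[face]
        Y[o + 6] = fa.DIV
        Y[o + 7] = fa.L
    return Y


def _Y_to_state(state: RootState, Y: np.ndarray) -> None:
    for f, fa in enumerate((state.epidermis, state.cortex)):
        o = 8 * f
        fa.A = Y[o + 0].copy()
        fa.PINc = Y[o + 1].copy()
        for j, face in enumerate(_FACE_KEYS):
            fa.Pm[face] = Y[o + 2 + j].copy()
        fa.DIV = Y[o + 6].copy()
        fa.L = Y[o + 7].copy()


def _advance_compiled(state: RootState, t_stop: float, h: float, N: int,
                      src_e: np.ndarray, p: ModelParameters,
                      integrator: str) -> None:
    """Advance the ODE pools to t_stop with the numba kernel (no events)."""
    span = t_stop - state.time
    if span <= 0:
        return
    nsub = int(span / h)
    rem = span - nsub * h
    Y = _state_to_Y(state)
    led = np.array([state.ledger[k] for k in _LEDGER_KEYS])
    pv = _param_vector(p)
    ee = np.ascontiguousarray(state.epidermis.elong)
    ec = np.ascontiguousarray(state.cortex.elong)
    rk4 = integrator == "rk4"
    if nsub:
        integrate_batch(Y, led, ee, ec, src_e, float(N), pv, h, nsub, rk4)
    if rem > 1e-12:
        integrate_batch(Y, led, ee, ec, src_e, float(N), pv, rem, 1, rk4)
    _Y_to_state(state, Y)
    state.ledger = dict(zip(_LEDGER_KEYS, (float(v) for v in led)))
    state.time = t_stop


def _max_rate(state: RootState, N: int, p: ModelParameters) -> Tuple[float, str]:
    """Largest total decay-rate coefficient across pools (stability check)."""
    worst, which = 0.0, "none"
    for name, fa in state.files():
        turn = p.d_p * (1.0 + fa.A / p.q_p)
        base = N * p.tr_n + (1 - N) * p.tr_wn
        idx = np.arange(1, fa.n + 1)
        rates = {
            "A": p.d_a + p.k_a * fa.total_membrane_pin() + p.k_d,
            "PINc": p.d_p * (1.0 + fa.A / p.q_p)
                    + base * logistic(p.tr_a * fa.A + p.tr_i * idx),
            "PINm": turn,
            "DIV": p.k_v2 * (1.0 + (fa.A / p.k_v3) ** p.h1)
                   / (1.0 + (fa.A / p.k_v4) ** p.h2),
            "L": np.full(fa.n, max(p.k_l_meristem, p.k_l_elongation)),
        }
        for pool, arr in rates.items():
            m = float(np.max(arr))
            if m > worst:
                worst, which = m, f"{pool} ({name})"
    return worst, which


# ---------------------------------------------------------------------------
# stepping and events
# ---------------------------------------------------------------------------

def _ode_step(state: RootState, dt: float, N: int, src_e: np.ndarray,
              p: ModelParameters, integrator: str = "rk4") -> None:
    y0 = _pack(state)
    k1 = _rhs(state, N, src_e, p, y0)
    if integrator == "euler":
        y = [a + dt * k for a, k in zip(y0, k1)]
    else:
        y1 = [a + 0.5 * dt * k for a, k in zip(y0, k1)]
        k2 = _rhs(state, N, src_e, p, y1)
        y2 = [a + 0.5 * dt * k for a, k in zip(y0, k2)]
        k3 = _rhs(state, N, src_e, p, y2)
        y3 = [a + dt * k for a, k in zip(y0, k3)]
        k4 = _rhs(state, N, src_e, p, y3)
        y = [a + (dt / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
             for a, b1, b2, b3, b4 in zip(y0, k1, k2, k3, k4)]
    # pools are non-negative; clip tiny negative undershoot from truncation
    y = [np.maximum(arr, 0.0) if j < 16 else arr for j, arr in enumerate(y)]
    _unpack(state, y)
    state.time += dt


def maybe_transition(state: RootState, N: int, p: ModelParameters) -> int:
    """Move meristem cells whose relative auxin reaches the regime threshold
    into the elongation zone (irreversible; ties transition)."""
    maxA = state.max_auxin() if isinstance(p.maxA_mode, str) \
        else float(p.maxA_mode)
    if maxA <= 0:
        return 0
    thr = p.A_thr(N)
    moved = 0
    for _, fa in state.files():
        rel = fa.A / maxA
        # the relative threshold is meaningful only once an auxin gradient
        # exists; the absolute guard keeps the near-uniform trace profile of
        # the first instants from triggering a spurious transition cascade
        new = (~fa.elong) & (rel >= thr) & (fa.A >= p.A_min_transition)
        moved += int(new.sum())
        fa.elong |= new
    return moved


def _divide_cell(fa: FileArrays, k: int, next_lineage: int) -> None:
    """Split cell k (0-based) into two daughters at k, k+1; amounts 50/50."""
    for name in ("A", "PINc", "DIV", "L"):
        arr = getattr(fa, name)
        half = arr[k] / 2.0
        setattr(fa, name, np.insert(arr, k, half))
        getattr(fa, name)[k + 1] = half
    for f in _FACE_KEYS:
        arr = fa.Pm[f]
        half = arr[k] / 2.0
        fa.Pm[f] = np.insert(arr, k, half)
        fa.Pm[f][k + 1] = half
    fa.DIV[k] = fa.DIV[k + 1] = 0.0
    fa.elong = np.insert(fa.elong, k, fa.elong[k])
    fa.lineage = np.insert(fa.lineage, k, next_lineage)


def maybe_divide(state: RootState, p: ModelParameters) -> int:
    """Divide meristem cells with DIV >= DIV_thr and L >= min_div_length.

    Candidates are processed from the QC outward; daughters each get half of
    every amount and DIV reset to 0; cells pushed past the window are
    dropped, their auxin booked to the ledger as advection loss.
    """
    events = 0
    next_lineage = int(max(state.epidermis.lineage.max(),
                           state.cortex.lineage.max())) + 1
    for name, fa in state.files():
        k = 0
        while k < fa.n:
            if (not fa.elong[k] and fa.DIV[k] >= p.DIV_thr
                    and fa.L[k] >= p.min_div_length):
                _divide_cell(fa, k, next_lineage)
                next_lineage += 1
                key = (name, k + 1)
                state.division_log[key] = state.division_log.get(key, 0) + 1
                events += 1
                k += 2          # both daughters have DIV=0; skip them
            else:
                k += 1
        # window advection
        while fa.n > p.window:
            state.ledger["advected"] += float(fa.A[-1])
            fa.A = fa.A[:-1]
            fa.PINc = fa.PINc[:-1]
            for f in _FACE_KEYS:
                fa.Pm[f] = fa.Pm[f][:-1]
            fa.DIV = fa.DIV[:-1]
            fa.L = fa.L[:-1]
            fa.elong = fa.elong[:-1]
            fa.lineage = fa.lineage[:-1]
    return events


def step(state: RootState, dt: float, regime: NitrogenRegime,
         variant="B", params: Optional[ModelParameters] = None,
         integrator: str = "rk4",
         source: Optional[SourceConfig] = None) -> RootState:
    """Advance a copy of ``state`` by one step of ``dt``: ODE update, then
    transitions, then divisions, then window advection.  Deterministic.

    Raises :class:`StabilityError` if ``dt`` exceeds the explicit stability
    bound ``dt * max_rate < 0.5``, naming the offending pool.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params or ModelParameters()
    src = source or (variant if isinstance(variant, SourceConfig)
                     else SourceConfig(str(variant)))
    new = state.copy()
    N = regime.N(new.time)
    rate, which = _max_rate(new, N, p)
    if dt * rate >= 0.5:
        raise StabilityError(
            f"dt={dt} violates stability bound for pool {which}: "
            f"rate={rate:.3g}, need dt < {0.5 / rate:.3g}")
    src_e = src.rates(p.window, p)[:new.epidermis.n]
    _ode_step(new, dt, N, src_e, p, integrator)
    maybe_transition(new, N, p)
    maybe_divide(new, p)
    return new


@dataclass
class Trajectory:
    snapshots: List[RootState]
    converged: bool
    params: ModelParameters
    regime: NitrogenRegime
    variant: str

    @property
    def final(self) -> RootState:
        return self.snapshots[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.snapshots],
                         ignore_index=True)


def run(params: Optional[ModelParameters] = None,
        regime: Optional[NitrogenRegime] = None,
        variant="B",
        horizon: float = 400.0,
        dt: Optional[float] = None,
        snapshot_every: float = 20.0,
        seed: int = 0,
        source: Optional[SourceConfig] = None,
        init: Optional[RootState] = None,
        integrator: str = "rk4",
        check_every: float = 0.25,
        conv_tol: float = 1e-3,
        use_numba: bool = True,
        transition_delay: float = 100.0) -> Trajectory:
    """Integrate from a naive uniform state to steady state or ``horizon``.

    ``dt=None`` chooses the largest stable step automatically (re-evaluated
    periodically).  The model is deterministic; ``seed`` is accepted for
    interface uniformity with the stochastic stages.  Convergence is
    declared when 10-time-unit moving averages of the summary pools (total
    auxin, meristem cell count and onset index per file) change by less
    than ``conv_tol`` relative between consecutive windows; in
    division-free configurations a strict pointwise criterion (relative
    pool change < 1e-6 over a window) is applied instead.
    """
    p = params or ModelParameters()
    regime = regime or NitrogenRegime.constant(0)
    src = source or (variant if isinstance(variant, SourceConfig)
                     else SourceConfig(str(variant)))
    state = init.copy() if init is not None else initial_state(p)
    state.initial_auxin = state.total_auxin()
    src_full = src.rates(p.window, p)

    snapshots = [state.copy()]
    converged = False
    next_snap = snapshot_every
    window_len = 10.0
    history: List[Tuple[float, np.ndarray]] = []
    prev_window: Optional[np.ndarray] = None
    divisions_in_window = 0
    pools_prev: Optional[list] = None

    t_end = float(horizon)
    while state.time < t_end - 1e-12:
        N = regime.N(state.time)
        rate, _ = _max_rate(state, N, p)
        h = dt if dt is not None else min(0.4 / max(rate, 1e-9), 0.05)
        t_stop = min(state.time + check_every, t_end)
        for sw in regime.switch_times():
            if state.time < sw < t_stop:
                t_stop = sw
        src_e = src_full[:state.epidermis.n]
        if use_numba and HAVE_NUMBA:
            _advance_compiled(state, t_stop, h, N, src_e, p, integrator)
        else:
            while state.time < t_stop - 1e-12:
                hh = min(h, t_stop - state.time)
                _ode_step(state, hh, N, src_e, p, integrator)
        # the relative-auxin transition rule describes the developed root;
        # during the establishment transient from the naive state (membrane
        # PIN2 still building up, auxin spiking) transitions are held off
        if state.time >= transition_delay:
            maybe_transition(state, N, p)
        divisions_in_window += maybe_divide(state, p)

        if state.time >= next_snap - 1e-9:
            snapshots.append(state.copy())
            next_snap += snapshot_every

        # convergence bookkeeping
        summ = _summary_vector(state)
        history.append((state.time, summ))
        history = [(t, v) for t, v in history if t > state.time - window_len]
        if history[0][0] <= state.time - window_len + 2 * check_every:
            cur = np.mean([v for _, v in history], axis=0)
            if prev_window is not None:
                denom = np.maximum(np.abs(prev_window), 1e-9)
                relchange = float(np.max(np.abs(cur - prev_window) / denom))
                if divisions_in_window == 0 and pools_prev is not None:
                    pools_now = _pack(state)[:16]
                    pd_rel = max(
                        float(np.max(np.abs(a - b)
                                     / np.maximum(np.abs(b), 1e-9)))
                        for a, b in zip(pools_now, pools_prev)
                        if a.shape == b.shape)
                    if pd_rel < 1e-6:
                        converged = True
                elif relchange < conv_tol:
                    converged = True
            prev_window = cur
            pools_prev = [a.copy() for a in _pack(state)[:16]]
            divisions_in_window = 0
            history = []
            if converged and state.time >= 50.0:
                break

    if snapshots[-1].time < state.time - 1e-9:
        snapshots.append(state.copy())
    return Trajectory(snapshots, converged, p, regime,
                      src.variant if isinstance(src, SourceConfig) else str(variant))


def _summary_vector(state: RootState) -> np.ndarray:
    out = []
    for _, fa in state.files():
        onset = int(np.argmax(fa.elong)) + 1 if fa.elong.any() else fa.n + 1
        out += [fa.A.sum(), fa.L.sum(), float((~fa.elong).sum()), float(onset)]
    return np.array(out)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryStatistics:
    onset_index: Dict[str, int]
    meristem_size_um: Dict[str, float]
    meristem_cells: Dict[str, int]
    synchrony_index: int
    division_fractions: pd.DataFrame      # file, i, fraction (sums to 1)
    profiles: pd.DataFrame                # per (file, i) pools and lengths
    lateralization_index: pd.DataFrame    # file, i, value
    total_membrane_pin: Dict[str, float]
    shootward_flux_epidermis: float
    converged: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "onset_index": self.onset_index,
            "meristem_size_um": self.meristem_size_um,
            "meristem_cells": self.meristem_cells,
            "synchrony_index": self.synchrony_index,
            "total_membrane_pin": self.total_membrane_pin,
            "shootward_flux_epidermis": self.shootward_flux_epidermis,
            "converged": self.converged,
            "division_fractions": self.division_fractions.to_dict("records"),
        }


def summarize(trajectory) -> SummaryStatistics:
    """Deterministic reductions of a trajectory's final state.

    Relative auxin is A/maxA; the lateralization index mirrors the
    experimental one: (apical+basal)/(inner+outer) membrane signal.
    """
    if isinstance(trajectory, Trajectory):
        if not trajectory.snapshots:
            raise ValueError("empty trajectory")
        state = trajectory.final
        converged = trajectory.converged
    else:
        state = trajectory
        converged = None

    maxA = max(state.max_auxin(), 1e-12)
    onset, msize, mcells, tpin = {}, {}, {}, {}
    prof_rows, lat_rows = [], []
    for name, fa in state.files():
        o = int(np.argmax(fa.elong)) + 1 if fa.elong.any() else fa.n + 1
        onset[name] = o
        msize[name] = float(fa.L[:o - 1].sum())
        mcells[name] = o - 1
        tpin[name] = float(fa.total_membrane_pin().sum())
        for k in range(fa.n):
            prof_rows.append({
                "file": name, "i": k + 1, "length": fa.L[k], "A": fa.A[k],
                "relative_auxin": fa.A[k] / maxA,
                **{f"PINm_{f}": fa.Pm[f][k] for f in _FACE_KEYS},
                "DIV": fa.DIV[k],
                "zone": "elongation" if fa.elong[k] else "meristem",
            })
            polar = fa.Pm["apical"][k] + fa.Pm["basal"][k]
            lateral = fa.Pm["inner"][k] + fa.Pm["outer"][k]
            lat_rows.append({"file": name, "i": k + 1,
                             "value": polar / max(lateral, 1e-12)})
    total = sum(state.division_log.values())
    div_rows = [{"file": f, "i": i, "fraction": cnt / total}
                for (f, i), cnt in sorted(state.division_log.items())] \
        if total else []
    e = state.epidermis
    flux = float(np.sum(e.A * e.Pm["apical"]))
    return SummaryStatistics(
        onset_index=onset, meristem_size_um=msize, meristem_cells=mcells,
        synchrony_index=abs(onset[EPIDERMIS] - onset[CORTEX]),
        division_fractions=pd.DataFrame(div_rows,
                                        columns=["file", "i", "fraction"]),
        profiles=pd.DataFrame(prof_rows),
        lateralization_index=pd.DataFrame(lat_rows),
        total_membrane_pin=tpin,
        shootward_flux_epidermis=flux,
        converged=converged)


# ---------------------------------------------------------------------------
# static-file steady state (fast path for inference / synthetic data)
# ---------------------------------------------------------------------------

def steady_state_profile(params: Optional[ModelParameters] = None,
                         N: int = 0,
                         variant="B",
                         source: Optional[SourceConfig] = None,
                         window: Optional[int] = None,
                         tol: float = 1e-10,
                         max_iter: int = 2000) -> Dict[str, pd.DataFrame]:
    """Fixed point of the auxin/PIN2 subsystem on a static pair of files.

    Growth, division and zonation do not feed back on auxin or PIN2, so the
    joint steady state solves in two stages: given auxin, the PIN2 pools
    have closed forms; substituting them leaves a fixed-point problem in
    the auxin vector alone, solved by damped iteration with a Newton-Krylov
    fallback.  Requires the mass-conserving equations (the literal printed
    equations have no membrane steady state).

    Returns ``{file: DataFrame(i, A, PINc, PINm_*, relative_auxin)}`` where
    relative auxin is normalized per file over the first 20 cells,
    mirroring the per-root normalization of the ratiometric reporter.
    """
    p = params or ModelParameters()
    n = window or p.window
    src = source or (variant if isinstance(variant, SourceConfig)
                     else SourceConfig(str(variant)))
    A_e, A_c, pools = solve_subsystem(p, N, src, n, tol=tol,
                                      max_iter=max_iter)
    out = {}
    for name, A in ((EPIDERMIS, A_e), (CORTEX, A_c)):
        PINc, Pa, Pex = pools[name]
        zeros = np.zeros(n)
        pm = {"apical": Pa, "basal": zeros,
              "outer": Pex if name == CORTEX else zeros,
              "inner": Pex if name == EPIDERMIS else zeros}
        ref = max(float(A[:min(20, n)].max()), 1e-12)
        out[name] = pd.DataFrame({
            "i": np.arange(1, n + 1), "A": A, "PINc": PINc,
            **{f"PINm_{f}": pm[f] for f in _FACE_KEYS},
            "relative_auxin": A / ref,
        })
    return out


def solve_subsystem(p: ModelParameters, N: int, src: SourceConfig,
                    n: Optional[int] = None, tol: float = 1e-10,
                    max_iter: int = 2000,
                    x0: Optional[Tuple[np.ndarray, np.ndarray]] = None):
    """Raw-array fixed point of the auxin/PIN2 subsystem.

    Returns ``(A_epidermis, A_cortex, pools)`` with ``pools[file] =
    (PINc, PINm_apical, PINm_lateral)`` — the lateral entry is the
    file-exchange face (inner for the epidermis, outer for the cortex).
    """
    if p.literal_equations:
        raise ValueError("no membrane steady state under literal_equations")
    n = n or p.window
    src_e = src.rates(n, p)
    idx = np.arange(1, n + 1, dtype=float)
    lat = p.l_n * N
    base = N * p.tr_n + (1 - N) * p.tr_wn

    def pin_pools(A):
        lg = logistic(p.tr_a * A + p.tr_i * idx)
        turn = p.d_p * (1.0 + A / p.q_p)
        PINc = p.m_p / (turn + base * lg)
        T = PINc * base * lg
        Pa = (1.0 - lat) * T / turn
        Pex = lat * T / turn
        return PINc, Pa, Pex

    def residual(x):
        A_e, A_c = x[:n], x[n:]
        _, Pa_e, Pi_e = pin_pools(A_e)
        _, Pa_c, Po_c = pin_pools(A_c)
        up_e, up_c = p.k_a * A_e * Pa_e, p.k_a * A_c * Pa_c
        lat_ec = p.k_a * A_e * Pi_e + p.k_d * A_e
        lat_ce = p.k_a * A_c * Po_c + p.k_d * A_c
        F_e = src_e - up_e - lat_ec + lat_ce - p.d_a * A_e
        F_e[1:] += up_e[:-1]
        F_c = -up_c - lat_ce + lat_ec - p.d_a * A_c
        F_c[1:] += up_c[:-1]
        return np.concatenate([F_e, F_c])

    def picard(A_e, A_c, omega, iters):
        ok = False
        for _ in range(iters):
            _, Pa_e, Pi_e = pin_pools(A_e)
            _, Pa_c, Po_c = pin_pools(A_c)
            up_e, up_c = p.k_a * A_e * Pa_e, p.k_a * A_c * Pa_c
            in_e = src_e.copy()
            in_e[1:] += up_e[:-1]
            in_e += p.k_a * A_c * Po_c + p.k_d * A_c
            out_e = p.k_a * (Pa_e + Pi_e) + p.k_d + p.d_a
            in_c = np.zeros(n)
            in_c[1:] += up_c[:-1]
            in_c += p.k_a * A_e * Pi_e + p.k_d * A_e
            out_c = p.k_a * (Pa_c + Po_c) + p.k_d + p.d_a
            new_e, new_c = in_e / out_e, in_c / out_c
            delta = max(np.max(np.abs(new_e - A_e) / np.maximum(A_e, 1e-9)),
                        np.max(np.abs(new_c - A_c) / np.maximum(A_c, 1e-9)))
            A_e = (1 - omega) * A_e + omega * new_e
            A_c = (1 - omega) * A_c + omega * new_c
            if delta < tol:
                ok = True
                break
        return A_e, A_c, ok

    if x0 is not None and x0[0].size == n:
        A_e, A_c = x0[0].copy(), x0[1].copy()
    else:
        A_e = src_e / p.d_a * 0.01 + 1e-3
        A_c = np.full(n, 1e-3)
    ok = False
    if HAVE_NUMBA:
        its = subsystem_gauss_seidel(A_e, A_c, np.ascontiguousarray(src_e),
                                     float(N), _param_vector(p), 0.7, tol,
                                     max_iter)
        ok = its > 0
    if not ok:
        A_e, A_c, ok = picard(A_e, A_c, 0.5, max_iter)
    if not ok:   # heavier damping from the last iterate
        A_e, A_c, ok = picard(A_e, A_c, 0.1, 5 * max_iter)
    if not ok or np.max(np.abs(residual(np.concatenate([A_e, A_c])))) > 1e-6:
        x0 = np.concatenate([A_e, A_c])
        for method in ("hybr", "lm"):
            sol = optimize.root(residual, x0, method=method)
            if sol.success and np.all(sol.x > -1e-9):
                break
        else:
            raise RuntimeError(f"steady-state solve failed: {sol.message}")
        A_e, A_c = np.maximum(sol.x[:n], 0.0), np.maximum(sol.x[n:], 0.0)

    return A_e, A_c, {EPIDERMIS: pin_pools(A_e), CORTEX: pin_pools(A_c)}
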