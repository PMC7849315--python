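"""Per-cell dynamical rules of the root growth model.

Two ordered cell files (epidermis and cortex, indexed outward from the
quiescent centre) carry five coupled quantities per cell: auxin amount A,
cytoplasmic PIN2, membrane PIN2 per face, a division factor DIV, and cell
length.  Auxin enters the epidermis from the QC and the lateral root cap,
moves between cells through membrane-localized PIN2 carriers, and is
degraded; PIN2 is synthesized in the cytoplasm and trafficked to membrane
faces at a rate controlled by the nitrogen source, auxin, and distance from
the QC.  Nitrate redirects a fraction ``l_n`` of trafficked PIN2 to the
lateral face, rerouting auxin between the files.

Functions here are pure and operate on a single :class:`Cell`; the
vectorized implementations used by the simulator mirror these formulas
exactly and are cross-checked against them in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .params import ModelParameters, NitrogenRegime

logger = logging.getLogger(__name__)

FACES = ("apical", "basal", "outer", "inner")
EPIDERMIS = "epidermis"
CORTEX = "cortex"
FILES = (EPIDERMIS, CORTEX)

#: membrane face through which a file exchanges auxin with the adjacent file.
#: The cortex lateral face is its outer face (toward the epidermis); the
#: epidermal lateral face is its inner face (toward the cortex).  The
#: epidermal *outer* face abuts the root surface: anything pumped through it
#: leaves the system.
EXCHANGE_FACE = {EPIDERMIS: "inner", CORTEX: "outer"}
SINK_FACE = {EPIDERMIS: "outer", CORTEX: None}

VARIANTS = ("A", "B", "C", "D")

_CLAMP_WARNED: set = set()


@dataclass
class Cell:
    """State of one cell: pools are amounts (a.u.), length in µm."""

    file: str
    i: int                      # 1-based index from the QC
    length: float = 10.0
    zone: str = "meristem"      # meristem -> elongation, one way
    A: float = 0.0
    PINc: float = 0.0
    PINm: Dict[str, float] = field(default_factory=lambda: dict.fromkeys(FACES, 0.0))
    DIV: float = 0.0
    lineage: int = 0

    def total_membrane_pin(self) -> float:
        return float(sum(self.PINm.values()))


def logistic(x: float) -> float:
    """Standard logistic 1/(1+exp(-x)); saturates for large |x|."""
    # evaluate on the side that cannot overflow
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass
class SourceConfig:
    """Variant-specific auxin source into the epidermis.

    A: uniform rate along the file; B: two rates split at cell index z
    (QC-proximal source below, lateral-root-cap influx at/above); C: natural
    cubic spline through knots, clamped non-negative; D: a free per-cell
    rate vector.
    """

    variant: str = "B"
    uniform_rate: Optional[float] = None          # variant A
    knots_x: Optional[Sequence[float]] = None      # variant C
    knots_y: Optional[Sequence[float]] = None
    per_cell: Optional[Sequence[float]] = None     # variant D

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")

    def rates(self, window: int, params: ModelParameters) -> np.ndarray:
        """Epidermal source rate for cells i = 1..window."""
        i = np.arange(1, window + 1, dtype=float)
        if self.variant == "B":
            return np.where(i < params.z, params.s1, params.s2)
        if self.variant == "A":
            rate = self.uniform_rate
            if rate is None:
                # default: same total input as the two-rate model
                rate = float(np.mean(np.where(i < params.z, params.s1, params.s2)))
            return np.full(window, float(rate))
        if self.variant == "C":
            kx = self.knots_x if self.knots_x is not None else [1, 7, 13, 19, 25]
            ky = self.knots_y if self.knots_y is not None else [params.s1] * len(kx)
            spline = CubicSpline(kx, ky, bc_type="natural")
            vals = spline(i)
            if np.any(vals < 0):
                # warn once per process; repeated clamps (e.g. inside a
                # sampler loop) log at debug level only
                level = logging.DEBUG if _CLAMP_WARNED else logging.WARNING
                logger.log(level, "spline source negative at %d positions; "
                           "clamped to 0", int(np.sum(vals < 0)))
                _CLAMP_WARNED.add(True)
                vals = np.clip(vals, 0.0, None)
            return np.asarray(vals, dtype=float)
        # variant D
        if self.per_cell is None:
            raise ValueError("variant D requires a per-cell source vector")
        vec = np.asarray(self.per_cell, dtype=float)
        if vec.size < window:
            raise ValueError(
                f"variant D source vector has {vec.size} entries; window={window}")
        return vec[:window].copy()


def auxin_source(i: int, file: str, variant, params: ModelParameters,
                 source: Optional[SourceConfig] = None) -> float:
    """Auxin production/influx rate (a.u./time) into cell *i* of *file*.

    The cortex receives no source in any variant; only the epidermis is fed
    (from the QC below index z and the lateral root cap at/above it in the
    default two-rate variant).
    """
    if i < 1:
        raise ValueError("cell index is 1-based")
    if file == CORTEX:
        return 0.0
    if source is None:
        source = variant if isinstance(variant, SourceConfig) else SourceConfig(str(variant))
    return float(source.rates(max(int(np.ceil(i)), 1), params)[int(i) - 1])


def trafficking_logistic_arg(A: float, i: float, params: ModelParameters) -> float:
    return params.tr_a * A + params.tr_i * i


def pin2_trafficking_rate(cell: Cell, regime: NitrogenRegime | int,
                          params: ModelParameters, t: float = 0.0,
                          ) -> Tuple[float, Dict[str, float]]:
    """Total PIN2 delivery rate from the cytoplasm and its per-face split.

    total = PINc * [N*tr_n + (1-N)*tr_wn] * logistic(tr_a*A + tr_i*i).
    A fraction ``l_n * N`` of the delivered protein is redirected to the
    lateral (file-exchange) face under nitrate; the remainder goes to the
    apical face (default polarity in both files).  The basal face and the
    epidermal outer (soil-facing) face receive nothing by default.
    """
    N = regime.N(t) if isinstance(regime, NitrogenRegime) else int(regime)
    base = N * params.tr_n + (1 - N) * params.tr_wn
    total = cell.PINc * base * logistic(trafficking_logistic_arg(cell.A, cell.i, params))
    lateral = params.l_n * N
    alloc = dict.fromkeys(FACES, 0.0)
    alloc["apical"] = 1.0 - lateral
    alloc[EXCHANGE_FACE[cell.file]] = lateral
    return float(total), alloc


def pin2_cytoplasm_rhs(cell: Cell, params: ModelParameters,
                       regime: NitrogenRegime | int = 0, t: float = 0.0) -> float:
    """dPINc/dt = m_p - d_p*PINc*(1+A/q_p) - trafficking outflow.

    The outflow debit keeps total PIN2 conserved between the cytoplasmic and
    membrane pools; with ``literal_equations`` the debit is dropped (the
    printed equations create membrane PIN2 without depleting the cytoplasm).
    """
    rate = params.m_p - params.d_p * cell.PINc * (1.0 + cell.A / params.q_p)
    if not params.literal_equations:
        total, _ = pin2_trafficking_rate(cell, regime, params, t)
        rate -= total
    return float(rate)


def pin2_membrane_rhs(cell: Cell, face: str, regime: NitrogenRegime | int,
                      params: ModelParameters, t: float = 0.0) -> float:
    """dPINm_face/dt = delivery - auxin-promoted membrane turnover."""
    if face not in FACES:
        raise ValueError(f"unknown face {face!r}")
    total, alloc = pin2_trafficking_rate(cell, regime, params, t)
    rate = alloc[face] * total
    if not params.literal_equations:
        rate -= params.d_p * (1.0 + cell.A / params.q_p) * cell.PINm[face]
    return float(rate)


def auxin_rhs(cell: Cell,
              neighbors: Iterable[Tuple[Cell, str, str]],
              regime: NitrogenRegime | int,
              variant,
              params: ModelParameters,
              t: float = 0.0,
              source: Optional[SourceConfig] = None) -> float:
    """dA/dt for one cell given its shared walls.

    ``neighbors`` lists each shared wall once as ``(other, face_out, face_in)``
    where ``face_out`` is this cell's face on the wall and ``face_in`` the
    neighbour's.  Carrier flux through a wall is ``k_a * A * PINm_face`` per
    side; the epidermal outer face has no neighbour and its efflux is simply
    removed (flux to the root surface).  A weak passive permeability ``k_d``
    acts across the lateral wall between the files.
    """
    rate = auxin_source(cell.i, cell.file, variant, params, source=source)
    for other, face_out, face_in in neighbors:
        if face_out not in FACES or (face_in is not None and face_in not in FACES):
            raise ValueError(f"unknown face pairing ({face_out!r}, {face_in!r})")
        rate -= params.k_a * cell.A * cell.PINm[face_out]
        if other is not None:
            rate += params.k_a * other.A * other.PINm[face_in]
            lateral_wall = other.file != cell.file
            if lateral_wall:
                rate += params.k_d * (other.A - cell.A)
    # sink flux through the epidermal outer face, if not already listed
    walls = [f for _, f, _ in neighbors] if neighbors else []
    sink = SINK_FACE.get(cell.file)
    if sink and sink not in walls:
        rate -= params.k_a * cell.A * cell.PINm[sink]
    rate -= params.d_a * cell.A
    return float(rate)


def division_factor_rhs(cell: Cell, maxA: float, params: ModelParameters) -> float:
    """dDIV/dt: position-gated, auxin- and size-promoted synthesis minus
    auxin-modulated first-order degradation.

    synthesis = k_v0*k_v1*(A/maxA + len/maxL) / (1 + exp(i*t_v))
    degradation = DIV * k_v2 * (1 + (A/k_v3)^h1) / (1 + (A/k_v4)^h2)
    """
    if maxA <= 0:
        raise ValueError("maxA must be > 0 (normalization undefined)")
    if params.maxL <= 0:
        raise ValueError("maxL must be > 0")
    synth = (params.k_v0 * params.k_v1
             * (cell.A / maxA + cell.length / params.maxL)
             / (1.0 + np.exp(cell.i * params.t_v)))
    degr = (cell.DIV * params.k_v2
            * (1.0 + (cell.A / params.k_v3) ** params.h1)
            / (1.0 + (cell.A / params.k_v4) ** params.h2))
    return float(synth - degr)


def growth_rhs(cell: Cell, params: ModelParameters) -> float:
    """dL/dt = k_l(zone) * A/(A+1) * L * (1 - L/m_l(zone)); never negative."""
    m_l = params.m_l(cell.zone)
    if cell.length > m_l:
        warnings.warn(f"cell length {cell.length} exceeds m_l={m_l}; growth clamped",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    rate = (params.k_l(cell.zone) * cell.A / (cell.A + 1.0)
            * cell.length * (1.0 - cell.length / m_l))
    return float(max(rate, 0.0))
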