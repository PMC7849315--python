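"""Synthetic observation generators.

Two kinds of generator cover the measurement types of the study:

* *Phenomenological* generators draw observations around mean curves
  calibrated to the printed summary statistics of the imaging data — the
  flat-then-linear cell-length profiles with their published slopes over
  positions 10-20 and elongation onsets, the ratiometric auxin-reporter
  (Venus/Tomato) profiles, and PIN2 membrane-intensity contrasts.  Noise
  is Gamma-distributed around the mean curve, matching the distribution
  family identified for the cell-length data.

* The *model-based* generator simulates the mechanistic model to steady
  state and corrupts its predictions with multiplicative Gamma noise, for
  parameter-recovery and model-comparison studies.

Every generator is a pure function of (calibration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import CORTEX, EPIDERMIS, SourceConfig
from .obs import CONDITION_N, DETECTION_FLOOR, N_CONDITION, \
    validate_observations
from .params import ModelParameters, NitrogenRegime
from .simulator import run, steady_state_profile, summarize

__all__ = [
    "GeneratorCalibration", "generate_length_profiles",
    "generate_model_observations", "generate_pin2_profiles",
    "generate_r2d2_profiles", "normalize_r2d2",
]


@dataclass
class LengthBlock:
    """Mean-curve calibration for one (condition, tissue) length profile."""
    L0: float            # meristematic baseline length (µm)
    onset: int           # first elongating cell (index from QC)
    slope: float         # target OLS slope over positions 10-20 (µm/cell)
    noise_shape: float = 16.0   # Gamma shape (cv ~ 25%); inf = deterministic

    def __post_init__(self):
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if not 8 <= self.onset <= 16:
            raise ValueError("onset must lie in [8, 16]")
        if self.noise_shape <= 0:
            raise ValueError("noise shape must be > 0")


@dataclass
class R2D2Block:
    """Relative-auxin ramp for one (condition, tissue): a logistic rise
    from `base` toward 1 centred at `midpoint` with the given `width`."""
    base: float
    midpoint: float
    width: float
    noise_shape: float = 30.0


@dataclass
class Pin2Block:
    """Phenomenological PIN2 face-intensity means for one condition."""
    apical: float
    lateral: float
    noise_shape: float = 16.0


def _default_lengths() -> Dict[Tuple[str, str], LengthBlock]:
    # slopes over cells 10-20 from the published length profiles (n=18
    # roots/condition); epidermal onsets at cells 11 (ammonium) and 13
    # (nitrate); cortex onsets chosen for the observed asynchrony on
    # ammonium and synchrony on nitrate.
    return {
        ("ammonium", EPIDERMIS): LengthBlock(10.0, 11, 3.32639),
        ("ammonium", CORTEX): LengthBlock(10.0, 14, 1.22033),
        ("nitrate", EPIDERMIS): LengthBlock(10.0, 13, 1.70502),
        ("nitrate", CORTEX): LengthBlock(10.0, 13, 0.82342),
    }


def _default_r2d2() -> Dict[Tuple[str, str], R2D2Block]:
    # ammonium: auxin activity rises earlier and steeper in the epidermis
    # than the cortex; nitrate: epidermis and cortex share a common trend.
    return {
        ("ammonium", EPIDERMIS): R2D2Block(0.15, 13.0, 2.5),
        ("ammonium", CORTEX): R2D2Block(0.12, 18.0, 4.0),
        ("nitrate", EPIDERMIS): R2D2Block(0.15, 15.0, 3.5),
        ("nitrate", CORTEX): R2D2Block(0.15, 15.0, 3.5),
    }


def _default_pin2() -> Dict[str, Pin2Block]:
    # nitrate raises total membrane PIN2 and moves signal to lateral faces
    return {
        "ammonium": Pin2Block(apical=300.0, lateral=25.0),
        "nitrate": Pin2Block(apical=150.0, lateral=215.0),
    }


@dataclass
class GeneratorCalibration:
    lengths: Dict[Tuple[str, str], LengthBlock] = field(
        default_factory=_default_lengths)
    r2d2: Dict[Tuple[str, str], R2D2Block] = field(
        default_factory=_default_r2d2)
    pin2: Dict[str, Pin2Block] = field(default_factory=_default_pin2)
    positions: int = 20
    master_seed: int = 0


def mean_length_curve(block: LengthBlock, positions: int = 20,
                      lo: int = 10, hi: int = 20) -> np.ndarray:
    """Flat-then-linear mean curve whose expected OLS slope over
    [lo, hi] equals the calibration target exactly.

    The curve is L0 for positions below the onset o and rises linearly
    from there; the per-cell increment g is the closed-form solution of
    slope_OLS(curve[lo..hi]) = target, which is linear in g.
    """
    p = np.arange(1, positions + 1, dtype=float)
    ramp = np.maximum(0.0, p - (block.onset - 1))
    win = (p >= lo) & (p <= hi)
    x = p[win]
    xc = x - x.mean()
    s_xx = float(np.sum(xc ** 2))
    s_xr = float(np.sum(xc * ramp[win]))
    if s_xr <= 0:
        raise ValueError("onset too high for the slope window")
    g = block.slope * s_xx / s_xr
    curve = block.L0 + g * ramp
    if np.any(curve <= 0):
        raise ValueError("infeasible slope/onset combination")
    return curve


def _gamma_around(rng: np.random.Generator, mean: np.ndarray,
                  shape: float) -> np.ndarray:
    if not np.isfinite(shape):
        return np.asarray(mean, dtype=float).copy()
    return rng.gamma(shape, np.asarray(mean) / shape)


def generate_length_profiles(calibration: Optional[GeneratorCalibration] = None,
                             condition: str = "ammonium",
                             n_roots: int = 18,
                             seed: int = 0,
                             tissues: Sequence[str] = (EPIDERMIS, CORTEX),
                             ) -> pd.DataFrame:
    """Cell-length profiles for ``n_roots`` roots at positions 1-20."""
    if n_roots < 2:
        raise ValueError("n_roots must be >= 2")
    cal = calibration or GeneratorCalibration()
    rng = np.random.default_rng([seed, cal.master_seed, CONDITION_N[condition]])
    rows = []
    for tissue in tissues:
        block = cal.lengths[(condition, tissue)]
        curve = mean_length_curve(block, cal.positions)
        for root in range(n_roots):
            vals = _gamma_around(rng, curve, block.noise_shape)
            for pos, v in enumerate(vals, start=1):
                rows.append((condition, tissue, pos, root, "length", "", v))
    return validate_observations(
        pd.DataFrame(rows, columns=["condition", "tissue", "position",
                                    "replicate", "measurement", "face",
                                    "value"]))


def normalize_r2d2(venus: np.ndarray, tomato: np.ndarray) -> np.ndarray:
    """Relative auxin from a ratiometric reporter profile.

    The auxin-degradable Venus signal is divided by the stable Tomato
    signal per position; the reciprocal of this ratio, normalized to its
    per-root maximum, is the relative auxin level: a_i =
    (1/r_i)/max_j(1/r_j) in (0, 1], higher where Venus is degraded, i.e.
    more auxin.
    """
    venus = np.asarray(venus, dtype=float)
    tomato = np.asarray(tomato, dtype=float)
    if venus.shape != tomato.shape:
        raise ValueError("venus and tomato must have equal length")
    if np.any(tomato <= 0):
        raise ValueError("tomato signal must be positive everywhere")
    if np.any(venus < 0):
        raise ValueError("venus signal must be non-negative")
    with np.errstate(divide="ignore"):
        inv = tomato / venus          # = 1/r, inf where venus == 0
    if np.any(np.isinf(inv)):
        return np.where(np.isinf(inv), 1.0, 0.0)
    return inv / inv.max()


def generate_r2d2_profiles(calibration: Optional[GeneratorCalibration] = None,
                           condition: str = "ammonium",
                           n_roots: int = 5,
                           seed: int = 0) -> pd.DataFrame:
    """Ratiometric reporter profiles, normalized per root.

    Venus/Tomato pairs are drawn so that the expected normalized profile
    follows the calibrated relative-auxin ramp for each tissue.
    """
    cal = calibration or GeneratorCalibration()
    rng = np.random.default_rng([seed + 1000, cal.master_seed,
                                 CONDITION_N[condition]])
    p = np.arange(1, cal.positions + 1, dtype=float)
    rows = []
    for root in range(n_roots):
        # one normalization constant per root: both tissue profiles of the
        # same root are normalized by their common maximum, so the
        # between-tissue amplitude contrast survives the normalization
        venus, tomato = {}, {}
        for tissue in (EPIDERMIS, CORTEX):
            block = cal.r2d2[(condition, tissue)]
            target = block.base + (1.0 - block.base) / (
                1.0 + np.exp(-(p - block.midpoint) / block.width))
            tomato[tissue] = _gamma_around(rng, np.full(p.size, 100.0), 30.0)
            ratio = _gamma_around(rng, 1.0 / target, block.noise_shape)
            venus[tissue] = tomato[tissue] * ratio
        joint = normalize_r2d2(
            np.concatenate([venus[EPIDERMIS], venus[CORTEX]]),
            np.concatenate([tomato[EPIDERMIS], tomato[CORTEX]]))
        joint = np.clip(joint, 1e-9, 1.0)
        for t_idx, tissue in enumerate((EPIDERMIS, CORTEX)):
            rel = joint[t_idx * cal.positions:(t_idx + 1) * cal.positions]
            for pos, v in enumerate(rel, start=1):
                rows.append((condition, tissue, pos, root,
                             "relative_auxin", "", v))
    return validate_observations(
        pd.DataFrame(rows, columns=["condition", "tissue", "position",
                                    "replicate", "measurement", "face",
                                    "value"]))


def generate_pin2_profiles(calibration: Optional[GeneratorCalibration] = None,
                           condition: str = "ammonium",
                           n_roots: int = 5,
                           seed: int = 0) -> pd.DataFrame:
    """Phenomenological PIN2 membrane-intensity observations.

    Mean apical and lateral face intensities are condition-calibrated:
    nitrate raises the total membrane signal and shifts it laterally.
    """
    cal = calibration or GeneratorCalibration()
    rng = np.random.default_rng([seed + 2000, cal.master_seed,
                                 CONDITION_N[condition]])
    block = cal.pin2[condition]
    rows = []
    for tissue in (EPIDERMIS, CORTEX):
        for face, mean in (("apical", block.apical),
                           ("lateral", block.lateral)):
            for root in range(n_roots):
                vals = _gamma_around(
                    rng, np.full(cal.positions, mean), block.noise_shape)
                for pos, v in enumerate(vals, start=1):
                    rows.append((condition, tissue, pos, root,
                                 "pin2_intensity", face, v))
    return validate_observations(
        pd.DataFrame(rows, columns=["condition", "tissue", "position",
                                    "replicate", "measurement", "face",
                                    "value"]))


def generate_model_observations(params: Optional[ModelParameters] = None,
                                variant="B",
                                conditions: Sequence[str] = ("ammonium",
                                                             "nitrate"),
                                noise_cv: float = 0.05,
                                seed: int = 0,
                                n_roots: int = 5,
                                measurements: Sequence[str] = (
                                    "pin2_intensity", "relative_auxin"),
                                positions: int = 20,
                                source: Optional[SourceConfig] = None,
                                ) -> pd.DataFrame:
    """Simulate the model to steady state and corrupt with Gamma noise.

    PIN2 intensities and relative auxin come from the static-file steady
    state of the auxin/PIN2 subsystem (the quantity the snapshot
    measurements emulate); length profiles, when requested, come from a
    full dynamic run.  ``noise_cv`` is the coefficient of variation of
    the multiplicative Gamma noise (0 = exact predictions).
    """
    from .inference import predict_observables   # local import, no cycle
    p = params or ModelParameters()
    rows = []
    for condition in conditions:
        pred = predict_observables(p, variant, condition,
                                   measurements=measurements,
                                   positions=positions, source=source)
        rng = np.random.default_rng([seed + 3000, CONDITION_N[condition]])
        shape = np.inf if noise_cv == 0 else 1.0 / noise_cv ** 2
        for (tissue, measurement, face), curve in pred.items():
            curve = np.maximum(curve, DETECTION_FLOOR)
            for root in range(n_roots):
                vals = _gamma_around(rng, curve, shape)
                if measurement == "relative_auxin":
                    vals = np.clip(vals, 1e-9, 1.0)
                for pos, v in enumerate(vals, start=1):
                    rows.append((condition, tissue, pos, root,
                                 measurement, face, v))
    return validate_observations(
        pd.DataFrame(rows, columns=["condition", "tissue", "position",
                                    "replicate", "measurement", "face",
                                    "value"]))
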