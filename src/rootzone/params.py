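"""Model parameters and the nitrogen regime.

The parameter set collects every symbol of the coupled per-cell ODEs for
auxin, PIN2 (cytoplasmic and membrane pools), the division factor and cell
growth, together with artifact-level constants the printed model leaves
open (elongation thresholds, division trigger, window size, lateral wall
permeability).  Defaults are the posterior means of the published
calibration; lengths are in µm, auxin and PIN2 in arbitrary units, and
time is in model units fixed by the transport normalization k_a = 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

__all__ = ["ModelParameters", "NitrogenRegime", "load_params", "dump_params"]


def _calibrated_thresholds() -> dict:
    """Read the bundled elongation-threshold calibration.

    The relative-auxin thresholds that trigger elongation are not printed in
    the source model; they are calibrated by ``scripts/calibrate_thresholds.py``
    so that default steady states place the epidermal elongation onset at
    cell 11 on ammonium and cell 13 on nitrate, and stored as package config.
    """
    cfg = resources.files("rootzone").joinpath("config/thresholds.yaml")
    with cfg.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


_THR = _calibrated_thresholds()

# Aliases accepted on load: the printed table lists a single k_l and m_l,
# the prose makes both zone dependent.
_ALIASES = {"k_l": ("k_l_meristem", "k_l_elongation"),
            "m_l": ("m_l_meristem", "m_l_elongation")}


@dataclass
class ModelParameters:
    # auxin production and turnover
    s1: float = 8.36          # epidermal source rate below z (a.u./time)
    s2: float = 22.53         # epidermal source rate at/above z (a.u./time)
    z: float = 10.6           # source-switch cell index (cells from QC)
    k_a: float = 1.0          # carrier transport rate (per PIN2 unit/time)
    d_a: float = 0.018        # auxin degradation rate (1/time)
    # PIN2 synthesis, degradation, trafficking
    m_p: float = 30.49        # basal PIN2 synthesis (a.u./time)
    d_p: float = 0.065        # basal PIN2 degradation (1/time)
    q_p: float = 100.0        # auxin scale of degradation enhancement (a.u.)
    l_n: float = 0.60         # lateral redirection fraction under nitrate
    tr_n: float = 0.246       # basal trafficking rate on nitrate (1/time)
    tr_wn: float = 0.13       # basal trafficking rate on ammonium (1/time)
    tr_a: float = -0.05       # logistic coefficient on auxin (1/a.u.)
    tr_i: float = 0.30        # logistic coefficient on cell index (1/cell)
    # division factor
    k_v0: float = 1.5
    k_v1: float = 20.0
    k_v2: float = 0.3
    k_v3: float = 3.5
    k_v4: float = 0.5
    t_v: float = 0.1          # positional tolerance factor (1/cell)
    h1: float = 2.0
    h2: float = 3.0
    # growth
    k_l_meristem: float = 0.3
    k_l_elongation: float = 0.3
    m_l_meristem: float = 200.0
    m_l_elongation: float = 200.0
    # normalization and artifact-level constants
    maxA_mode: Union[str, float] = "dynamic"  # "dynamic" or a fixed a.u. value
    maxL: float = 200.0       # length normalization (defaults to m_l_elongation)
    A_thr_ammonium: float = _THR["A_thr_ammonium"]
    A_thr_nitrate: float = _THR["A_thr_nitrate"]
    A_min_transition: float = _THR["A_min_transition"]
    DIV_thr: float = _THR["DIV_thr"]
    min_div_length: float = _THR["min_div_length"]
    window: int = 40          # cells retained per file from the QC
    k_d: float = _THR["k_d"]  # passive lateral wall permeability (1/time)
    literal_equations: bool = False  # disable the mass-conservation corrections

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = ["s1", "s2", "k_a", "d_a", "m_p", "d_p", "q_p", "tr_n",
                  "tr_wn", "tr_i", "k_v0", "k_v1", "k_v2", "k_v3", "k_v4",
                  "t_v", "k_l_meristem", "k_l_elongation", "m_l_meristem",
                  "m_l_elongation", "maxL", "A_thr_ammonium", "A_thr_nitrate",
                  "A_min_transition", "DIV_thr", "min_div_length", "k_d"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if not 0.0 <= self.l_n <= 1.0:
            raise ValueError("l_n must lie in [0, 1]")
        if self.h1 < 1 or self.h2 < 1:
            raise ValueError("Hill exponents h1, h2 must be >= 1")
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.window < 20:
            raise ValueError("window must be >= 20")
        if isinstance(self.maxA_mode, str):
            if self.maxA_mode != "dynamic":
                raise ValueError("maxA_mode must be 'dynamic' or a number")
        elif self.maxA_mode <= 0:
            raise ValueError("fixed maxA must be > 0")

    # -- growth/normalization helpers ------------------------------------
    def k_l(self, zone: str) -> float:
        return self.k_l_meristem if zone == "meristem" else self.k_l_elongation

    def m_l(self, zone: str) -> float:
        return self.m_l_meristem if zone == "meristem" else self.m_l_elongation

    def A_thr(self, N: int) -> float:
        return self.A_thr_nitrate if N else self.A_thr_ammonium

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, mapping: dict | None) -> "ModelParameters":
        """Build parameters from a mapping; missing keys take table defaults.

        Unknown keys raise (catches typos such as ``"trn "``); the aliases
        ``k_l`` and ``m_l`` set both zone-specific values at once.
        """
        mapping = dict(mapping or {})
        known = set(cls.field_names())
        out: dict = {}
        for key, value in mapping.items():
            if key in _ALIASES:
                for target in _ALIASES[key]:
                    out.setdefault(target, value)
            elif key in known:
                out[key] = value
            else:
                raise KeyError(f"unknown parameter key: {key!r}")
        return cls(**out)


def load_params(path: Union[str, Path]) -> ModelParameters:
    """Load parameters from a YAML or JSON mapping (empty file = defaults)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise TypeError(f"{path}: expected a mapping of parameter names")
    return ModelParameters.from_dict(data)


def dump_params(params: ModelParameters, path: Union[str, Path]) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


class NitrogenRegime:
    """Binary nitrate schedule: N(t) = 1 on nitrate, 0 on ammonium.

    The schedule is an ordered list of ``(time, N)`` pairs with strictly
    increasing times; N(t) is piecewise constant and right-continuous,
    mirroring transfer experiments in which seedlings are moved between
    ammonium- and nitrate-supplemented media.
    """

    _NAMES = {"ammonium": 0, "nitrate": 1, "0": 0, "1": 1}

    def __init__(self, schedule: Iterable[tuple]):
        sched = [(float(t), int(n)) for t, n in schedule]
        if not sched:
            raise ValueError("schedule must contain at least one entry")
        times = [t for t, _ in sched]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if any(n not in (0, 1) for _, n in sched):
            raise ValueError("N must be binary (0 = ammonium, 1 = nitrate)")
        self.schedule = sched

    @classmethod
    def constant(cls, condition: Union[str, int]) -> "NitrogenRegime":
        if isinstance(condition, str):
            condition = cls._NAMES[condition]
        return cls([(0.0, int(condition))])

    @classmethod
    def from_string(cls, text: str) -> "NitrogenRegime":
        """Parse e.g. ``"0:ammonium,500:nitrate"``."""
        entries = []
        for part in text.split(","):
            t, _, name = part.strip().partition(":")
            name = name.strip().lower()
            if name not in cls._NAMES:
                raise ValueError(f"unknown condition {name!r}")
            entries.append((float(t), cls._NAMES[name]))
        return cls(entries)

    def N(self, t: float) -> int:
        value = self.schedule[0][1]
        for time, n in self.schedule:
            if t >= time:
                value = n
            else:
                break
        return value

    __call__ = N

    def switch_times(self) -> Sequence[float]:
        return [t for t, _ in self.schedule[1:]]

    def __repr__(self) -> str:  # pragma: no cover
        body = ",".join(f"{t:g}:{'nitrate' if n else 'ammonium'}"
                        for t, n in self.schedule)
        return f"NitrogenRegime({body})"
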