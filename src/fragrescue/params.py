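"""Parameter containers, unit handling and flat-config I/O.

Internal units are fixed throughout the package: volumes in ml, times in
minutes, concentrations in ug/ml, populations in cells.  Picolitres and
cubic micrometres are accepted only at the interface layer (CLI flags and
config files) and converted on entry: 1 pl = 1e-9 ml, 1 um^3 = 1e-12 ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Union

__all__ = [
    "ModelParams",
    "InitialCondition",
    "ForagingParams",
    "PartitionSpec",
    "convert_volume",
    "load_config",
    "dump_config",
]

#: exact volume conversion factors to ml
_VOLUME_TO_ML = {"ml": 1.0, "pl": 1e-9, "um3": 1e-12}


def convert_volume(value: float, unit: str) -> float:
    """Convert a volume to ml.  Supported units: ``ml``, ``pl``, ``um3``."""
    if value < 0:
        raise ValueError(f"volume must be non-negative, got {value}")
    try:
        return value * _VOLUME_TO_ML[unit]
    except KeyError:
        raise ValueError(
            f"unknown volume unit {unit!r}; expected one of {sorted(_VOLUME_TO_ML)}"
        ) from None


def _check_finite_positive(name: str, value: float, *, allow_zero: bool = False) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
    if value < 0 or (value == 0 and not allow_zero):
        bound = "non-negative" if allow_zero else "positive"
        raise ValueError(f"{name} must be {bound}, got {value}")


@dataclass(frozen=True)
class ModelParams:
    """Kinetic constants of the collective-defence model.

    Attributes
    ----------
    mu : float
        Exponential growth rate below the threshold concentration, 1/min.
    gamma : float
        Exponential death rate above the threshold concentration, 1/min.
    enzyme_rate : float
        Per-cell degradation capacity E = b * r_max, ug cell^-1 min^-1
        (enzyme copy number per cell times maximal turnover; only the
        product is identifiable, so it is a single parameter).
    K_M : float
        Michaelis constant of antibiotic degradation, ug/ml.
    a_th : float
        Threshold (single-cell MIC) antibiotic concentration, ug/ml: cells
        grow for a < a_th and die for a > a_th.
    """

    mu: float = 0.01
    gamma: float = 0.045
    enzyme_rate: float = 3.5e-8
    K_M: float = 6.7
    a_th: float = 1.0

    def __post_init__(self) -> None:
        _check_finite_positive("mu", self.mu)
        _check_finite_positive("gamma", self.gamma)
        _check_finite_positive("enzyme_rate", self.enzyme_rate, allow_zero=True)
        _check_finite_positive("K_M", self.K_M)
        _check_finite_positive("a_th", self.a_th)

    @classmethod
    def reference(cls) -> "ModelParams":
        """Reference beta-lactamase / beta-lactam parameter set.

        Literature-derived values for a beta-lactamase producing strain in a
        microfluidic droplet setting: mu = 0.01/min, gamma = 0.045/min,
        E = 3.5e-8 ug/cell/min, K_M = 6.7 ug/ml, a_th = 1 ug/ml.
        """
        return cls()


@dataclass(frozen=True)
class InitialCondition:
    """Starting state of one sub-volume.

    n_init is a cell count (non-negative integer), a_init the initial
    antibiotic concentration in ug/ml, volume the sub-volume size in ml.
    """

    n_init: int
    a_init: float
    volume: float

    def __post_init__(self) -> None:
        if self.n_init < 0 or int(self.n_init) != self.n_init:
            raise ValueError(f"n_init must be a non-negative integer, got {self.n_init}")
        if not math.isfinite(self.a_init) or self.a_init < 0:
            raise ValueError(f"a_init must be finite and non-negative, got {self.a_init}")
        _check_finite_positive("volume", self.volume)

    @property
    def density(self) -> float:
        """Initial cell density n_init/volume, cells/ml."""
        return self.n_init / self.volume


@dataclass(frozen=True)
class ForagingParams:
    """Constants of the enzymatic-foraging (nutrient release) model.

    Enzymes release nutrient from a substrate pool (Michaelis-Menten in the
    remaining substrate); cells are dormant until the nutrient concentration
    reaches n_th, then grow exponentially at rate mu.  Defaults mirror the
    defence reference preset with a substrate pool of 15 ug/ml and a growth
    threshold of 1 ug/ml.
    """

    mu: float = 0.01
    enzyme_rate: float = 3.5e-8
    K_M: float = 6.7
    n_th: float = 1.0
    s_init: float = 15.0

    def __post_init__(self) -> None:
        _check_finite_positive("mu", self.mu)
        _check_finite_positive("enzyme_rate", self.enzyme_rate, allow_zero=True)
        _check_finite_positive("K_M", self.K_M)
        _check_finite_positive("n_th", self.n_th)
        _check_finite_positive("s_init", self.s_init)
        if self.n_th > self.s_init:
            raise ValueError(
                "n_th exceeds s_init: the nutrient threshold can never be reached"
            )


@dataclass(frozen=True)
class PartitionSpec:
    """Fragmentation geometry: total volume V split into m sub-volumes.

    mean_density is the whole-system cell density rho (cells/ml); each
    sub-volume receives a Poisson(rho * v) cell count, v = V/m.
    """

    total_volume: float
    m: int
    mean_density: float
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite_positive("total_volume", self.total_volume)
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError(f"m must be a positive integer, got {self.m}")
        if not math.isfinite(self.mean_density) or self.mean_density < 0:
            raise ValueError(f"mean_density must be >= 0, got {self.mean_density}")

    @property
    def sub_volume(self) -> float:
        """Sub-volume size v = V/m, ml."""
        return self.total_volume / self.m

    @property
    def mean_occupancy(self) -> float:
        """Mean cells per sub-volume, lambda = rho * v."""
        return self.mean_density * self.sub_volume

    def with_m(self, m: int, seed: int | None = None) -> "PartitionSpec":
        """Same system partitioned into a different number of sub-volumes."""
        return PartitionSpec(
            total_volume=self.total_volume,
            m=m,
            mean_density=self.mean_density,
            seed=self.seed if seed is None else seed,
        )


# ---------------------------------------------------------------------------
# Flat key=value config files.  Unit-suffixed keys avoid silent unit errors:
#   mu_per_min=0.01          gamma_per_min=0.045
#   enzyme_rate_ug_per_cell_min=3.5e-8
#   K_M_ug_per_ml=6.7        a_th_ug_per_ml=1.0
# Bare keys (mu, gamma, enzyme_rate, K_M, a_th) are accepted as synonyms in
# the internal units.  Volumes may use volume_ml / volume_pl / volume_um3.
# ---------------------------------------------------------------------------

_KEY_SYNONYMS = {
    "mu_per_min": "mu",
    "gamma_per_min": "gamma",
    "enzyme_rate_ug_per_cell_min": "enzyme_rate",
    "K_M_ug_per_ml": "K_M",
    "a_th_ug_per_ml": "a_th",
    "n_th_ug_per_ml": "n_th",
    "s_init_ug_per_ml": "s_init",
}


def load_config(path: Union[str, Path]) -> dict:
    """Parse a flat ``key=value`` config file into a dict of floats.

    ``#`` starts a comment; blank lines are ignored.  Volume keys with a
    unit suffix (``volume_pl`` etc.) are converted to ml under the key
    ``volume``.
    """
    out: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        try:
            num = float(value)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric value {value!r}") from None
        if key.startswith("volume_"):
            out["volume"] = convert_volume(num, key.removeprefix("volume_"))
        else:
            out[_KEY_SYNONYMS.get(key, key)] = num
    return out


def model_params_from_config(cfg: dict) -> ModelParams:
    """Build ModelParams from a config dict, using defaults for missing keys."""
    names = {f.name for f in fields(ModelParams)}
    return ModelParams(**{k: v for k, v in cfg.items() if k in names})


def dump_config(cfg: dict, path: Union[str, Path]) -> None:
    """Write a dict back out as a flat key=value file (sorted, reproducible)."""
    lines = [f"{k}={cfg[k]!r}" if isinstance(cfg[k], str) else f"{k}={cfg[k]}" for k in sorted(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")
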