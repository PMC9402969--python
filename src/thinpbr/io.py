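"""Dataset and parameter-file I/O, run configuration, seed fan-out.

The observation CSV dialect has the header
``thickness_mm,I0_umol_m2_s,tau_d,X_obs_g_m3,replicate``; floats are written
at 17 significant digits so write→read round-trips are exact.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth_model import KineticParams

__all__ = [
    "OBS_COLUMNS",
    "ObservationValidationError",
    "read_observations",
    "write_observations",
    "validate_observations",
    "load_parameter_sets",
    "reference_parameter_sets",
    "RunConfig",
    "ensure_output",
    "derive_seed",
]

OBS_COLUMNS = ["thickness_mm", "I0_umol_m2_s", "tau_d", "X_obs_g_m3", "replicate"]

_NUMERIC = ["thickness_mm", "I0_umol_m2_s", "tau_d", "X_obs_g_m3"]

#: Bundled reference parameter sets (fitted values per thickness).
_BUNDLED_PARAMS = "tobliquus_fitted_params.yaml"


class ObservationValidationError(ValueError):
    """Validation failure of an observation table; ``errors`` lists one
    message per offending row (with its file line number) or column."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid observation table:\n  " + "\n  ".join(errors))


def validate_observations(df: pd.DataFrame, line_offset: int = 2) -> pd.DataFrame:
    """Check the dialect contract; returns the coerced frame or raises.

    ``line_offset`` maps a zero-based row index to the file line number
    (header is line 1, first data row line 2).
    """
    errors = [f"missing column {c!r}" for c in OBS_COLUMNS if c not in df.columns]
    if errors:
        raise ObservationValidationError(errors)
    out = df.copy()
    for c in _NUMERIC:
        out[c] = pd.to_numeric(out[c], errors="coerce")
    for idx, row in out.iterrows():
        line = idx + line_offset
        if any(pd.isna(row[c]) for c in _NUMERIC):
            errors.append(f"line {line}: non-numeric value")
            continue
        if row["thickness_mm"] <= 0:
            errors.append(f"line {line}: thickness_mm must be > 0")
        if row["I0_umol_m2_s"] < 0:
            errors.append(f"line {line}: I0 must be >= 0")
        if row["tau_d"] <= 0:
            errors.append(f"line {line}: tau_d must be > 0")
        if row["X_obs_g_m3"] < 0:
            errors.append(f"line {line}: X_obs_g_m3 must be >= 0")
    if errors:
        raise ObservationValidationError(errors)
    return out[OBS_COLUMNS + [c for c in out.columns if c not in OBS_COLUMNS]]


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observation CSV; malformed rows are rejected
    with their line numbers."""
    df = pd.read_csv(path)
    return validate_observations(df.reset_index(drop=True))


def write_observations(df: pd.DataFrame, path) -> None:
    """Write an observation table in the canonical dialect (17 significant
    digits, lossless round-trip)."""
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationValidationError([f"missing column {c!r}" for c in missing])
    df.to_csv(path, index=False, float_format="%.17g")


def _params_from_mapping(raw: dict) -> dict[float, KineticParams]:
    out = {}
    for key, vals in raw.items():
        out[float(key)] = KineticParams(**{k: float(v) for k, v in vals.items()})
    return out


def load_parameter_sets(path) -> dict[float, KineticParams]:
    """Load a thickness(mm) → {mu_max, K_I, I_opt, k_d, k_a} mapping from a
    YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _params_from_mapping(raw)


def reference_parameter_sets() -> dict[float, KineticParams]:
    """The bundled fitted parameter sets for T. obliquus at 2/5/8/15/35 mm."""
    text = resources.files("thinpbr.data").joinpath(_BUNDLED_PARAMS).read_text()
    return _params_from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class RunConfig:
    """Paths, seed and verbosity of one pipeline run."""

    params_path: Path | None = None
    data_path: Path | None = None
    out_path: Path | None = None
    seed: int = 0
    force: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("params_path", "data_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")


def ensure_output(path, force: bool = False) -> Path:
    """Refuse to overwrite an existing output unless forced."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"output {path} exists; pass force to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def derive_seed(global_seed: int, stage: str) -> int:
    """Fan a single global seed out to a per-stage seed.

    The stage name is hashed (CRC-32) and combined with the global seed
    through a SeedSequence, so each pipeline stage is independently
    reproducible from the one global seed. The result is < 2**31.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(global_seed), tag])
    return int(ss.generate_state(1)[0] % 2**31)
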