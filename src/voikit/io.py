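"""Draw-table and configuration I/O.

Draw tables are plain CSV with a mandatory header row (parameter or
action labels), comma separator, "." decimal, UTF-8, floats written with
17 significant digits so write-then-read round-trips exactly. Results are
serialized as versioned JSON objects {schema_version, measure, value,
mc_se, meta}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import OutputDraws, ParameterDraws, VoIEstimate
from .impact_model import HealthModelConfig

__all__ = [
    "read_parameter_draws", "read_output_draws", "write_draws",
    "read_config", "write_config", "write_results",
]

_FLOAT_FMT = "%.17g"


def _read_numeric_csv(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed CSV ({err})") from err
    bad = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric cells in columns {bad}")
    return frame


def read_parameter_draws(path) -> ParameterDraws:
    """Read an R x P CSV of sampled inputs, one column per parameter."""
    return ParameterDraws(_read_numeric_csv(path))


def read_output_draws(path, kind: str, inputs: ParameterDraws | None = None
                      ) -> OutputDraws:
    """Read sampled outputs and, if inputs are given, cross-check the row
    counts between the paired files."""
    out = OutputDraws(kind, _read_numeric_csv(path))
    if inputs is not None:
        try:
            out.check_aligned(inputs)
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from err
    return out


def write_draws(obj: ParameterDraws | OutputDraws, path) -> None:
    obj.values.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_config(path) -> HealthModelConfig:
    """Read a model configuration from YAML (JSON is valid YAML).

    Recognised keys mirror HealthModelConfig fields; ``dr_table`` may be a
    path to a CSV with columns (x, rr, se_log_rr).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    if "dr_table" in raw and isinstance(raw["dr_table"], str):
        dr_path = Path(raw["dr_table"])
        if not dr_path.is_absolute():
            dr_path = Path(path).parent / dr_path
        raw["dr_table"] = pd.read_csv(dr_path)
    known = set(HealthModelConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return HealthModelConfig(**raw)


def write_config(config: HealthModelConfig, path, dr_table_path=None) -> None:
    data = {
        "mu_meanlog": config.mu_meanlog, "mu_sdlog": config.mu_sdlog,
        "pi_alpha": config.pi_alpha, "pi_beta": config.pi_beta,
        "D": config.D, "I0": config.I0, "k": config.k,
    }
    if dr_table_path is not None:
        config.dr_table.to_csv(dr_table_path, index=False, float_format=_FLOAT_FMT)
        data["dr_table"] = Path(dr_table_path).name
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_results(results, path) -> None:
    """Serialize one VoIEstimate or a list of them as JSON."""
    if isinstance(results, VoIEstimate):
        payload = results.to_dict()
    else:
        payload = [r.to_dict() for r in results]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
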