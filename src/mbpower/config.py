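"""Run configuration: defaults, flat key=value config files, flag merging."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    """All knobs for the fit -> simulate -> power workflow."""

    # pre-filter thresholds
    min_count: int = 5
    min_samples: int = 3
    # significance / model-selection thresholds
    alpha_sig: float = 0.1
    bootstrap_level: float = 0.05
    # model knobs
    k_max: int = 5
    n_bootstrap: int = 100
    dispersion_scale: float = 0.3
    log_base: float = 2.0
    # simulation design
    n_taxa: int = 1000
    n_per_group: int = 100
    n_sims: int = 100
    sizes: tuple[int, ...] = (30, 50, 70, 90, 110, 130, 150, 170, 190)
    lfc_values: tuple[float, ...] = (2.0, 3.0, 4.0)
    x1_ref: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_sig < 1) or not (0 < self.bootstrap_level < 1):
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.min_count < 0 or self.min_samples < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not (0 < self.dispersion_scale <= 1):
            raise ValueError("dispersion_scale must lie in (0, 1]")
        if self.k_max < 1 or self.n_bootstrap < 1:
            raise ValueError("k_max and n_bootstrap must be positive")
        self.seed = int(self.seed)

    def write(self, path: str | Path) -> None:
        """Write the fully resolved configuration as flat key=value lines."""
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key}={value}")
        Path(path).write_text("\n".join(lines) + "\n")


_TUPLE_FIELDS = {"sizes": int, "lfc_values": float}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional key=value file plus overrides.

    Overrides (command-line flags) win over file values; None overrides are
    ignored so unset flags fall through to the file/default.
    """
    values: dict = {}
    if path is not None:
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})

    typed: dict = {}
    by_name = {f.name: f for f in fields(RunConfig)}
    for key, val in values.items():
        if key not in by_name:
            raise ValueError(f"unknown config key: {key!r}")
        if key in _TUPLE_FIELDS:
            if isinstance(val, str):
                val = tuple(_TUPLE_FIELDS[key](v) for v in val.split(",") if v)
            else:
                val = tuple(_TUPLE_FIELDS[key](v) for v in val)
        elif isinstance(val, str):
            ftype = by_name[key].type
            caster = float if "float" in str(ftype) else int
            val = caster(val)
        typed[key] = val
    return RunConfig(**typed)
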