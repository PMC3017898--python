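"""Run configuration, CSV snapshot export and diagnostics tables.

A run is described by a plain-text ``key=value`` configuration (or CLI
flags that compile to one).  A ``preset`` key seeds the defaults from the
published parameter table; explicit keys override it.  Unknown keys and
invalid values are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chebyshev import CollocationGrid
from .integrate import IntegratorSettings, SimulationResult
from .models import InvasionParameters, ModelVariant
from .oracle import barycentric_interpolate, count_clusters, total_mass
from .presets import DEFAULT_SNAPSHOT_TIMES, get_preset

__all__ = [
    "RunSpec",
    "ConfigError",
    "load_config",
    "dump_config",
    "export_csv",
    "read_csv",
    "diagnostics_table",
]

_PARAM_KEYS = tuple(f.name for f in dataclasses.fields(InvasionParameters))
_MODEL_BY_NAME = {v.value: v for v in ModelVariant}


class ConfigError(ValueError):
    """A configuration key is unknown, malformed or violates an invariant."""


@dataclass(frozen=True)
class RunSpec:
    """Fully validated description of one simulation run."""

    variant: ModelVariant
    params: InvasionParameters
    N: int
    snapshot_times: tuple[float, ...] = DEFAULT_SNAPSHOT_TIMES
    settings: IntegratorSettings = IntegratorSettings()


def _parse_pairs(text: str) -> dict[str, str]:
    pairs: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in pairs:
            raise ConfigError(f"duplicate key {key!r}")
        pairs[key] = value
    return pairs


def _as_float(key: str, value: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ConfigError(f"key {key!r}: non-numeric value {value!r}") from None


def load_config(source: str | Path) -> RunSpec:
    """Parse a key=value configuration from a path or inline text.

    Recognised keys: ``preset``, ``model``, ``N``, ``snapshots`` (comma
    separated times), ``rtol``, ``atol``, ``max_step``, ``method`` and
    every model coefficient (``dn``, ``dm``, ``du``, ``gamma``, ``eta``,
    ``alpha``, ``beta``, ``mu1``, ``mu2``, ``theta``, ``xi``, ``rho``,
    ``epsilon``).
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "=" not in source and "\n" not in source
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    pairs = _parse_pairs(text)

    variant: ModelVariant | None = None
    params = InvasionParameters()
    N = 30
    times: tuple[float, ...] = DEFAULT_SNAPSHOT_TIMES
    settings = IntegratorSettings()

    if "preset" in pairs:
        try:
            preset = get_preset(pairs.pop("preset"))
        except KeyError as exc:
            raise ConfigError(str(exc)) from None
        variant, params, N = preset.variant, preset.params, preset.N

    overrides: dict[str, float] = {}
    for key, value in pairs.items():
        if key == "model":
            if value not in _MODEL_BY_NAME:
                raise ConfigError(
                    f"key 'model': unknown model {value!r}; "
                    f"choose from {', '.join(_MODEL_BY_NAME)}"
                )
            variant = _MODEL_BY_NAME[value]
        elif key == "N":
            try:
                N = int(value)
            except ValueError:
                raise ConfigError(f"key 'N': non-integer value {value!r}") from None
            if N < 4:
                raise ConfigError(f"key 'N': spectral order must be >= 4, got {N}")
        elif key == "snapshots":
            try:
                times = tuple(float(t) for t in value.split(",") if t.strip())
            except ValueError:
                raise ConfigError(f"key 'snapshots': non-numeric entry in {value!r}") from None
            if not times or any(np.diff(times) <= 0) or times[0] < 0:
                raise ConfigError("key 'snapshots': times must be ascending and nonnegative")
        elif key == "rtol":
            settings = dataclasses.replace(settings, rel_tol=_as_float(key, value))
        elif key == "atol":
            settings = dataclasses.replace(settings, abs_tol=_as_float(key, value))
        elif key == "max_step":
            settings = dataclasses.replace(settings, max_step=_as_float(key, value))
        elif key == "method":
            try:
                settings = dataclasses.replace(settings, method=value)
            except ValueError as exc:
                raise ConfigError(f"key 'method': {exc}") from None
        elif key in _PARAM_KEYS:
            overrides[key] = _as_float(key, value)
        else:
            raise ConfigError(f"unknown configuration key {key!r}")

    if variant is None:
        raise ConfigError("configuration must name a 'preset' or a 'model'")
    try:
        params = params.evolve(**overrides)
        params.validate_for(variant)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None
    return RunSpec(variant=variant, params=params, N=N, snapshot_times=times, settings=settings)


def dump_config(spec: RunSpec) -> str:
    """Serialise a RunSpec so that :func:`load_config` round-trips it."""
    lines = [f"model={spec.variant.value}", f"N={spec.N}"]
    lines += [f"{k}={getattr(spec.params, k)!r}" for k in _PARAM_KEYS]
    lines.append("snapshots=" + ",".join(repr(t) for t in spec.snapshot_times))
    lines.append(f"rtol={spec.settings.rel_tol!r}")
    lines.append(f"atol={spec.settings.abs_tol!r}")
    if spec.settings.max_step is not None:
        lines.append(f"max_step={spec.settings.max_step!r}")
    lines.append(f"method={spec.settings.method}")
    return "\n".join(lines) + "\n"


def export_csv(result: SimulationResult, path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Write snapshots as long-format CSV: ``time,x,n,f,m,u``.

    One row per (snapshot time, node), sorted by time then x; the ``u``
    column is zero for three-field variants.  Floats are written with
    ``repr`` precision so a re-import reproduces the values bit-exactly.
    """
    x = result.grid.nodes
    frames = []
    for i, t in enumerate(result.times):
        frame = {
            "time": np.full(x.size, t),
            "x": x,
            "n": result.fields["n"][i],
            "f": result.fields["f"][i],
            "m": result.fields["m"][i],
            "u": result.fields["u"][i] if "u" in result.fields else np.zeros(x.size),
        }
        frames.append(pd.DataFrame(frame))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False)  # pandas writes repr-round-trip floats
    return table


def read_csv(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read back a snapshot CSV written by :func:`export_csv`."""
    table = pd.read_csv(path, float_precision="round_trip")
    expected = ["time", "x", "n", "f", "m", "u"]
    if list(table.columns) != expected:
        raise ValueError(f"snapshot CSV must have columns {expected}, got {list(table.columns)}")
    return table


def diagnostics_table(
    result: SimulationResult,
    eval_points: int = 1001,
    height_frac: float = 0.1,
    dip_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-snapshot diagnostics: tumour mass, field minima, cluster count.

    The cluster count evaluates the tumour profile on ``eval_points``
    uniform positions through the barycentric interpolant.
    """
    grid: CollocationGrid = result.grid
    xq = np.linspace(0.0, 1.0, eval_points)
    rows = []
    for i, t in enumerate(result.times):
        n = result.fields["n"][i]
        profile = barycentric_interpolate(grid, n, xq)
        rows.append(
            {
                "time": t,
                "total_mass_n": total_mass(grid, n),
                "min_n": float(n.min()),
                "min_f": float(result.fields["f"][i].min()),
                "min_m": float(result.fields["m"][i].min()),
                "clusters_n": count_clusters(profile, height_frac, dip_frac),
            }
        )
    return pd.DataFrame(rows)
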