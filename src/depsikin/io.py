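"""Delimited-text readers, config parsing, and result serialization.

Tables are comma- or tab-separated (auto-detected; decimal separator is
"." only); configs are YAML or JSON.  Every result written to disk carries
a metadata block (package version, configuration, seed) so a run can be
replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import TitrationPoint
from .errors import SchemaError
from .exsy import ExchangeNetwork, ExsyVolumeSet
from .msm import FeatureTrajectory

__all__ = [
    "read_volume_table",
    "read_network_config",
    "read_titration",
    "read_trajectories",
    "write_results",
    "packaged_worked_example",
]


def _detect_sep(path: Path) -> str:
    head = path.read_text().splitlines()
    for line in head:
        if line.strip():
            return "\t" if "\t" in line else ","
    raise SchemaError(f"{path}: file is empty")


def read_volume_table(path: str | Path, mixing_time: float) -> tuple[ExsyVolumeSet, list[str]]:
    """Read a square EXSY volume table with site labels as header and index.

    Returns the volume set and the site-label order of the table.
    """
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise SchemaError(f"{path}: could not parse delimited table: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise SchemaError(
            f"{path}: volume table must be square, got {df.shape[0]} rows x {df.shape[1]} columns"
        )
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise SchemaError(f"{path}: row labels {list(df.index)} != column labels {list(df.columns)}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = [
            (i + 2, col)
            for i, row in df.iterrows()
            for col, v in row.items()
            if not isinstance(v, (int, float, np.number))
        ]
        raise SchemaError(f"{path}: non-numeric cells at (line, column): {bad[:5]}")
    return ExsyVolumeSet(mixing_time, values.astype(float)), [str(c) for c in df.columns]


def read_network_config(path: str | Path) -> tuple[ExchangeNetwork, float]:
    """Read the exchange-network sidecar config (YAML or JSON).

    Returns the network and the mixing time in seconds.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    missing = {"mixing_time_s", "site_labels", "magnetic_fractions", "conformer_of_site"} - cfg.keys()
    if missing:
        raise SchemaError(f"{path}: missing config keys: {sorted(missing)}")
    network = ExchangeNetwork(
        site_labels=tuple(cfg["site_labels"]),
        conformer_of_site=dict(cfg["conformer_of_site"]),
        symmetry_pairs=tuple(
            tuple((str(a), str(b)) for a, b in group) for group in cfg.get("symmetry_pairs", [])
        ),
        forbidden_pairs=tuple((str(a), str(b)) for a, b in cfg.get("forbidden_pairs", [])),
        magnetic_fractions={str(k): float(v) for k, v in cfg["magnetic_fractions"].items()},
        c2_symmetric=bool(cfg.get("c2_symmetric", True)),
        k1_group=cfg.get("k1_group"),
    )
    return network, float(cfg["mixing_time_s"])


def packaged_worked_example() -> tuple[ExsyVolumeSet, ExchangeNetwork]:
    """The PF1022A EXSY worked example shipped with the package.

    Cross-/diagonal-peak volumes of the three exchanging H-alpha sites in
    CDCl3 (mixing time 0.1 s) together with their magnetic fractions.
    """
    data_dir = Path(__file__).parent / "data"
    network, tm = read_network_config(data_dir / "pf1022a_network.yaml")
    volumes, labels = read_volume_table(data_dir / "pf1022a_exsy_volumes.csv", tm)
    assert tuple(labels) == network.site_labels
    return volumes, network


_TITRATION_COLS = ("P_total_M", "M_total_M")


def read_titration(path: str | Path) -> list[TitrationPoint]:
    """Read a titration CSV/TSV into points.

    Required columns: ``P_total_M``, ``M_total_M``; optional: ``delta_ppm``,
    ``ratio_asym_to_sym``, ``cation`` (free text, ignored here).
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = set(_TITRATION_COLS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    points = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            points.append(
                TitrationPoint(
                    P_total=float(row["P_total_M"]),
                    M_total=float(row["M_total_M"]),
                    delta_obs=(
                        float(row["delta_ppm"])
                        if "delta_ppm" in df.columns and pd.notna(row["delta_ppm"])
                        else None
                    ),
                    ratio_obs=(
                        float(row["ratio_asym_to_sym"])
                        if "ratio_asym_to_sym" in df.columns
                        and pd.notna(row["ratio_asym_to_sym"])
                        else None
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {line}: {exc}") from exc
    return points


def read_trajectories(paths: list[str | Path], dt: float) -> list[FeatureTrajectory]:
    """Read dihedral time series from delimited text (frames x angles, header
    names the dihedrals) or ``.npy`` array containers."""
    out = []
    for p in paths:
        p = Path(p)
        if p.suffix == ".npy":
            arr = np.load(p)
            names = None
        else:
            sep = _detect_sep(p)
            df = pd.read_csv(p, sep=sep)
            if not all(np.issubdtype(d, np.number) for d in df.dtypes):
                raise SchemaError(f"{p}: non-numeric values in trajectory table")
            arr = df.to_numpy(float)
            names = tuple(str(c) for c in df.columns)
        out.append(FeatureTrajectory(arr, dt, trajectory_id=p.stem, feature_names=names))
    return out


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_results(result: Any, path: str | Path, config: dict | None = None, seed: int | None = None) -> None:
    """Serialize a result object (dataclass/dict) to JSON with replay metadata."""
    payload = {
        "metadata": {
            "package": "depsikin",
            "version": __version__,
            "config": _jsonable(config or {}),
            "seed": seed,
        },
        "result": _jsonable(result),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
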