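"""Plain-text interchange: tab-separated tables, pupil traces, run manifests."""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import PupilTimeSeries

__all__ = [
    "write_table",
    "read_table",
    "write_pupil",
    "read_pupil",
    "write_manifest",
    "read_manifest",
]


def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Write a TSV table, optionally stamped with the run's config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if config_hash is not None:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_pupil(ts: PupilTimeSeries, path, config_hash: str | None = None) -> None:
    """Write a pupil trace as TSV with rate and bookkeeping in header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if config_hash is not None:
        buf.write(f"# config_hash={config_hash}\n")
    buf.write(f"# rate_hz={ts.rate_hz!r}\n")
    buf.write(f"# interpolated_fraction={ts.interpolated_fraction!r}\n")
    ts.to_frame().to_csv(buf, sep="\t", index=False, float_format="%.6f")
    path.write_text(buf.getvalue())


def read_pupil(path) -> PupilTimeSeries:
    path = Path(path)
    rate_hz = None
    interp = 0.0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "rate_hz":
                rate_hz = float(value)
            elif key.strip() == "interpolated_fraction":
                interp = float(value)
    df = pd.read_csv(path, sep="\t", comment="#")
    if rate_hz is None:
        dt = np.median(np.diff(df["t_s"].to_numpy()))
        rate_hz = 1.0 / dt
    return PupilTimeSeries(
        t=df["t_s"].to_numpy(),
        diameter=df["diameter_mm"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        rate_hz=rate_hz,
        interpolated_fraction=interp,
    )


def write_manifest(manifest: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
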