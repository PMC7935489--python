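"""Structured outputs: delimited tables and run-metadata records.

Tables are written as tab-separated text with a header row and 17
significant digits, so re-reading reproduces the float64 values exactly.
Metadata records are YAML (package version, full configuration, seed,
convergence diagnostics) and suffice to reconstruct a run.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import VariantGrid
from .passaging import SteadyStateReport

FLOAT_FMT = "%.17g"


def write_table(frame: pd.DataFrame, path) -> None:
    """Tab-separated table, header row, bit-round-trippable floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    except OSError as exc:
        raise OSError(f"could not write table to {path}: {exc}") from exc


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_metadata(metadata: dict, path) -> None:
    """YAML metadata record (full config + seed + diagnostics)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clean = {}
    for key, value in metadata.items():
        if isinstance(value, np.generic):
            value = value.item()
        elif isinstance(value, np.ndarray):
            value = value.tolist()
        clean[key] = value
    try:
        with open(path, "w") as fh:
            yaml.safe_dump(clean, fh, sort_keys=False)
    except OSError as exc:
        raise OSError(f"could not write metadata to {path}: {exc}") from exc


def read_metadata(path) -> dict:
    with open(Path(path)) as fh:
        return yaml.safe_load(fh)


def report_to_frame(report: SteadyStateReport, grid: VariantGrid) -> pd.DataFrame:
    """Per-episode summary: episode, carrying capacity, dominant traits and
    the full end-of-episode phage frequency vector."""
    from .analysis import dominant_variant_index

    labels = grid.labels()
    rows = []
    for ep in range(report.n_episodes):
        freq = report.phage_freqs[ep]
        row = {"episode": ep, "k": report.k_values[ep]}
        if np.any(np.isnan(freq)):
            row["dominant_phi_max"] = np.nan
            row["dominant_theta"] = np.nan
        else:
            idx = dominant_variant_index(freq, grid)
            row["dominant_phi_max"], row["dominant_theta"] = grid.traits(idx)
        for j, lab in enumerate(labels):
            row[f"freq_{lab}"] = freq[j]
        rows.append(row)
    return pd.DataFrame(rows)
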