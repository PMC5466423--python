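"""Readers and writers for the package's tabular artifacts.

All artifacts are TSV with a ``#``-prefixed metadata header (tool version,
seed, config hash) and deterministic column order, so identical configuration
and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Mapping, Optional

import pandas as pd

from . import __version__
from .errors import SchemaError
from .fitness import CompetitionObservation
from .simulate import Trajectory
from .survival import SurvivalSurface

OBSERVATION_COLUMNS = [
    "host_id",
    "timepoint_hr",
    "count_evolved",
    "count_ancestor",
    "dilution_factor",
    "inoculum_density",
    "inoculum_frequency_evolved",
    "marker_orientation",
]

__all__ = [
    "OBSERVATION_COLUMNS",
    "config_hash",
    "read_observations",
    "write_observations",
    "write_table",
    "write_surface",
    "write_trajectory",
]


def config_hash(config: Mapping) -> str:
    """Stable short hash of a flat configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _metadata_lines(metadata: Optional[Mapping]) -> List[str]:
    lines = [f"# bottlepass {__version__}"]
    for key in sorted(metadata or {}):
        lines.append(f"# {key}: {metadata[key]}")
    return lines


def write_table(path, frame: pd.DataFrame, metadata: Optional[Mapping] = None) -> None:
    """Write a DataFrame as TSV under a ``#`` metadata header."""
    path = Path(path)
    body = frame.to_csv(sep="\t", index=False, lineterminator="\n", float_format="%.17g")
    path.write_text("\n".join(_metadata_lines(metadata)) + "\n" + body)


def write_surface(path, surface: SurvivalSurface, metadata: Optional[Mapping] = None) -> None:
    """Survival surface as TSV: header row of s values, first column t."""
    frame = surface.to_frame()
    meta = dict(metadata or {})
    meta.setdefault("tau", surface.regime.tau)
    if surface.regime.label:
        meta.setdefault("regime", surface.regime.label)
    path = Path(path)
    body = frame.to_csv(sep="\t", lineterminator="\n")
    path.write_text("\n".join(_metadata_lines(meta)) + "\n" + body)


def write_trajectory(path, trajectory: Trajectory, metadata: Optional[Mapping] = None) -> None:
    meta = dict(metadata or {})
    meta.setdefault("status", trajectory.status)
    write_table(path, trajectory.to_frame(), meta)


def write_observations(
    path, observations, metadata: Optional[Mapping] = None
) -> None:
    frame = pd.DataFrame(
        [
            {col: getattr(obs, col) for col in OBSERVATION_COLUMNS}
            for obs in observations
        ],
        columns=OBSERVATION_COLUMNS,
    )
    write_table(path, frame, metadata)


def _count_comment_lines(path: Path) -> int:
    k = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                k += 1
            else:
                break
    return k


def read_observations(path) -> List[CompetitionObservation]:
    """Read and validate a competition-observation TSV.

    Malformed rows are reported with their 1-based file line numbers; a
    missing column is a schema error.
    """
    path = Path(path)
    n_comments = _count_comment_lines(path)
    frame = pd.read_csv(path, sep="\t", skiprows=n_comments, float_precision="round_trip")
    missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns and c != "marker_orientation"]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "marker_orientation" not in frame.columns:
        frame["marker_orientation"] = "evolved_blue"

    observations = []
    problems = []
    for idx, row in frame.iterrows():
        line_no = n_comments + 2 + idx  # comments + header + 1-based row
        try:
            observations.append(
                CompetitionObservation(
                    host_id=str(row["host_id"]),
                    timepoint_hr=int(row["timepoint_hr"]),
                    count_evolved=float(row["count_evolved"]),
                    count_ancestor=float(row["count_ancestor"]),
                    dilution_factor=float(row["dilution_factor"]),
                    inoculum_density=float(row["inoculum_density"]),
                    inoculum_frequency_evolved=float(row["inoculum_frequency_evolved"]),
                    marker_orientation=str(row["marker_orientation"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise SchemaError(f"{path}: {len(problems)} malformed row(s):\n" + "\n".join(problems))
    return observations
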