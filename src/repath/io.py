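"""File formats and run configuration.

Frames and trajectories travel as multi-frame XYZ with an optional
``key=value`` channel on the comment line (used to carry the weight-selection
name); replica paths are multi-frame XYZ with one frame per replica, in order.
Minimal PDB reading (via gemmi) extracts labeled points with residue/chain
metadata for building selections on real structures — no chemistry perception.
Run configuration is YAML validated against a strict schema (unknown keys are
rejected) before any computation runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import Frame
from .trajectory import Trajectory


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _format_comment(meta: dict | None) -> str:
    if not meta:
        return ""
    return " ".join(f"{k}={v}" for k, v in meta.items())


def _parse_comment(line: str) -> dict:
    meta = {}
    for tok in line.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            meta[k] = v
    return meta


def write_xyz(path: str | Path, frames: Frame | Iterable[Frame],
              meta: dict | None = None, precision: int = 8) -> None:
    """Write one frame or a sequence of frames as (multi-frame) XYZ."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{f.n_points}\n{_format_comment(meta)}\n")
            for lab, (x, y, z) in zip(f.labels, f.coords):
                fh.write(f"{lab} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n")


def read_xyz_frames(path: str | Path) -> tuple[list[Frame], dict]:
    """Read all frames of a (multi-frame) XYZ file.

    Returns the frames plus the key=value metadata of the first comment line.
    Malformed count lines or records raise :class:`ParseError` with the line
    number.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    meta: dict = {}
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i+1}: expected an atom count, got {lines[i]!r}")
        if n < 1:
            raise ParseError(f"{path}:{i+1}: atom count must be positive")
        if i + 1 + n >= len(lines) + 0 and i + 1 + n > len(lines):
            raise ParseError(f"{path}:{i+1}: truncated frame (need {n} records)")
        if not frames:
            meta = _parse_comment(lines[i + 1])
        labels, coords = [], []
        for j in range(i + 2, i + 2 + n):
            if j >= len(lines):
                raise ParseError(f"{path}:{j+1}: truncated frame")
            parts = lines[j].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{j+1}: malformed record {lines[j]!r}")
            labels.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise ParseError(f"{path}:{j+1}: non-numeric coordinate")
        frames.append(Frame(labels, np.array(coords)))
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames, meta


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-frame XYZ file as a :class:`Trajectory`."""
    frames, _ = read_xyz_frames(path)
    first = frames[0]
    for k, f in enumerate(frames):
        if f.labels != first.labels:
            raise ParseError(f"{path}: frame {k} labels differ from frame 0")
    coords = np.stack([f.coords for f in frames])
    return Trajectory(list(first.labels), coords)


def write_trajectory_xyz(path: str | Path, traj: Trajectory,
                         precision: int = 8) -> None:
    write_xyz(path, (traj.frame(i) for i in range(traj.n_frames)),
              precision=precision)


# ---------------------------------------------------------------------------
# minimal PDB
# ---------------------------------------------------------------------------

def read_pdb_minimal(path: str | Path, atom_name: str | None = "CA"
                     ) -> tuple[Frame, "np.ndarray", list[str]]:
    """Read labeled points from a PDB file — metadata only, no chemistry.

    Keeps one point per matching atom record (default: Cα atoms; pass
    ``atom_name=None`` for all atoms).  Returns the frame, the residue
    numbers, and the chain ids, so residue-range/chain selections can be
    built on real structures.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    labels, coords, resnums, chains = [], [], [], []
    model = st[0] if len(st) else None
    if model is None:
        raise ParseError(f"{path}: no models in structure")
    for chain in model:
        for res in chain:
            for atom in res:
                if atom_name is not None and atom.name != atom_name:
                    continue
                labels.append(f"{chain.name}:{res.seqid.num}:{atom.name}")
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                resnums.append(res.seqid.num)
                chains.append(chain.name)
    if not coords:
        raise ParseError(f"{path}: no matching ATOM records")
    return Frame(labels, np.array(coords)), np.array(resnums), chains


def residue_range_mask(resnums: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Boolean mask for residues in [lo, hi] (the domain-split convention)."""
    return (np.asarray(resnums) >= lo) & (np.asarray(resnums) <= hi)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class SurfaceBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "bond_swap_cartesian"
    params: dict = Field(default_factory=dict)


class PathBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_replicas: int = 16
    k_rms: float = 2000.0
    k_angle: float = 100.0
    cosmax: float = 0.95
    max_steps: int = 10000
    grad_tol: float = 0.01
    energy_tol: float = 1.0
    patience: int = 30
    refine: bool = True
    refine_window: int = 2
    fit: bool = False


class RestraintBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pair: tuple[str, str]
    k_force: float = 500.0
    d_eq: float = 1.6


class ResdBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    restraints: list[RestraintBlock] = Field(default_factory=list)
    n_steps: int = 100
    schedule: str = "constant"
    release_grad_tol: float = 1e-4


class AnalysisBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    selection: Optional[str] = None
    n_modes: int = 2
    dccm_low: float = -0.25
    dccm_high: float = 0.25
    align_reference: str = "mean_iterative"


class SynthBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: str = "coherent_holo_like"
    n_frames: int = 1200


class MonitorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pairs: dict[str, tuple[str, str]] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    surface: SurfaceBlock = Field(default_factory=SurfaceBlock)
    path: PathBlock = Field(default_factory=PathBlock)
    resd: ResdBlock = Field(default_factory=ResdBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    synth: SynthBlock = Field(default_factory=SynthBlock)
    monitor: MonitorBlock = Field(default_factory=MonitorBlock)
    seed: int = 0
    output_dir: str = "repath_out"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
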