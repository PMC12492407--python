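"""Trajectory flexibility measures: RMSD series, per-residue RMSF, replica
aggregation and loop-region summaries.

RMSF is computed over C-alpha positions by default (configurable to the full
N/CA/C backbone).  When alignment is requested, frames are superposed onto an
iteratively refined average structure (two passes: align to an initial
reference, average, realign to the average) before fluctuations are measured
— the standard way to remove global rigid-body motion.  Replicas are
aggregated as mean +/- sample standard deviation (N-1 denominator); a region
summary averages within each replica first and then reports the spread of
those per-replica averages, matching how triplicate simulation results are
conventionally reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import (BACKBONE_ATOMS, BackboneFrame, ConformerTrajectory,
                       ResidueRange, kabsch_superpose)


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Angstrom) for one trajectory replica."""

    residue_indices: np.ndarray
    rmsf: np.ndarray
    system_label: str = "system"
    replica_id: int = 0
    aligned: bool = True

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.rmsf.shape != self.residue_indices.shape:
            raise ValidationError("rmsf and residue_indices must align")
        if np.any(self.rmsf < 0):
            raise ValidationError("RMSF values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue_index": self.residue_indices, "rmsf_A": self.rmsf}
        )

    def region_average(self, region: ResidueRange) -> float:
        mask = np.asarray(region.contains(self.residue_indices), dtype=bool)
        if not mask.any():
            raise ValidationError(
                f"region {region.start}-{region.end} overlaps no profiled residues"
            )
        return float(self.rmsf[mask].mean())


@dataclass
class RegionSummary:
    """Mean +/- SD (across replicas) of per-replica region-average RMSF."""

    label: str
    mean: float
    sd: float
    n_replicas: int

    def to_dict(self) -> dict:
        return {
            "region": self.label,
            "mean_A": self.mean,
            "sd_A": self.sd,
            "n_replicas": self.n_replicas,
        }


def _atom_columns(atoms: Sequence[str]) -> list[int]:
    bad = set(atoms) - set(BACKBONE_ATOMS)
    if bad:
        raise ValidationError(f"unknown atom names {sorted(bad)}")
    return [BACKBONE_ATOMS.index(a) for a in atoms]


def rmsd_series(traj: ConformerTrajectory, reference: BackboneFrame,
                subset: ResidueRange | None = None,
                atoms: Sequence[str] = ("CA",)) -> np.ndarray:
    """Per-frame least-squares RMSD to ``reference`` after Kabsch superposition."""
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj):
        _, out[i] = kabsch_superpose(frame, reference, subset, atoms)
    return out


def _aligned_coords(traj: ConformerTrajectory, reference: BackboneFrame | None,
                    atoms: Sequence[str]) -> np.ndarray:
    """Two-pass iterative-average alignment; returns (F, n_sel, 3) coordinates."""
    cols = _atom_columns(atoms)
    ref = reference if reference is not None else traj.frame(0)
    aligned = []
    for frame in traj:
        moved, _ = kabsch_superpose(frame, ref, None, atoms)
        aligned.append(moved.coords)
    mean_coords = np.mean(aligned, axis=0)
    mean_frame = BackboneFrame(mean_coords, traj.residue_indices, traj.residue_names)
    final = np.empty((traj.n_frames, len(cols) * traj.n_residues, 3))
    for i, frame in enumerate(traj):
        moved, _ = kabsch_superpose(frame, mean_frame, None, atoms)
        final[i] = moved.coords[:, cols, :].reshape(-1, 3)
    return final.reshape(traj.n_frames, traj.n_residues, len(cols), 3)


def rmsf_per_residue(traj: ConformerTrajectory, align: bool = True,
                     reference: BackboneFrame | None = None,
                     atoms: Sequence[str] = ("CA",)) -> RmsfProfile:
    """Per-residue RMSF: sqrt(mean_t |r_i(t) - r_bar_i|^2) over selected atoms.

    With ``align=True`` frames are first superposed onto the iteratively
    refined average structure and fluctuations are taken about the time-mean
    position.  With ``align=False`` raw coordinates are used, and if a
    ``reference`` frame is given its positions serve as the fluctuation
    centre instead of the time mean (useful when the generating reference of
    synthetic data is known).
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF undefined for fewer than 2 frames")
    cols = _atom_columns(atoms)
    if align:
        coords = _aligned_coords(traj, reference, atoms)
        center = coords.mean(axis=0)
    else:
        coords = traj.coords[:, :, cols, :]
        if reference is not None:
            if not traj.frame(0).same_topology(reference):
                raise ValidationError("reference topology differs from trajectory")
            center = reference.coords[:, cols, :]
        else:
            center = coords.mean(axis=0)
    sq = np.sum((coords - center[None]) ** 2, axis=-1)  # (F, R, n_atoms)
    msf = sq.mean(axis=(0, 2))
    return RmsfProfile(
        traj.residue_indices, np.sqrt(msf), traj.system_label, traj.replica_id,
        aligned=align,
    )


def aggregate_replicas(profiles: Sequence[RmsfProfile]) -> pd.DataFrame:
    """Per-residue mean and sample SD of RMSF across replicas.

    A single replica yields SD 0 with ``n`` recorded as 1 rather than a
    missing value, so downstream tabulation stays uniform.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residue_indices, first.residue_indices):
            raise ValidationError("replica profiles cover different residue sets")
    stack = np.stack([p.rmsf for p in profiles])
    n = stack.shape[0]
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros(stack.shape[1])
    return pd.DataFrame(
        {
            "residue_index": first.residue_indices,
            "mean_A": stack.mean(axis=0),
            "sd_A": sd,
            "n": n,
        }
    )


def region_summary(profiles: Sequence[RmsfProfile], region: ResidueRange) -> RegionSummary:
    """Average RMSF over a loop region, summarized across replicas.

    Each replica contributes its within-region average; the summary is the
    mean +/- sample SD of those averages (SD 0 when only one replica).
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    averages = np.array([p.region_average(region) for p in profiles])
    sd = float(averages.std(ddof=1)) if averages.size > 1 else 0.0
    return RegionSummary(region.label or f"{region.start}-{region.end}",
                         float(averages.mean()), sd, int(averages.size))


def write_region_summaries(summaries: Sequence[RegionSummary], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in summaries], fh, indent=2)
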