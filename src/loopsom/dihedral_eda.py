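"""Per-system dihedral tables and the divergent-angle exploratory filter.

The filter flags backbone dihedrals whose per-system mean directions
diverge: an angle is retained when the largest pairwise angular difference
of its per-system means exceeds a threshold (30 degrees by default).  Means
are circular by default — an arithmetic mean of angles is an artifact of
where the +/-180 seam falls — but an arithmetic mode is available for
strict replication of pipelines that used plain means.  Comparison is
all-pairs by default; a designated baseline system (e.g. the unmodified
control) can be used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import UndefinedStatisticError, ValidationError
from .geometry import ConformerTrajectory, ResidueRange, phi_psi, wrap_angle

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def circular_mean(angles_deg, min_resultant: float = 1e-9) -> float:
    """Direction of the mean resultant vector, degrees in (-180, 180].

    Undefined (raises) when the angles are spread so evenly that the
    resultant length vanishes.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValidationError("circular mean of an empty set")
    s = np.sin(a).mean()
    c = np.cos(a).mean()
    if np.hypot(s, c) <= min_resultant:
        raise UndefinedStatisticError(
            "circular mean undefined: mean resultant length ~ 0"
        )
    return wrap_angle(np.degrees(np.arctan2(s, c)))


def angular_difference(a: float, b: float) -> float:
    """Shortest angular separation of two directions, degrees in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    out = np.minimum(d, 360.0 - d)
    return float(out) if out.ndim == 0 else out


@dataclass
class SystemDihedralTable:
    """Frames x named dihedral angles (degrees) for one simulated system."""

    system_label: str
    values: pd.DataFrame

    def __post_init__(self):
        vals = self.values[self.angle_ids].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValidationError("dihedral table contains undefined entries")
        if np.any(vals <= -180.0) or np.any(vals > 180.0):
            raise ValidationError("dihedral values must lie in (-180, 180]")

    @property
    def angle_ids(self) -> list[str]:
        return [c for c in self.values.columns if c != "frame"]

    def matrix(self, angle_ids: Sequence[str] | None = None) -> np.ndarray:
        return self.values[list(angle_ids or self.angle_ids)].to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        df = self.values.copy()
        if "frame" not in df.columns:
            df.insert(0, "frame", np.arange(len(df)))
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, system_label: str) -> "SystemDihedralTable":
        return cls(system_label, pd.read_csv(path))


def angle_label(residue_name: str, residue_index: int, which: str) -> str:
    """Angle naming convention: '<OneLetter><index>_phi|psi', e.g. 'R65_phi'."""
    one = THREE_TO_ONE.get(residue_name.upper(), residue_name[:1].upper())
    return f"{one}{residue_index}_{which}"


def dihedral_table(traj: ConformerTrajectory,
                   ranges: Sequence[ResidueRange]) -> SystemDihedralTable:
    """Extract phi/psi for the given residue ranges across all frames.

    Angles undefined at chain termini are excluded from the table entirely
    rather than carried as missing values.
    """
    probe = phi_psi(traj.frame(0))
    keep: list[tuple[int, str]] = []
    labels: list[str] = []
    for _, row in probe.iterrows():
        if not any(r.contains(row["residue_index"]) for r in ranges):
            continue
        for which in ("phi", "psi"):
            if np.isfinite(row[which]):
                keep.append((int(row["residue_index"]), which))
                labels.append(angle_label(row["residue_name"], int(row["residue_index"]), which))
    if not keep:
        raise ValidationError("no defined dihedrals in the requested ranges")
    data = np.empty((traj.n_frames, len(keep)))
    for i, frame in enumerate(traj):
        tab = phi_psi(frame).set_index("residue_index")
        for j, (idx, which) in enumerate(keep):
            data[i, j] = tab.at[idx, which]
    df = pd.DataFrame(data, columns=labels)
    df.insert(0, "frame", np.arange(traj.n_frames))
    return SystemDihedralTable(traj.system_label, df)


@dataclass
class FeatureSelection:
    """Outcome of the divergence filter with per-angle diagnostics."""

    selected: list[str]
    system_means: pd.DataFrame       # systems x angles, degrees
    max_divergence: pd.Series        # per angle, degrees in [0, 180]
    threshold: float
    circular: bool
    excluded: list[str]

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "threshold_deg": self.threshold,
            "circular_means": self.circular,
            "max_divergence_deg": {k: float(v) for k, v in self.max_divergence.items()},
            "system_means_deg": {
                sys: {k: float(v) for k, v in row.items()}
                for sys, row in self.system_means.iterrows()
            },
            "excluded": list(self.excluded),
        }


class DivergentAngleSelector(BaseEstimator):
    """Feature selector keeping angles whose per-group means diverge.

    scikit-learn-style estimator: ``fit(X, y)`` takes a frames x angles
    matrix of degrees and per-frame group labels (one group per simulated
    system); an angle is selected when the maximum pairwise angular
    difference of its per-group mean directions exceeds ``threshold``
    degrees.  With ``baseline`` set, only differences against that group
    are considered.

    Parameters
    ----------
    threshold : float, default 30.0
        Divergence threshold in degrees; an angle must exceed it strictly.
    circular : bool, default True
        Use circular means; ``False`` restores arithmetic means.
    baseline : str or None, default None
        Group label to compare against instead of all pairs.

    Attributes
    ----------
    angle_ids_ : list of str
    support_ : boolean mask of selected angles
    group_means_ : DataFrame (groups x angles, degrees)
    max_divergence_ : Series per angle
    """

    def __init__(self, threshold: float = 30.0, circular: bool = True,
                 baseline: str | None = None):
        self.threshold = threshold
        self.circular = circular
        self.baseline = baseline

    def fit(self, X, y, angle_ids: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be frames x angles with one label per frame")
        groups = pd.unique(y)
        if len(groups) < 2:
            raise ValidationError("need at least two systems to compare")
        if self.baseline is not None and self.baseline not in groups:
            raise ValidationError(f"baseline {self.baseline!r} not among groups")
        ids = list(angle_ids) if angle_ids is not None else [
            f"angle_{j}" for j in range(X.shape[1])
        ]
        means = np.empty((len(groups), X.shape[1]))
        for gi, g in enumerate(groups):
            sub = X[y == g]
            for j in range(X.shape[1]):
                if self.circular:
                    means[gi, j] = circular_mean(sub[:, j])
                else:
                    means[gi, j] = sub[:, j].mean()
        div = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            if self.baseline is not None:
                bi = list(groups).index(self.baseline)
                diffs = [angular_difference(means[bi, j], means[gi, j])
                         for gi in range(len(groups)) if gi != bi]
            else:
                diffs = [angular_difference(means[a, j], means[b, j])
                         for a in range(len(groups)) for b in range(a + 1, len(groups))]
            div[j] = max(diffs)
        self.angle_ids_ = ids
        self.group_means_ = pd.DataFrame(means, index=list(groups), columns=ids)
        self.max_divergence_ = pd.Series(div, index=ids)
        self.support_ = div > self.threshold
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]


def eda_filter(tables: Mapping[str, SystemDihedralTable],
               threshold: float = 30.0, circular: bool = True,
               baseline: str | None = None) -> FeatureSelection:
    """Divergence filter over per-system dihedral tables.

    Angles must be shared by every system to be considered; an angle present
    in only some systems is excluded with a warning.
    """
    if len(tables) < 2:
        raise ValidationError("need at least two systems")
    id_sets = {label: set(t.angle_ids) for label, t in tables.items()}
    shared = set.intersection(*id_sets.values())
    union = set.union(*id_sets.values())
    excluded = sorted(union - shared)
    if excluded:
        warnings.warn(
            f"angles missing from some systems were excluded: {excluded}",
            stacklevel=2,
        )
    # keep a stable, first-table-driven ordering
    first = next(iter(tables.values()))
    ids = [a for a in first.angle_ids if a in shared]
    if not ids:
        raise ValidationError("no angles shared across all systems")
    X = np.vstack([t.matrix(ids) for t in tables.values()])
    y = np.concatenate([
        np.full(len(t.values), label) for label, t in tables.items()
    ])
    sel = DivergentAngleSelector(threshold, circular, baseline).fit(X, y, ids)
    return FeatureSelection(
        selected=[a for a, keep in zip(ids, sel.support_) if keep],
        system_means=sel.group_means_,
        max_divergence=sel.max_divergence_,
        threshold=threshold,
        circular=circular,
        excluded=excluded,
    )
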