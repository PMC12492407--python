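"""Synthetic generators with known ground truth.

Every downstream stage of the analysis (dihedral feature selection, SOM
macrostate clustering, RMSF summaries, modification-site profiling) is
exercised against data produced here, where the truth — state labels,
per-residue fluctuation amplitudes, planted modification sites — is known
exactly.

The dihedral generator emulates metastable loop dynamics as a first-order
Markov chain over K discrete macrostates; within the active state each
angle is drawn from a von Mises distribution (the circular analogue of a
Gaussian) centred on that state's mean.  The positional generator applies
independent isotropic Gaussian displacements per residue, rigidly to the
residue's N/CA/C triplet, so the RMSF ground truth is exactly
``sigma * sqrt(3)`` per residue.  The peptide generator digests a protein
in silico, plants phenylglyoxal adducts on chosen arginines and perturbs
the theoretical neutral masses with ppm-scale relative Gaussian noise.

All generators are deterministic given (parameters, seed); seeds are
explicit fields, never global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import BackboneFrame, ConformerTrajectory, wrap_angle


@dataclass
class MacrostateModel:
    """First-order Markov chain over K macrostates emitting von Mises angles.

    Parameters
    ----------
    state_means : (K, D) array, degrees in (-180, 180]
    concentrations : (D,) von Mises kappa per angle (dimensionless, > 0)
    transition_matrix : (K, K) row-stochastic
    initial_distribution : (K,) simplex vector; uniform if omitted
    seed : int
    """

    state_means: np.ndarray
    concentrations: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        self.state_means = np.atleast_2d(np.asarray(self.state_means, dtype=float))
        k, d = self.state_means.shape
        if np.any(self.state_means <= -180.0) or np.any(self.state_means > 180.0):
            raise ValidationError("state means must lie in (-180, 180]")
        self.concentrations = np.broadcast_to(
            np.asarray(self.concentrations, dtype=float), (d,)
        ).copy()
        if np.any(self.concentrations <= 0):
            raise ValidationError("von Mises concentrations must be positive")
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.shape != (k, k):
            raise ValidationError(f"transition matrix must be ({k}, {k})")
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
            raise ValidationError("transition matrix rows must sum to 1")
        self.transition_matrix = t
        if self.initial_distribution is None:
            self.initial_distribution = np.full(k, 1.0 / k)
        else:
            p = np.asarray(self.initial_distribution, dtype=float)
            if p.shape != (k,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValidationError("initial distribution must be a length-K simplex vector")
            self.initial_distribution = p

    @property
    def n_states(self) -> int:
        return self.state_means.shape[0]

    @property
    def n_angles(self) -> int:
        return self.state_means.shape[1]

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class SyntheticDihedralSet:
    """Frames x angles matrix with per-frame true state labels."""

    angles: np.ndarray
    true_labels: np.ndarray
    angle_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.angles, columns=self.angle_ids)
        df.insert(0, "frame", np.arange(len(df)))
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_truth_json(self, path, **extra) -> None:
        payload = {
            "true_labels": self.true_labels.tolist(),
            "angle_ids": self.angle_ids,
            **extra,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_dihedral_markov(model: MacrostateModel, n_frames: int,
                             angle_ids: Sequence[str] | None = None) -> SyntheticDihedralSet:
    """Sample a Markov state path and von Mises angle emissions.

    Angles are wrapped into (-180, 180].  Deterministic given ``model.seed``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rng = np.random.default_rng(model.seed)
    k = model.n_states
    labels = np.empty(n_frames, dtype=int)
    labels[0] = rng.choice(k, p=model.initial_distribution)
    for t in range(1, n_frames):
        labels[t] = rng.choice(k, p=model.transition_matrix[labels[t - 1]])
    mu = np.radians(model.state_means[labels])
    kappa = np.broadcast_to(model.concentrations, mu.shape)
    angles = np.degrees(rng.vonmises(mu, kappa))
    angles = wrap_angle(angles)
    if angle_ids is None:
        angle_ids = [f"angle_{j}" for j in range(model.n_angles)]
    else:
        angle_ids = list(angle_ids)
        if len(angle_ids) != model.n_angles:
            raise ValidationError("angle_ids length must match the number of angles")
    return SyntheticDihedralSet(angles, labels, angle_ids)


@dataclass
class FluctuationSpec:
    """Gaussian positional-fluctuation model around a reference backbone.

    ``sigma_per_residue`` is the per-coordinate displacement SD in Angstrom;
    the whole N/CA/C triplet of a residue moves rigidly, so per-residue RMSF
    ground truth is sigma * sqrt(3).
    """

    reference: BackboneFrame
    sigma_per_residue: np.ndarray
    n_frames: int
    seed: int = 0

    def __post_init__(self):
        sig = np.broadcast_to(
            np.asarray(self.sigma_per_residue, dtype=float),
            (self.reference.n_residues,),
        ).copy()
        if np.any(sig < 0):
            raise ValidationError("sigma values must be >= 0")
        self.sigma_per_residue = sig
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


def simulate_fluctuating_trajectory(spec: FluctuationSpec,
                                    system_label: str = "synthetic",
                                    replica_id: int = 0) -> ConformerTrajectory:
    """Reference frame plus i.i.d. isotropic Gaussian displacements per residue."""
    rng = np.random.default_rng(spec.seed)
    disp = rng.normal(
        0.0, spec.sigma_per_residue[None, :, None],
        size=(spec.n_frames, spec.reference.n_residues, 3),
    )
    coords = spec.reference.coords[None, :, :, :] + disp[:, :, None, :]
    return ConformerTrajectory(
        coords, spec.reference.residue_indices, spec.reference.residue_names,
        system_label, replica_id,
    )


@dataclass
class SyntheticScoreTable:
    """Per-frame scalar scores with cluster-dependent means (energy-like units)."""

    scores: np.ndarray
    cluster_means: np.ndarray
    noise_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.scores)), "score": self.scores})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_score_table(true_labels, cluster_means, noise_sd: float,
                         seed: int = 0) -> SyntheticScoreTable:
    """score_t = cluster_means[label_t] + N(0, noise_sd)."""
    labels = np.asarray(true_labels, dtype=int)
    if labels.size == 0:
        raise ValidationError("true_labels must be nonempty")
    means = np.asarray(cluster_means, dtype=float)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    scores = means[labels] + rng.normal(0.0, noise_sd, size=labels.shape)
    return SyntheticScoreTable(scores, means, float(noise_sd))


def simulate_peptide_observations(protein, pg_sites, intensity_per_site,
                                  ppm_noise: float = 0.0, seed: int = 0,
                                  max_missed: int = 2,
                                  baseline_intensity: float = 100.0) -> pd.DataFrame:
    """Observed neutral-mass/intensity table with planted PG sites.

    For every tryptic peptide covering a planted arginine, one observation is
    emitted per covered site carrying a single phenylglyoxal adduct there, at
    that site's intensity; every peptide is also emitted unmodified at the
    baseline intensity.  Fixed carbamidomethylation of cysteines is applied
    throughout, matching the search configuration the matcher assumes.
    Masses are perturbed multiplicatively: m_obs = m * (1 + eps),
    eps ~ N(0, ppm_noise * 1e-6).

    Returns a DataFrame with columns mass_da, intensity, peptide, pg_site
    (-1 for unmodified observations).
    """
    from .site_mapping import (CARBAMIDOMETHYL, PHENYLGLYOXAL, apply_fixed,
                               digest, peptide_mass)

    pg_sites = sorted(int(s) for s in pg_sites)
    intensity = dict(zip(pg_sites, np.broadcast_to(
        np.asarray(intensity_per_site, dtype=float), (len(pg_sites),))))
    for site in pg_sites:
        if protein.sequence[site - 1] != "R":
            raise ValidationError(
                f"planted PG site {site} is {protein.sequence[site - 1]!r}, not arginine"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for pep in digest(protein, max_missed=max_missed):
        fixed = apply_fixed(pep, [CARBAMIDOMETHYL])
        base_mass = peptide_mass(pep, fixed)
        rows.append((base_mass, baseline_intensity, pep.sequence, -1))
        for site in pg_sites:
            if pep.start <= site <= pep.end:
                mods = dict(fixed)
                mods[site] = PHENYLGLYOXAL
                rows.append((peptide_mass(pep, mods), intensity[site], pep.sequence, site))
    df = pd.DataFrame(rows, columns=["mass_da", "intensity", "peptide", "pg_site"])
    eps = rng.normal(0.0, ppm_noise * 1e-6, size=len(df))
    df["mass_da"] = df["mass_da"] * (1.0 + eps)
    return df
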