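"""Self-organizing-map macrostate pipeline.

A square SOM is trained online on standardized dihedral features; model
quality over a (grid side, neighborhood width) hyperparameter grid is judged
by a three-metric rule — keep the 10% of models with the lowest topographic
error, then rank those by quantization error with distortion as tie-break.
The weight vectors of units that are best-matching units (BMUs) for at least
one frame are then merged by hierarchical agglomerative clustering (Ward/
Euclidean by default); the number of macrostates is chosen from a candidate
range by the silhouette curve, taking its *second-largest* value (a
conservative heuristic that avoids the frequent degenerate maximum at the
smallest k; the global maximum is available behind a flag).  Every frame
inherits the cluster of its BMU.

Representative conformers per macrostate are the frame with the lowest
external score (e.g. an MM/GBSA effective energy supplied as a per-frame
table) and the frame with the highest subset C-alpha RMSD from a reference
— the most stable and the most excursive member of each state.

Estimators follow scikit-learn conventions (``fit``, ``predict``,
``get_params``; fitted attributes carry a trailing underscore) and compose
with scikit-learn pipelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError
from .geometry import BackboneFrame, ConformerTrajectory, ResidueRange
from .fluctuation import rmsd_series

DEFAULT_SIDES = tuple(range(5, 105, 5))
DEFAULT_SIGMAS = tuple(np.round(np.arange(1.00, 6.25 + 1e-9, 0.25), 2))


def standardize(X) -> tuple[np.ndarray, StandardScaler]:
    """Center to zero mean and scale to unit variance (population SD).

    Raises on zero-variance features, naming them — a constant dihedral
    cannot be meaningfully standardized and would poison the SOM distance
    metric.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("X must be a frames x features matrix with >= 2 frames")
    var = X.var(axis=0)
    dead = np.nonzero(var == 0.0)[0]
    if dead.size:
        raise ValidationError(f"zero-variance feature(s) at column(s) {dead.tolist()}")
    scaler = StandardScaler().fit(X)
    return scaler.transform(X), scaler


def _asymptotic_decay(value: float, t: int, n_epochs: int) -> float:
    return value / (1.0 + t / (n_epochs / 2.0))


@dataclass(frozen=True)
class SomMetrics:
    """Fit-quality metrics of a trained SOM on a dataset."""

    quantization_error: float
    topographic_error: float
    distortion: float

    def __post_init__(self):
        if self.quantization_error < 0 or self.distortion < 0:
            raise ValidationError("QE and distortion must be >= 0")
        if not 0.0 <= self.topographic_error <= 1.0:
            raise ValidationError("topographic error must lie in [0, 1]")


class SelfOrganizingMap(BaseEstimator):
    """Square-grid SOM trained by online (single-sample) updates.

    Parameters
    ----------
    grid_side : int
        Side length n of the square n x n map (n >= 2).
    sigma : float
        Initial Gaussian neighborhood width, in grid units; must satisfy
        0 < sigma < grid_side.
    learning_rate : float, default 0.5
    n_epochs : int, default 5000
        Number of single-sample update steps.
    decay : str, default "asymptotic"
        Learning-rate and width schedule: x(t) = x0 / (1 + t / (T/2)).
    random_state : int or None
        Seeds sample order and weight initialization; fixed seed gives
        bit-identical weights.

    Attributes
    ----------
    weights_ : (n_units, D) array
    grid_coords_ : (n_units, 2) integer grid positions
    sigma_final_ : neighborhood width at the last epoch
    """

    def __init__(self, grid_side: int = 10, sigma: float = 1.0,
                 learning_rate: float = 0.5, n_epochs: int = 5000,
                 decay: str = "asymptotic", random_state: int | None = None):
        self.grid_side = grid_side
        self.sigma = sigma
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.decay = decay
        self.random_state = random_state

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_weights(cls, weights, grid_shape: tuple[int, int],
                     sigma_final: float = 1.0) -> "SelfOrganizingMap":
        """Wrap an explicit weight matrix as a fitted map (for analysis only).

        ``grid_shape`` may be rectangular; training itself always uses square
        grids.
        """
        weights = np.asarray(weights, dtype=float)
        rows, cols = grid_shape
        if weights.shape[0] != rows * cols:
            raise ValidationError("weights row count must equal rows * cols")
        model = cls(grid_side=max(rows, cols))
        model.weights_ = weights.copy()
        gy, gx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        model.grid_coords_ = np.stack([gy.ravel(), gx.ravel()], axis=1).astype(float)
        model.sigma_final_ = float(sigma_final)
        model.n_features_in_ = weights.shape[1]
        return model

    def _validate_params(self):
        if self.grid_side < 2:
            raise ValidationError("grid_side must be >= 2")
        if not 0 < self.sigma < self.grid_side:
            raise ValidationError("sigma must satisfy 0 < sigma < grid_side")
        if self.decay != "asymptotic":
            raise ValidationError(f"unknown decay schedule {self.decay!r}")

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y=None) -> "SelfOrganizingMap":
        self._validate_params()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValidationError("X must be a nonempty frames x features matrix")
        rng = np.random.default_rng(self.random_state)
        n = self.grid_side
        n_units = n * n
        gy, gx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        coords = np.stack([gy.ravel(), gx.ravel()], axis=1).astype(float)
        # initialize unit weights from random data samples
        init_idx = rng.integers(0, X.shape[0], size=n_units)
        w = X[init_idx].astype(float).copy()
        order = rng.integers(0, X.shape[0], size=self.n_epochs)
        for t in range(self.n_epochs):
            x = X[order[t]]
            alpha = _asymptotic_decay(self.learning_rate, t, self.n_epochs)
            sig = _asymptotic_decay(self.sigma, t, self.n_epochs)
            d2 = np.sum((w - x) ** 2, axis=1)
            bmu = int(np.argmin(d2))
            gd2 = np.sum((coords - coords[bmu]) ** 2, axis=1)
            h = np.exp(-gd2 / (2.0 * sig * sig))
            w += alpha * h[:, None] * (x - w)
        self.weights_ = w
        self.grid_coords_ = coords
        self.sigma_final_ = _asymptotic_decay(self.sigma, self.n_epochs - 1, self.n_epochs)
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ------------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise ValidationError("SOM is not fitted")

    def _unit_distances(self, X, chunk: int = 1024):
        """Yield (slice, squared distance block samples x units)."""
        X = np.asarray(X, dtype=float)
        for lo in range(0, X.shape[0], chunk):
            block = X[lo:lo + chunk]
            d2 = (
                np.sum(block ** 2, axis=1)[:, None]
                - 2.0 * block @ self.weights_.T
                + np.sum(self.weights_ ** 2, axis=1)[None, :]
            )
            np.maximum(d2, 0.0, out=d2)
            yield slice(lo, lo + block.shape[0]), d2

    def predict(self, X) -> np.ndarray:
        """Best-matching-unit (flat) index per sample."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=int)
        for sl, d2 in self._unit_distances(X):
            out[sl] = np.argmin(d2, axis=1)
        return out

    def transform(self, X) -> np.ndarray:
        """Distance of each sample to every unit."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        full = np.empty((X.shape[0], self.weights_.shape[0]))
        for sl, d2 in self._unit_distances(X):
            full[sl] = np.sqrt(d2)
        return full

    # -- metrics --------------------------------------------------------------

    def metrics(self, X, adjacency: str = "8") -> SomMetrics:
        """Quantization error, topographic error and distortion on ``X``.

        QE is the mean Euclidean sample-to-BMU distance.  TE is the fraction
        of samples whose best and second-best units are not grid-adjacent
        (8-neighborhood by default, 4-neighborhood optional).  Distortion is
        the neighborhood-weighted sum of squared sample-to-unit distances
        using the final-epoch neighborhood width.
        """
        self._check_fitted()
        if adjacency not in ("4", "8"):
            raise ValidationError("adjacency must be '4' or '8'")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ValidationError("metrics need nonempty data")
        qe_sum = 0.0
        te_count = 0
        distortion = 0.0
        sig2 = 2.0 * self.sigma_final_ ** 2
        coords = self.grid_coords_
        for sl, d2 in self._unit_distances(X):
            order2 = np.argpartition(d2, 1, axis=1)[:, :2]
            # argpartition does not order the pair; fix it
            first = np.where(
                d2[np.arange(d2.shape[0]), order2[:, 0]]
                <= d2[np.arange(d2.shape[0]), order2[:, 1]],
                order2[:, 0], order2[:, 1],
            )
            second = np.where(first == order2[:, 0], order2[:, 1], order2[:, 0])
            qe_sum += np.sum(np.sqrt(d2[np.arange(d2.shape[0]), first]))
            delta = np.abs(coords[first] - coords[second])
            if adjacency == "8":
                adjacent = np.max(delta, axis=1) <= 1
            else:
                adjacent = np.sum(delta, axis=1) <= 1
            te_count += int(np.sum(~adjacent))
            gd2 = np.sum(
                (coords[first][:, None, :] - coords[None, :, :]) ** 2, axis=2
            )
            h = np.exp(-gd2 / sig2)
            distortion += float(np.sum(h * d2))
        n = X.shape[0]
        return SomMetrics(qe_sum / n, te_count / n, distortion)


# ---------------------------------------------------------------------------
# hyperparameter grid search


def select_best_model(table: pd.DataFrame, decile: float = 0.10) -> int:
    """Index of the winning row under the three-metric selection rule.

    Keep the ``ceil(decile * N)`` rows (minimum 1) with the lowest
    topographic error — ties broken by row order — then pick the row with
    the lowest quantization error, using distortion and finally row order
    as tie-breaks.
    """
    if len(table) == 0:
        raise ValidationError("empty metrics table")
    m = max(1, math.ceil(decile * len(table)))
    te_order = np.argsort(table["te"].to_numpy(), kind="stable")
    candidates = te_order[:m]
    qe = table["qe"].to_numpy()[candidates]
    dist = table["distortion"].to_numpy()[candidates]
    # lexicographic: qe, then distortion, then original order
    best = candidates[np.lexsort((candidates, dist, qe))[0]]
    return int(best)


def grid_search(X, sides: Sequence[int] = DEFAULT_SIDES,
                sigmas: Sequence[float] = DEFAULT_SIGMAS,
                learning_rate: float = 0.5, n_epochs: int = 5000,
                random_state: int = 0, adjacency: str = "8",
                ) -> tuple[SelfOrganizingMap, pd.DataFrame]:
    """Train a SOM per (side, sigma) combination and apply the selection rule.

    Returns the winning model and the full metrics table with columns
    ``side, sigma, qe, te, distortion, selected``.  Each combination is
    seeded deterministically from ``random_state``.
    """
    sides = list(sides)
    sigmas = list(sigmas)
    if not sides or not sigmas:
        raise ValidationError("sides and sigmas must be nonempty")
    if max(sigmas) >= min(sides):
        raise ValidationError("every sigma must be smaller than the smallest side")
    models = []
    rows = []
    combo = 0
    for side in sides:
        for sigma in sigmas:
            seed = (int(random_state) * 1000003 + combo) % (2**31 - 1)
            som = SelfOrganizingMap(
                grid_side=side, sigma=sigma, learning_rate=learning_rate,
                n_epochs=n_epochs, random_state=seed,
            ).fit(X)
            met = som.metrics(X, adjacency=adjacency)
            models.append(som)
            rows.append(
                {
                    "side": side, "sigma": sigma,
                    "qe": met.quantization_error,
                    "te": met.topographic_error,
                    "distortion": met.distortion,
                }
            )
            combo += 1
    table = pd.DataFrame(rows)
    winner = select_best_model(table)
    table["selected"] = False
    table.loc[winner, "selected"] = True
    return models[winner], table


# ---------------------------------------------------------------------------
# macrostate assignment


@dataclass
class MacrostateAssignment:
    """Frame-to-macrostate labelling with its model-selection diagnostics."""

    labels: np.ndarray
    k: int
    silhouette_by_k: dict[int, float]
    populations: np.ndarray
    bmu_to_cluster: dict[int, int]
    frame_bmus: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.populations = np.asarray(self.populations, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValidationError("labels must lie in [0, k)")
        if int(self.populations.sum()) != self.labels.size:
            raise ValidationError("populations must sum to the frame count")

    def silhouette_frame(self) -> pd.DataFrame:
        ks = sorted(self.silhouette_by_k)
        return pd.DataFrame(
            {"k": ks, "silhouette": [self.silhouette_by_k[k] for k in ks]}
        )


def choose_k(silhouette_by_k: Mapping[int, float], selection: str = "second_max") -> int:
    """Pick the cluster count from a silhouette curve.

    ``second_max`` takes the k with the second-largest silhouette value
    (ties resolved toward smaller k); ``global_max`` takes the largest.
    """
    if selection not in ("second_max", "global_max"):
        raise ValidationError("selection must be 'second_max' or 'global_max'")
    items = sorted(silhouette_by_k.items())  # ascending k
    if not items:
        raise ValidationError("empty silhouette curve")
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    if selection == "global_max" or len(ranked) == 1:
        return ranked[0][0]
    return ranked[1][0]


def cluster_neurons(model: SelfOrganizingMap, X, k_range: tuple[int, int] = (5, 20),
                    selection: str = "second_max", linkage: str = "ward",
                    ) -> MacrostateAssignment:
    """Cluster BMU-hit unit weights hierarchically and label every frame.

    Only units that are the BMU of at least one frame enter the clustering
    (each distinct unit once, unweighted).  Agglomerative clustering with the
    given linkage runs for every k in ``k_range``; the silhouette score is
    evaluated on the unit weights and k is chosen per ``selection``.  If
    fewer units are hit than ``k_range`` allows, the range is truncated with
    a warning; fewer than 3 hit units is an error.
    """
    bmus = model.predict(X)
    hit_units = np.unique(bmus)
    if hit_units.size < 3:
        raise ValidationError(
            f"only {hit_units.size} distinct BMU-hit units; cannot cluster"
        )
    k_min, k_max = k_range
    if k_min < 2:
        raise ValidationError("k_min must be >= 2")
    if hit_units.size <= k_max:
        new_max = hit_units.size - 1
        warnings.warn(
            f"only {hit_units.size} BMU-hit units: truncating k range to "
            f"[{min(k_min, new_max)}, {new_max}]",
            stacklevel=2,
        )
        k_max = new_max
        k_min = min(k_min, new_max)
    w = model.weights_[hit_units]
    sil: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        hac = AgglomerativeClustering(n_clusters=k, linkage=linkage)
        unit_labels = hac.fit_predict(w)
        sil[k] = float(silhouette_score(w, unit_labels))
        labelings[k] = unit_labels
    k = choose_k(sil, selection)
    unit_labels = labelings[k]
    bmu_to_cluster = {int(u): int(c) for u, c in zip(hit_units, unit_labels)}
    labels = np.array([bmu_to_cluster[int(b)] for b in bmus])
    populations = np.bincount(labels, minlength=k)
    return MacrostateAssignment(labels, k, sil, populations, bmu_to_cluster, bmus)


# ---------------------------------------------------------------------------
# representative frames


@dataclass(frozen=True)
class ClusterRepresentatives:
    """The most stable and the most excursive frame of one macrostate."""

    cluster: int
    min_score_frame: int
    min_score: float
    max_rmsd_frame: int
    max_rmsd: float


def select_representatives(assignment: MacrostateAssignment, scores,
                           traj: ConformerTrajectory | None = None,
                           subset: ResidueRange | None = None,
                           reference: BackboneFrame | None = None,
                           ) -> dict[int, ClusterRepresentatives]:
    """Per cluster: the minimum-score frame and the maximum subset-RMSD frame.

    ``scores`` is a per-frame array or a DataFrame with ``frame``/``score``
    columns and must cover every frame.  The RMSD leg needs a trajectory, a
    C-alpha subset range and a reference frame; without them only the score
    representative is filled and the RMSD fields mirror it.  Ties break
    toward the lowest frame index.
    """
    n = assignment.labels.size
    if isinstance(scores, pd.DataFrame):
        if not {"frame", "score"} <= set(scores.columns):
            raise ValidationError("score table needs 'frame' and 'score' columns")
        s = np.full(n, np.nan)
        idx = scores["frame"].to_numpy(dtype=int)
        if np.any(idx < 0) or np.any(idx >= n):
            raise ValidationError("score table references frames outside the trajectory")
        s[idx] = scores["score"].to_numpy(dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
        if s.shape != (n,):
            raise ValidationError(f"scores must cover all {n} frames")
    missing = np.nonzero(~np.isfinite(s))[0]
    if missing.size:
        raise ValidationError(f"missing scores for frames {missing.tolist()[:20]}")
    rmsd = None
    if traj is not None:
        if traj.n_frames != n:
            raise ValidationError("trajectory frame count does not match assignment")
        if reference is None:
            raise ValidationError("reference frame required for RMSD representatives")
        rmsd = rmsd_series(traj, reference, subset, atoms=("CA",))
    out: dict[int, ClusterRepresentatives] = {}
    for c in range(assignment.k):
        members = np.nonzero(assignment.labels == c)[0]
        if members.size == 0:
            continue
        best_score = members[np.argmin(s[members])]
        if rmsd is not None:
            best_rmsd = members[np.argmax(rmsd[members])]
            rep_rmsd = float(rmsd[best_rmsd])
        else:
            best_rmsd = best_score
            rep_rmsd = float("nan")
        out[c] = ClusterRepresentatives(
            c, int(best_score), float(s[best_score]), int(best_rmsd), rep_rmsd
        )
    return out


# ---------------------------------------------------------------------------
# end-to-end estimator


class SomMacrostateClusterer(ClusterMixin, BaseEstimator):
    """Standardize -> (grid-searched) SOM -> HAC macrostates, as one estimator.

    Scalar ``grid_side``/``sigma`` train a single map; iterables trigger the
    grid search with its three-metric selection rule.

    Parameters
    ----------
    grid_side : int or sequence of int
    sigma : float or sequence of float
    learning_rate, n_epochs : SOM schedule (0.5 / 5000 by default)
    k_range : (k_min, k_max) candidate macrostate counts, default (5, 20)
    selection : 'second_max' (default) or 'global_max' silhouette rule
    linkage : HAC linkage, default 'ward'
    scale : standardize features before training (default True)
    random_state : int

    Attributes
    ----------
    som_ : the winning trained SOM
    metrics_table_ : grid-search table (single row when no search)
    assignment_ : MacrostateAssignment
    labels_ : per-frame macrostate labels
    scaler_ : fitted StandardScaler (when ``scale``)
    """

    def __init__(self, grid_side=10, sigma=1.0, learning_rate: float = 0.5,
                 n_epochs: int = 5000, k_range: tuple[int, int] = (5, 20),
                 selection: str = "second_max", linkage: str = "ward",
                 scale: bool = True, adjacency: str = "8",
                 random_state: int = 0):
        self.grid_side = grid_side
        self.sigma = sigma
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.k_range = k_range
        self.selection = selection
        self.linkage = linkage
        self.scale = scale
        self.adjacency = adjacency
        self.random_state = random_state

    def fit(self, X, y=None) -> "SomMacrostateClusterer":
        X = np.asarray(X, dtype=float)
        if self.scale:
            Xs, self.scaler_ = standardize(X)
        else:
            Xs = X
        sides = [self.grid_side] if np.isscalar(self.grid_side) else list(self.grid_side)
        sigmas = [self.sigma] if np.isscalar(self.sigma) else list(self.sigma)
        self.som_, self.metrics_table_ = grid_search(
            Xs, sides, sigmas, self.learning_rate, self.n_epochs,
            self.random_state, self.adjacency,
        )
        self.assignment_ = cluster_neurons(
            self.som_, Xs, self.k_range, self.selection, self.linkage
        )
        self.labels_ = self.assignment_.labels
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Macrostate of new frames via their BMU (unseen BMUs are an error)."""
        if not hasattr(self, "som_"):
            raise ValidationError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if self.scale:
            X = self.scaler_.transform(X)
        bmus = self.som_.predict(X)
        unseen = [int(b) for b in np.unique(bmus)
                  if int(b) not in self.assignment_.bmu_to_cluster]
        if unseen:
            raise ValidationError(f"BMU units {unseen[:10]} were never hit during fit")
        return np.array([self.assignment_.bmu_to_cluster[int(b)] for b in bmus])
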