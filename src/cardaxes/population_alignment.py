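"""Population-level rotational alignment of anatomical and electrical axes.

The average rotational relationship between the two axis families is learned
by solving the orthogonal Procrustes problem: find the proper rotation T
minimising sum_i ||e_i - T a_i||^2 over paired unit vectors. With
H = sum_i a_i e_i^T and SVD H = U S V^T, the optimum is T = V D U^T where
D = diag(1, 1, det(V U^T)) guards against reflections (the Kabsch
correction). Prediction quality is the mean geodesic distance (MGD, radians)
between predicted and observed electrical directions on a held-out test
split; ranking the 20 anatomical x electrical definition pairs by test MGD
identifies the pair with the strongest anatomical-electrical coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cardaxes.axes_metrics import signed_delta
from cardaxes.errors import DegenerateGeometryError, UsageError
from cardaxes.mesh_anatomy import ANATOMICAL_METHODS
from cardaxes.ecg_vcg import ELECTRICAL_METHODS


@dataclass
class RotationModel:
    """Fitted proper rotation mapping anatomical to electrical unit vectors."""

    matrix: np.ndarray
    anat_method: str = ""
    elec_method: str = ""
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)
    seed: int | None = None
    mgd_train: float = float("nan")
    mgd_test: float = float("nan")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise UsageError("rotation matrix must be 3x3")
        if not np.allclose(self.matrix.T @ self.matrix, np.eye(3), atol=1e-9):
            raise UsageError("rotation matrix must be orthogonal")
        if abs(np.linalg.det(self.matrix) - 1.0) > 1e-9:
            raise UsageError("rotation matrix must be proper (det +1)")


def _as_unit_rows(vectors: Sequence[np.ndarray], name: str) -> np.ndarray:
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise UsageError(f"{name} must be a sequence of 3-vectors")
    norms = np.linalg.norm(arr, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise UsageError(f"{name} must contain unit vectors")
    return arr


def fit_rotation(
    anat: Sequence[np.ndarray],
    elec: Sequence[np.ndarray],
    anat_method: str = "",
    elec_method: str = "",
) -> RotationModel:
    """Least-squares proper rotation T with T a_i ~ e_i (Kabsch/Procrustes)."""
    A = _as_unit_rows(anat, "anat")
    E = _as_unit_rows(elec, "elec")
    if len(A) != len(E):
        raise UsageError("anat and elec must be paired (equal length)")
    if len(A) < 3:
        raise UsageError("need at least 3 vector pairs")
    H = A.T @ E  # sum_i a_i e_i^T
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError("vector pairs are collinear; rotation underdetermined")
    V = Vt.T
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(V @ U.T))])
    T = V @ D @ U.T
    return RotationModel(matrix=T, anat_method=anat_method, elec_method=elec_method)


def predict_electrical(model: RotationModel, anat: np.ndarray) -> np.ndarray:
    """Apply the fitted rotation to one or many anatomical unit vectors."""
    arr = np.asarray(anat, dtype=float)
    if arr.ndim == 1:
        return model.matrix @ arr
    return arr @ model.matrix.T


def mean_geodesic_distance(
    pred: Sequence[np.ndarray], true: Sequence[np.ndarray]
) -> float:
    """Mean great-circle distance (radians) between paired unit vectors."""
    P = _as_unit_rows(pred, "pred")
    T = _as_unit_rows(true, "true")
    if len(P) != len(T):
        raise UsageError("pred and true must have equal length")
    if len(P) == 0:
        raise UsageError("need at least one pair")
    dots = np.clip(np.einsum("ij,ij->i", P, T), -1.0, 1.0)
    return float(np.mean(np.arccos(dots)))


def _method_columns(method: str) -> list[str]:
    return [f"{method}_{c}" for c in "xyz"]


def train_test_split_ids(ids: Sequence, split_fraction: float, seed: int) -> tuple[list, list]:
    """Seeded subject-level split, shared by all method pairs."""
    if not 0.0 < split_fraction < 1.0:
        raise UsageError("split fraction must be in (0, 1)")
    ids = sorted(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(split_fraction * len(ids)))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def evaluate_method_pairs(
    cohort: pd.DataFrame,
    split_fraction: float = 0.8,
    seed: int = 0,
    anat_methods: Sequence[str] = ANATOMICAL_METHODS,
    elec_methods: Sequence[str] = ELECTRICAL_METHODS,
) -> tuple[pd.DataFrame, dict[tuple[str, str], RotationModel]]:
    """Fit and score a rotation for every anatomical x electrical pair.

    ``cohort`` is indexed by subject_id with unit-vector columns
    ``<method>_x/_y/_z`` for each of the 9 definitions. One seeded
    subject-level 80/20 split is shared across all pairs so their test MGDs
    are directly comparable (paired). Subjects with any non-finite axis
    component are dropped (count recorded in the table's ``attrs``).

    Returns the anat x elec table of test MGDs (radians) and the fitted
    models keyed by (anat_method, elec_method); the arg-min pair is stored
    in ``table.attrs["best_pair"]``.
    """
    needed = [c for m in list(anat_methods) + list(elec_methods) for c in _method_columns(m)]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise UsageError(f"cohort table missing columns {missing}")
    if cohort.index.has_duplicates:
        raise UsageError("duplicate subject ids in cohort table")

    finite = np.isfinite(cohort[needed].to_numpy(dtype=float)).all(axis=1)
    dropped = int((~finite).sum())
    data = cohort.loc[finite].sort_index()
    if len(data) < 10:
        raise UsageError(f"cohort too small after drops: {len(data)} < 10")

    train_ids, test_ids = train_test_split_ids(data.index, split_fraction, seed)
    train, test = data.loc[train_ids], data.loc[test_ids]

    table = pd.DataFrame(
        index=list(anat_methods), columns=list(elec_methods), dtype=float
    )
    models: dict[tuple[str, str], RotationModel] = {}
    for am in anat_methods:
        a_tr = train[_method_columns(am)].to_numpy()
        a_te = test[_method_columns(am)].to_numpy()
        for em in elec_methods:
            e_tr = train[_method_columns(em)].to_numpy()
            e_te = test[_method_columns(em)].to_numpy()
            model = fit_rotation(a_tr, e_tr, anat_method=am, elec_method=em)
            model.train_ids = list(train_ids)
            model.test_ids = list(test_ids)
            model.seed = seed
            model.mgd_train = mean_geodesic_distance(predict_electrical(model, a_tr), e_tr)
            model.mgd_test = mean_geodesic_distance(predict_electrical(model, a_te), e_te)
            table.loc[am, em] = model.mgd_test
            models[(am, em)] = model

    flat = table.stack()
    best = flat.idxmin()
    table.attrs.update(
        {
            "best_pair": (str(best[0]), str(best[1])),
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "n_dropped": dropped,
            "seed": seed,
        }
    )
    return table, models


def exclude_outlier_vectors(
    theta: Sequence[float], phi: Sequence[float], k: float = 3.0
) -> tuple[np.ndarray, float]:
    """Population-level +/- k SD cutoff on the spherical coordinates.

    A subject is excluded when its theta deviates from the circular
    population mean by more than k SD (deviations wrapped to (-180, 180])
    or its phi deviates from the plain mean by more than k SD. Returns the
    inclusion mask and the excluded fraction.
    """
    th = np.asarray(theta, dtype=float)
    ph = np.asarray(phi, dtype=float)
    if th.shape != ph.shape or th.ndim != 1:
        raise UsageError("theta and phi must be equal-length 1D arrays")
    if len(th) < 10:
        raise UsageError("need at least 10 subjects for the population cutoff")

    # circular mean of theta, then wrapped deviations
    rad = np.radians(th)
    mean_theta = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    dev_theta = np.array([signed_delta(t, mean_theta) for t in th])
    sd_theta = np.std(dev_theta, ddof=1)
    sd_phi = np.std(ph, ddof=1)

    bad_theta = np.abs(dev_theta) > k * sd_theta if sd_theta > 0 else np.zeros(len(th), bool)
    bad_phi = np.abs(ph - ph.mean()) > k * sd_phi if sd_phi > 0 else np.zeros(len(th), bool)
    include = ~(bad_theta | bad_phi)
    return include, float(1.0 - include.mean())
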