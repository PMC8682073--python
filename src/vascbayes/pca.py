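"""Data-driven vascular risk score: correlation-matrix PCA on eight
standardised vascular-health indicators, with split-sample replication and
projection of new subjects onto training-set loadings.

The eight indicators, in canonical order, are BMI, mean arterial pressure,
HDL, LDL, total cholesterol, triglycerides, fasting glucose and a
current-smoker indicator.  PCA is performed on z-scored variables (the
indicators have incommensurate units), so eigenvalues sum to the number of
variables.  Loadings carry a deterministic sign convention: within each
component the entry of largest magnitude is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VASCULAR_PCA_VARIABLES",
    "PCAModel",
    "fit_pca",
    "split_replicate",
    "tucker_congruence",
]

VASCULAR_PCA_VARIABLES = (
    "bmi", "map", "hdl", "ldl", "total_chol",
    "triglycerides", "fasting_glucose", "current_smoker",
)


@dataclass(frozen=True)
class PCAModel:
    """Loadings, eigenvalues and standardisation parameters of a fitted PCA."""

    variables: tuple
    means: np.ndarray          # (p,)
    sds: np.ndarray            # (p,)
    loadings: np.ndarray       # (p, m), column-orthonormal
    eigenvalues: np.ndarray    # (m,), nonincreasing
    n_train: int

    @property
    def explained_variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / len(self.variables)

    def project(self, subjects, n_components: int = 3) -> pd.DataFrame:
        """Scores of new subjects along the first ``n_components`` training
        components, using the training means and SDs for standardisation."""
        df = pd.DataFrame(subjects)
        missing = [v for v in self.variables if v not in df.columns]
        if missing:
            raise ValueError(f"missing variables: {missing}")
        X = df[list(self.variables)].to_numpy(float)
        if np.isnan(X).any():
            raise ValueError("missing values in projection input")
        Z = (X - self.means) / self.sds
        scores = Z @ self.loadings[:, :n_components]
        cols = [f"pcs{i + 1}" for i in range(n_components)]
        return pd.DataFrame(scores, columns=cols, index=df.index)

    def to_json(self, path):
        payload = {
            "variables": list(self.variables),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_train": self.n_train,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(variables=tuple(d["variables"]),
                   means=np.asarray(d["means"], float),
                   sds=np.asarray(d["sds"], float),
                   loadings=np.asarray(d["loadings"], float),
                   eigenvalues=np.asarray(d["eigenvalues"], float),
                   n_train=int(d["n_train"]))


def fit_pca(training, variables=VASCULAR_PCA_VARIABLES) -> PCAModel:
    """Fit correlation-matrix PCA on complete rows of the training table."""
    df = pd.DataFrame(training)
    missing_cols = [v for v in variables if v not in df.columns]
    if missing_cols:
        raise ValueError(f"missing variables: {missing_cols}")
    X = df[list(variables)].to_numpy(float)
    if np.isnan(X).any():
        bad = df.index[np.isnan(X).any(axis=1)].tolist()
        raise ValueError(f"missing values in rows {bad}")
    n, p = X.shape
    if n < 20:
        raise ValueError("need at least 20 complete training rows")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        const = [variables[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant columns: {const}")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    # SVD of Z/sqrt(n-1): right singular vectors are the loadings,
    # squared singular values the eigenvalues of the correlation matrix
    _, s, Vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
    loadings = Vt.T
    eigenvalues = s ** 2
    # sign convention: largest-|loading| entry positive in each component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(variables=tuple(variables), means=means, sds=sds,
                    loadings=loadings, eigenvalues=eigenvalues, n_train=n)


def tucker_congruence(u, v) -> float:
    """Tucker coefficient |u.v| / (||u|| ||v||) between two loading vectors."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    return float(abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def split_replicate(table, split_fraction: float = 0.5, seed: int = 0,
                    variables=VASCULAR_PCA_VARIABLES,
                    n_components: int = 3):
    """Split-sample PCA replication.

    Rows are randomly partitioned, PCA is fitted separately in each half, and
    per-component Tucker congruence between the two loading sets is reported
    for the first ``n_components`` components.

    Returns ``(model_train, model_test, congruence)``.
    """
    df = pd.DataFrame(table).reset_index(drop=True)
    if not 0 < split_fraction < 1:
        raise ValueError("split fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    n_train = int(round(len(df) * split_fraction))
    if n_train < 20 or len(df) - n_train < 20:
        raise ValueError("each split needs at least 20 rows")
    model_a = fit_pca(df.iloc[order[:n_train]], variables)
    model_b = fit_pca(df.iloc[order[n_train:]], variables)
    congruence = np.array([
        tucker_congruence(model_a.loadings[:, j], model_b.loadings[:, j])
        for j in range(n_components)
    ])
    return model_a, model_b, congruence
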