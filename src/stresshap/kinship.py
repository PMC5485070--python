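"""Marker-based kinship (realized relationship) matrices.

The kinship matrix K is the random-effect covariance shared by the
heritability, animal-model and multi-trait GWAS stages.  Two estimators
are offered:

``standardized``
    VanRaden-type cross-product of the column-centred, column-scaled call
    matrix, ``K = Z Z' / m`` over polymorphic markers.  This is the default
    and the estimator assumed by the rest of the pipeline.
``ibs``
    Identity-by-state: proportion of markers with identical calls.

Because downstream solvers require a positive semi-definite K, a kinship
whose smallest eigenvalue falls below ``-1e-8`` is ridge-repaired by adding
``delta * I`` with ``delta = |lambda_min| + 1e-8``; the applied ridge is
recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["KinshipMatrix", "compute_kinship"]

_SYM_TOL = 1e-10
_EIG_TOL = -1e-8


@dataclass
class KinshipMatrix:
    """n x n symmetric relatedness matrix aligned with ``accession_ids``."""

    accession_ids: list[str]
    K: np.ndarray
    estimator: str = "standardized"
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.accession_ids)
        if self.K.shape != (n, n):
            raise ValueError(f"K shape {self.K.shape} does not match {n} accessions")
        if np.max(np.abs(self.K - self.K.T)) > _SYM_TOL:
            raise ValueError("K is not symmetric to within 1e-10")

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def align(self, ids: list[str]) -> "KinshipMatrix":
        """Reorder/subset to the given accession ids."""
        index = {a: i for i, a in enumerate(self.accession_ids)}
        rows = np.array([index[a] for a in ids])
        return KinshipMatrix(
            accession_ids=list(ids),
            K=self.K[np.ix_(rows, rows)].copy(),
            estimator=self.estimator,
            ridge=self.ridge,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, index=self.accession_ids, columns=self.accession_ids)

    @classmethod
    def from_file(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(accession_ids=[str(a) for a in df.index], K=df.to_numpy())

    def to_file(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _ridge_repair(K: np.ndarray) -> tuple[np.ndarray, float]:
    lam_min = float(np.linalg.eigvalsh(K)[0])
    if lam_min < _EIG_TOL:
        delta = abs(lam_min) + 1e-8
        K = K + delta * np.eye(K.shape[0])
        return K, delta
    return K, 0.0


def compute_kinship(geno: GenotypeMatrix, estimator: str = "standardized") -> KinshipMatrix:
    """Compute a kinship matrix from a 0/1 genotype matrix.

    Monomorphic markers carry no relatedness information and are excluded
    for the standardized estimator (they are undefined after scaling).
    Raises if fewer than two polymorphic markers remain.
    """
    X = geno.calls.astype(float)
    p = X.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if estimator == "standardized":
        if poly.sum() < 2:
            raise ValueError("need at least 2 polymorphic markers for kinship")
        Xp = X[:, poly]
        pp = p[poly]
        Z = (Xp - pp) / np.sqrt(pp * (1.0 - pp))
        K = Z @ Z.T / Z.shape[1]
    elif estimator == "ibs":
        if poly.sum() < 2:
            raise ValueError("need at least 2 polymorphic markers for kinship")
        m = X.shape[1]
        K = (X @ X.T + (1.0 - X) @ (1.0 - X).T) / m
    else:
        raise ValueError(f"unknown kinship estimator {estimator!r}")
    K = (K + K.T) / 2.0
    K, delta = _ridge_repair(K)
    return KinshipMatrix(
        accession_ids=list(geno.accession_ids), K=K, estimator=estimator, ridge=delta
    )
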