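"""Linear per-source kernels, cosine normalization, additive combination,
and the joint input-output product kernel."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasources import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class KernelMatrix:
    """Symmetric gene x gene similarity grid."""

    genes: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel shape {self.values.shape} != ({n}, {n})")


def linear_kernel(X: FeatureMatrix) -> KernelMatrix:
    """Gram matrix of dot products between gene feature rows."""
    if not X.genes:
        raise ValueError("empty feature matrix")
    return KernelMatrix(list(X.genes), X.values @ X.values.T, normalized=False)


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Cosine normalization: K(i,j) / sqrt(K(i,i) K(j,j)), unit diagonal.

    Genes with a zero diagonal (all-zero feature rows in this source) get
    zeroed rows/columns with a unit diagonal, staying neutral under
    additive combination.
    """
    diag = np.diag(K.values).copy()
    zero = diag <= 0
    if zero.any():
        logger.info("normalize_kernel: %d genes have zero self-similarity", zero.sum())
    safe = np.where(zero, 1.0, diag)
    scale = 1.0 / np.sqrt(safe)
    values = K.values * np.outer(scale, scale)
    if zero.any():
        values[zero, :] = 0.0
        values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(list(K.genes), values, normalized=True)


def combine_kernels(
    Ks: Sequence[KernelMatrix], weights: Sequence[float] | None = None
) -> KernelMatrix:
    """Entrywise (weighted) sum of kernels over an identical gene list."""
    if not Ks:
        raise ValueError("no kernels to combine")
    genes = Ks[0].genes
    for K in Ks[1:]:
        if K.genes != genes:
            raise ValueError("kernel gene lists do not match")
    if weights is None:
        weights = [1.0] * len(Ks)
    if len(weights) != len(Ks):
        raise ValueError("one weight per kernel required")
    values = sum(w * K.values for w, K in zip(weights, Ks))
    return KernelMatrix(list(genes), values, normalized=False)


def joint_kernel(kx: float, ky: float) -> float:
    """Product joint kernel over an (input, output) pair of evaluations."""
    return kx * ky


# ---------------------------------------------------------------------------
# dense TSV round-trip (12 significant digits)
# ---------------------------------------------------------------------------


def write_kernel(path: str, K: KernelMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(K.genes) + "\n")
        for row in K.values:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


def read_kernel(path: str, normalized: bool = False) -> KernelMatrix:
    with open(path) as fh:
        genes = fh.readline().rstrip("\n").split("\t")
        values = np.array(
            [[float(v) for v in line.rstrip("\n").split("\t")] for line in fh]
        )
    return KernelMatrix(genes, values, normalized=normalized)
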