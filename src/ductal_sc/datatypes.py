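"""Core in-memory containers shared across pipeline stages.

The central object is :class:`CountMatrix`, a genes x barcodes integer UMI
count matrix with per-barcode sample labels.  Downstream stages attach their
results in small dedicated dataclasses rather than mutating the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Genes x barcodes UMI count matrix.

    Attributes
    ----------
    genes : list of str
        Row identifiers.
    barcodes : list of str
        Column identifiers (droplet barcodes).
    X : scipy.sparse.csr_matrix
        Nonnegative integer counts, shape ``(len(genes), len(barcodes))``.
    sample_of : numpy.ndarray of str
        Per-barcode sample label (one anatomical sample per barcode).
    """

    genes: list[str]
    barcodes: list[str]
    X: sp.csr_matrix
    sample_of: np.ndarray

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.sample_of = np.asarray(self.sample_of, dtype=object)
        if self.X.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"count matrix shape {self.X.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(self.sample_of) != len(self.barcodes):
            raise ValueError("sample_of must have one label per barcode")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    def totals(self) -> np.ndarray:
        """Total UMIs per barcode."""
        return np.asarray(self.X.sum(axis=0)).ravel()

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}

    def subset_barcodes(self, keep: list[str] | np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given barcodes (in given order)."""
        idx = self.barcode_index()
        cols = np.array([idx[b] for b in keep], dtype=int)
        return CountMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[c] for c in cols],
            X=self.X[:, cols].tocsr(),
            sample_of=self.sample_of[cols],
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    @staticmethod
    def concat(matrices: list["CountMatrix"]) -> "CountMatrix":
        """Column-concatenate matrices sharing an identical gene list."""
        genes = matrices[0].genes
        for m in matrices[1:]:
            if m.genes != genes:
                raise ValueError("cannot concatenate matrices with different gene lists")
        return CountMatrix(
            genes=list(genes),
            barcodes=[b for m in matrices for b in m.barcodes],
            X=sp.hstack([m.X for m in matrices]).tocsr(),
            sample_of=np.concatenate([m.sample_of for m in matrices]),
        )


@dataclass
class SoupModel:
    """Per-sample ambient-RNA model plus per-cell contamination fractions.

    ``soup_profile[s]`` is a gene-fraction vector (sums to 1) describing the
    ambient transcript pool of sample ``s``; ``modal_empty_umis[s]`` is the
    most frequent total-UMI count among that sample's empty droplets, read as
    a fixed ambient budget of that many UMIs per droplet.  ``rho_per_cell``
    maps each valid cell barcode to min(1, budget / cell total).
    """

    soup_profile: dict[str, np.ndarray]
    modal_empty_umis: dict[str, int]
    rho_per_cell: pd.Series


@dataclass
class ClusterResult:
    """Output of density-peak clustering on a 2-D embedding."""

    rho_density: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    centers: np.ndarray  # indices into the clustered cells
    assignment: np.ndarray  # cluster id per cell, 0..k-1
    embedding2d: np.ndarray
    barcodes: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


@dataclass
class ClusterProfile:
    """Aggregated per-cluster expression in UMIs-per-million (UPM)."""

    upm: pd.DataFrame  # genes x clusters
    n_cells: pd.Series  # per cluster
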