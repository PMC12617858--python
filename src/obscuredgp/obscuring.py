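"""Obscured vectors and the pair-level training dataset.

An obscured vector encodes, for two genotypes A and B, which marker positions
carry the same allele code: bit i is 1 iff A and B agree at marker i. It is
the only genomic information the obscured model ever sees — the raw codes of
the query genotype are never exposed downstream of this module.

The pair dataset enumerates ordered pairs (query, reference) from a set of
individuals; each training row is [obscured(query, ref) ‖ y_ref] with target
y_query. Rows are generated on demand from pair indices so that n² rows over
many thousands of markers never need to exist in memory at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ShapeError


@dataclass(frozen=True)
class ObscuredVector:
    """Binary agreement vector between two genotypes."""

    bits: np.ndarray
    pair: tuple[int, int]

    def __len__(self) -> int:
        return self.bits.shape[0]


def obscured_vector(a: np.ndarray, b: np.ndarray, pair: tuple[int, int] = (-1, -1)) -> ObscuredVector:
    """Positionwise agreement of two genotype rows (exact code equality)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError(f"genotype rows must be 1-D and equal length, got {a.shape} vs {b.shape}")
    return ObscuredVector(bits=(a == b).astype(np.float64), pair=pair)


def obscure_rows(queries: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Agreement bits of many query rows against one reference row."""
    queries = np.atleast_2d(np.asarray(queries))
    if queries.shape[1] != reference.shape[0]:
        raise ShapeError("marker count mismatch between queries and reference")
    return (queries == reference[None, :]).astype(np.float64)


class PairDataset:
    """Ordered (query, reference) pairs over one aligned genotype/phenotype set.

    Attributes
    ----------
    pair_index : ndarray, shape (n_pairs, 2)
        Rows of (query, reference) positions into the underlying set.
    n_features : int
        Active marker count; each materialized design row has length
        ``n_features + 1`` (obscured bits then the reference phenotype).
    """

    def __init__(self, codes: np.ndarray, phenotypes: np.ndarray, pair_index: np.ndarray):
        codes = np.asarray(codes)
        phenotypes = np.asarray(phenotypes, dtype=float)
        if codes.shape[0] != phenotypes.shape[0]:
            raise ShapeError("genotype rows and phenotypes misaligned")
        self.codes = codes
        self.phenotypes = phenotypes
        self.pair_index = np.asarray(pair_index, dtype=np.int64)
        if self.pair_index.ndim != 2 or self.pair_index.shape[1] != 2:
            raise ShapeError("pair_index must be (n_pairs, 2)")

    @property
    def n_pairs(self) -> int:
        return self.pair_index.shape[0]

    @property
    def n_features(self) -> int:
        return self.codes.shape[1]

    def batch(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Materialize design rows for the given pair positions.

        Returns (bits, y_ref, y_query): bits is (len(rows), n_features).
        """
        idx = self.pair_index[rows]
        q, r = idx[:, 0], idx[:, 1]
        bits = (self.codes[q] == self.codes[r]).astype(np.float64)
        return bits, self.phenotypes[r], self.phenotypes[q]

    def materialize(self) -> tuple[np.ndarray, np.ndarray]:
        """Full design matrix [bits ‖ y_ref] and target vector; small sets only."""
        bits, y_ref, y_query = self.batch(np.arange(self.n_pairs))
        design = np.hstack([bits, y_ref[:, None]])
        return design, y_query


def build_pair_dataset(
    codes: np.ndarray,
    phenotypes: np.ndarray,
    include_self: bool = False,
    ordered: bool = True,
) -> PairDataset:
    """Enumerate pairs of individuals into a :class:`PairDataset`.

    Defaults (ordered, no self-pairs) give one row per ordered pair (q, r),
    q ≠ r — n(n−1) rows, both directions of every pair with the phenotype
    roles swapped.
    """
    codes = np.asarray(codes)
    n = codes.shape[0]
    if n < 2 and not include_self:
        raise ParameterError("need at least 2 individuals to form non-self pairs")
    q, r = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    pairs = np.stack([q.ravel(), r.ravel()], axis=1)
    if not include_self:
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    if not ordered:
        pairs = pairs[pairs[:, 0] <= pairs[:, 1]] if include_self else pairs[pairs[:, 0] < pairs[:, 1]]
    if pairs.shape[0] == 0:
        raise ParameterError("no pairs can be formed")
    return PairDataset(codes, phenotypes, pairs)
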