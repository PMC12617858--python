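"""Genotype/phenotype table I/O and trait standardization.

The on-disk dialect is a single CSV with a header row: the first column holds
the individual ID, trait columns are named explicitly at load time, and every
remaining column is a marker with small non-negative integer allele codes
(biallelic dosage 0/1/2 is typical, but any finite discrete alphabet works).

Trait standardization is deliberately split into :func:`zscore_fit` and
:func:`zscore_apply` so that the statistics are always fit on a declared
subset (a training fold) and applied elsewhere; nothing in this module
re-fits silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError, DegenerateTraitError, ShapeError


@dataclass
class GenotypeMatrix:
    """Individuals × markers table of discrete allele codes.

    Parameters
    ----------
    individual_ids : list of str
        Unique row identifiers, in file order.
    marker_ids : list of str
        Unique column identifiers, in file order.
    codes : ndarray of int, shape (n_individuals, n_markers)
        Non-negative allele codes; no missing entries.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ShapeError("codes must be a 2-D matrix")
        n, m = self.codes.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise ShapeError(
                f"ID lists ({len(self.individual_ids)}×{len(self.marker_ids)}) "
                f"do not match codes shape {self.codes.shape}"
            )
        if len(set(self.individual_ids)) != n:
            raise DataFormatError("duplicate individual IDs")
        if len(set(self.marker_ids)) != m:
            raise DataFormatError("duplicate marker IDs")
        if n < 2 or m < 1:
            raise DataFormatError("need at least 2 individuals and 1 marker")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise DataFormatError("allele codes must be integers")
        if (self.codes < 0).any():
            raise DataFormatError("allele codes must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def subset_markers(self, indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            codes=self.codes[:, idx],
        )

    def subset_individuals(self, indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            codes=self.codes[idx, :],
        )


@dataclass
class PhenotypeTable:
    """Trait vectors aligned row-for-row with a :class:`GenotypeMatrix`.

    ``standardization`` maps trait name → (mean, sd) when a trait has been
    z-scored; absence of an entry means the stored values are raw.
    """

    individual_ids: list[str]
    traits: dict[str, np.ndarray]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        for name, vec in self.traits.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise ShapeError(f"trait {name!r} has length {vec.shape}, expected {n}")
            self.traits[name] = vec

    def trait(self, name: str) -> np.ndarray:
        return self.traits[name]


def load_dataset(
    path,
    trait_names: list[str],
    missing_policy: str = "error",
    id_column: str | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Load an aligned genotype matrix and phenotype table from one CSV.

    Parameters
    ----------
    path : str or Path
        CSV with header; first column (or ``id_column``) is the individual ID.
    trait_names : list of str
        Columns to treat as traits; every other non-ID column is a marker.
    missing_policy : {"error", "mode_impute"}
        ``error`` raises on any non-numeric/missing marker cell;
        ``mode_impute`` replaces missing cells with the column mode.

    Row order is preserved from the file.
    """
    if missing_policy not in ("error", "mode_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataFormatError(f"{path}: empty file")
    id_col = id_column if id_column is not None else df.columns[0]
    if id_col not in df.columns:
        raise DataFormatError(f"{path}: ID column {id_col!r} not found")
    for t in trait_names:
        if t not in df.columns:
            raise DataFormatError(f"{path}: trait column {t!r} not found")

    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise DataFormatError(f"{path}: duplicate individual IDs")

    marker_cols = [c for c in df.columns if c != id_col and c not in trait_names]
    if not marker_cols:
        raise DataFormatError(f"{path}: no marker columns")

    raw = df[marker_cols].to_numpy()
    codes = np.empty(raw.shape, dtype=np.int64)
    missing_mask = np.zeros(raw.shape, dtype=bool)
    numeric = pd.DataFrame(raw).apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isfinite(numeric)
    frac = np.nan_to_num(numeric) % 1 != 0
    if missing_policy == "error":
        if bad.any() or frac.any():
            r, c = np.argwhere(bad | frac)[0]
            raise DataFormatError(
                f"{path}: non-integer marker cell at row {ids[r]!r}, "
                f"column {marker_cols[c]!r}"
            )
        codes = numeric.astype(np.int64)
    else:
        if frac.any():
            r, c = np.argwhere(frac)[0]
            raise DataFormatError(
                f"{path}: fractional marker code at row {ids[r]!r}, "
                f"column {marker_cols[c]!r}"
            )
        missing_mask = bad
        codes = np.where(bad, 0, np.nan_to_num(numeric)).astype(np.int64)
        for c in np.unique(np.argwhere(missing_mask)[:, 1]) if missing_mask.any() else []:
            col_missing = missing_mask[:, c]
            observed = codes[~col_missing, c]
            if observed.size == 0:
                raise DataFormatError(
                    f"{path}: column {marker_cols[c]!r} entirely missing"
                )
            counts = np.bincount(observed)
            codes[col_missing, c] = int(np.argmax(counts))  # ties → smallest code

    traits = {}
    for t in trait_names:
        vec = pd.to_numeric(df[t], errors="coerce").to_numpy(dtype=float)
        if not np.isfinite(vec).all():
            r = int(np.argwhere(~np.isfinite(vec))[0])
            raise DataFormatError(f"{path}: non-numeric trait value at row {ids[r]!r} in {t!r}")
        traits[t] = vec

    genos = GenotypeMatrix(ids, marker_cols, codes)
    phenos = PhenotypeTable(ids, traits)
    return genos, phenos


def write_dataset(path, genos: GenotypeMatrix, phenos: PhenotypeTable, id_column: str = "ID") -> None:
    """Write the single-CSV dialect that :func:`load_dataset` reads."""
    if genos.individual_ids != phenos.individual_ids:
        raise ShapeError("genotype and phenotype individual IDs differ")
    df = pd.DataFrame(genos.codes, columns=genos.marker_ids)
    df.insert(0, id_column, genos.individual_ids)
    for name, vec in phenos.traits.items():
        df[name] = [repr(float(v)) for v in vec]  # repr → round-trip precision
    df.to_csv(path, index=False)


def zscore_fit(trait: np.ndarray) -> tuple[float, float]:
    """Sample mean and sd (n−1 denominator) of a trait vector."""
    trait = np.asarray(trait, dtype=float)
    if trait.size < 2:
        raise DegenerateTraitError("need at least 2 values to fit a z-score")
    mean = float(np.mean(trait))
    sd = float(np.std(trait, ddof=1))
    if sd == 0.0:
        raise DegenerateTraitError("constant trait: z-scoring undefined")
    return mean, sd


def zscore_apply(trait: np.ndarray, stats: tuple[float, float]) -> np.ndarray:
    mean, sd = stats
    if sd <= 0:
        raise DegenerateTraitError("sd must be positive")
    return (np.asarray(trait, dtype=float) - mean) / sd


def zscore_invert(z: np.ndarray, stats: tuple[float, float]) -> np.ndarray:
    mean, sd = stats
    return np.asarray(z, dtype=float) * sd + mean
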