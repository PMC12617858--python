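"""Marker-density reduction: sliding-window redundancy removal,
mutual-information ranking against the trait, and random selection.

The window dedup scans markers left to right and drops a column when an
identical column survives within the previous ``w`` positions. Comparisons
are against *survivors*, so eliminated columns do not shield later ones —
this makes the operation idempotent, which the density-stability behaviour
around w = 8 relies on.

Mutual information uses a fully deterministic plug-in estimator: the trait is
discretized into equal-frequency bins, markers are already discrete, and MI
is the double sum over the empirical joint histogram. Ranking ties break
toward the lower original marker index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import GenotypeMatrix
from .errors import ParameterError


@dataclass
class SelectionResult:
    """Outcome of a marker-selection step, replayable from its params."""

    kept_indices: np.ndarray
    method: str  # window_dedup | mutual_info | random
    scores: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kept_indices = np.asarray(self.kept_indices, dtype=np.int64)
        if self.kept_indices.size:
            assert np.all(np.diff(self.kept_indices) > 0), "kept_indices must be sorted unique"

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "params": self.params,
                "kept_indices": self.kept_indices.tolist(),
                "scores": None if self.scores is None else np.asarray(self.scores).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        d = json.loads(text)
        return cls(
            kept_indices=np.asarray(d["kept_indices"], dtype=np.int64),
            method=d["method"],
            scores=None if d["scores"] is None else np.asarray(d["scores"]),
            params=d["params"],
        )


def _columns(genos) -> np.ndarray:
    return genos.codes if isinstance(genos, GenotypeMatrix) else np.asarray(genos)


def window_dedup(genos, w: int) -> SelectionResult:
    """Remove markers identical to a surviving marker within the previous w positions."""
    if w < 1:
        raise ParameterError("window w must be ≥ 1")
    codes = _columns(genos)
    m = codes.shape[1]
    # hash columns first so full comparisons happen only on hash collisions
    hashes = np.array([hash(codes[:, j].tobytes()) for j in range(m)])
    survivors: list[int] = []
    kept = np.zeros(m, dtype=bool)
    for j in range(m):
        duplicate = False
        for i in reversed(survivors):
            if i < j - w:
                break
            if hashes[i] == hashes[j] and np.array_equal(codes[:, i], codes[:, j]):
                duplicate = True
                break
        if not duplicate:
            survivors.append(j)
            kept[j] = True
    return SelectionResult(np.flatnonzero(kept), "window_dedup", params={"w": int(w)})


def count_redundant_pairs(genos, w: int) -> int:
    """Number of identical column pairs (i, j) with i < j ≤ i + w."""
    if w < 1:
        raise ParameterError("window w must be ≥ 1")
    codes = _columns(genos)
    m = codes.shape[1]
    hashes = np.array([hash(codes[:, j].tobytes()) for j in range(m)])
    count = 0
    for i in range(m):
        for j in range(i + 1, min(i + w, m - 1) + 1):
            if hashes[i] == hashes[j] and np.array_equal(codes[:, i], codes[:, j]):
                count += 1
    return count


def _equal_frequency_bins(trait: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value a bin label 0..bins-1 with near-equal occupancy.

    Ranks (stable for ties via argsort of argsort) are mapped proportionally;
    deterministic for a fixed input order.
    """
    n = trait.shape[0]
    order = np.argsort(trait, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * bins) // n


def _plugin_mi(x: np.ndarray, y_bins: np.ndarray, n_bins: int) -> float:
    """Plug-in MI (nats) between a discrete vector and binned labels."""
    xv, x_inv = np.unique(x, return_inverse=True)
    joint = np.zeros((xv.size, n_bins))
    np.add.at(joint, (x_inv, y_bins), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def mi_rank(genos, trait: np.ndarray, k: int, bins: int = 10) -> SelectionResult:
    """Top-k markers by plug-in mutual information with the binned trait."""
    if k < 1:
        raise ParameterError("k must be ≥ 1")
    codes = _columns(genos)
    trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != codes.shape[0]:
        raise ParameterError("trait not aligned with genotype rows")
    m = codes.shape[1]
    if k > m:
        warnings.warn(f"k={k} exceeds {m} markers; clipping", stacklevel=2)
        k = m
    y_bins = _equal_frequency_bins(trait, bins)
    scores = np.array([_plugin_mi(codes[:, j], y_bins, bins) for j in range(m)])
    # stable sort on (-score, index): ties go to the lower original index
    order = np.lexsort((np.arange(m), -scores))
    kept = np.sort(order[:k])
    return SelectionResult(kept, "mutual_info", scores=scores, params={"k": int(k), "bins": int(bins)})


def random_select(n_markers: int, k: int, seed: int) -> SelectionResult:
    """Uniform sample of k marker indices without replacement."""
    if not 1 <= k <= n_markers:
        raise ParameterError(f"k={k} out of range [1, {n_markers}]")
    rng = np.random.default_rng(seed)
    kept = np.sort(rng.choice(n_markers, size=k, replace=False))
    return SelectionResult(kept, "random", params={"k": int(k), "seed": int(seed)})
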