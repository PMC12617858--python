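"""Synthetic genotype/phenotype generator.

Emulates the structure a genomic-prediction panel presents to this toolkit:
a few hundred lines genotyped at 10³–10⁴ biallelic markers coded {0,1,2},
local linkage-disequilibrium (LD) blocks, a share of exactly duplicated
marker columns (to exercise the redundancy filter), and a standardizable
additive polygenic trait with controllable heritability.

LD is produced by block copying rather than coalescent simulation: each
block has a template dosage column drawn Binomial(2, p) with p uniform over
``allele_freq_range``, and the other block members copy the template
entrywise, redrawing an entry from Binomial(2, p) with probability
``within_block_flip_prob``. Adjacent markers within a block are therefore
correlated, markers across blocks are independent. Exact duplicates are then
planted by overwriting a chosen fraction of columns with a copy of a column
at most eight positions to their left. The trait is g + e with g = Σ βⱼ zⱼ
over ``n_qtl`` causal markers (effects ~ N(0,1)) and e scaled so that
var(g)/var(g+e) hits the target heritability on the realized g. The trait is
returned raw; standardization belongs to fold-scoped downstream code.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .data_io import GenotypeMatrix, PhenotypeTable
from .errors import ParameterError
from .feature_select import SelectionResult

DUPLICATE_MAX_DISTANCE = 8  # duplicates land within the default dedup window


@dataclass
class SimConfig:
    """Generator settings; defaults are the package's standard study conditions."""

    n_individuals: int = 300
    n_markers: int = 1000
    block_size: int = 10
    within_block_flip_prob: float = 0.1
    n_qtl: int = 20
    heritability: float = 0.6
    duplicate_frac: float = 0.05
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ParameterError("n_qtl cannot exceed n_markers")
        if not 0.0 < self.heritability < 1.0:
            raise ParameterError("heritability must be in (0, 1)")
        if not 0.0 <= self.duplicate_frac < 1.0:
            raise ParameterError("duplicate_frac must be in [0, 1)")
        if self.block_size > self.n_markers:
            raise ParameterError("block_size cannot exceed n_markers")
        if self.n_individuals < 2:
            raise ParameterError("need at least 2 individuals")


@dataclass
class TruthRecord:
    """Ground truth of one simulation, for selection-recall scoring."""

    causal_indices: np.ndarray
    effects: np.ndarray
    realized_heritability: float
    duplicate_map: dict[int, int]  # duplicated column → source column
    config: SimConfig


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Draw one dataset; bit-identical for identical configs (seed included)."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers

    codes = np.empty((n, m), dtype=np.int64)
    freqs = np.empty(m)
    lo, hi = config.allele_freq_range
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        p = rng.uniform(lo, hi)
        template = rng.binomial(2, p, size=n)
        codes[:, start] = template
        freqs[start:stop] = p
        for j in range(start + 1, stop):
            col = template.copy()
            flip = rng.random(n) < config.within_block_flip_prob
            col[flip] = rng.binomial(2, p, size=int(flip.sum()))
            codes[:, j] = col

    n_dup = int(round(config.duplicate_frac * m))
    duplicate_map: dict[int, int] = {}
    if n_dup > 0:
        candidates = rng.choice(np.arange(1, m), size=n_dup, replace=False)
        for j in sorted(candidates):
            d = int(rng.integers(1, min(DUPLICATE_MAX_DISTANCE, j) + 1))
            codes[:, j] = codes[:, j - d]
            duplicate_map[int(j)] = int(j - d)

    causal = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    effects = rng.normal(0.0, 1.0, size=config.n_qtl)
    g = codes[:, causal].astype(float) @ effects
    var_g = float(np.var(g))
    if var_g == 0.0:
        raise ParameterError("degenerate simulation: genetic value has zero variance")
    var_e = var_g * (1.0 - config.heritability) / config.heritability
    e = rng.normal(0.0, np.sqrt(var_e), size=n)
    trait = g + e
    realized_h2 = float(np.var(g) / np.var(trait))

    ids = [f"G{i:04d}" for i in range(n)]
    marker_ids = [f"M{j:05d}" for j in range(m)]
    genos = GenotypeMatrix(ids, marker_ids, codes)
    phenos = PhenotypeTable(ids, {"trait": trait})
    truth = TruthRecord(
        causal_indices=causal,
        effects=effects,
        realized_heritability=realized_h2,
        duplicate_map=duplicate_map,
        config=config,
    )
    return genos, phenos, truth


def truth_eval(selection: SelectionResult, truth: TruthRecord) -> float:
    """Recall of causal markers; a duplicate of a causal column counts as a hit.

    Duplicate chains are followed: if j copies i and i copies h, selecting j
    recovers a causal h.
    """

    def resolve(j: int) -> int:
        seen = set()
        while j in truth.duplicate_map and j not in seen:
            seen.add(j)
            j = truth.duplicate_map[j]
        return j

    causal = set(int(c) for c in truth.causal_indices)
    # any column whose resolved source is causal, plus causal columns themselves
    hits = set()
    for j in selection.kept_indices:
        j = int(j)
        if j in causal or resolve(j) in causal:
            hits.add(resolve(j) if j not in causal else j)
    return len(hits) / len(causal)


def truth_to_json(truth: TruthRecord) -> dict:
    d = {
        "causal_indices": truth.causal_indices.tolist(),
        "effects": truth.effects.tolist(),
        "realized_heritability": truth.realized_heritability,
        "duplicate_map": {str(k): v for k, v in truth.duplicate_map.items()},
        "config": asdict(truth.config),
    }
    return d
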