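"""The obscured ensemble predictor.

A query genotype is compared against each *reference instance* — a
(genotype, phenotype) pair held fixed inside the model, drawn from the
training fold — and the base model's pair predictions are averaged into the
final prediction. The base model is trained once on the whole training fold;
choosing a reference subset is purely an inference-time decision, so sweeps
over reference fractions never retrain.

Two subset strategies are provided: uniform random sampling, and targeted
selection of the candidates whose predictions have the lowest mean squared
error across the rest of the training fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .obscured_net import ObscuredNet
from .obscuring import obscure_rows


def reference_set_size(train_size: int, fraction: float) -> int:
    """Round half away from zero, floored at one reference."""
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, int(np.floor(fraction * train_size + 0.5)))


@dataclass
class ReferenceSet:
    """Training-fold instances an ensemble prediction averages over."""

    indices: np.ndarray
    genotypes: np.ndarray  # rows restricted to kept features, aligned to indices
    phenotypes: np.ndarray  # standardized trait values, aligned to indices
    strategy: str  # all | random | targeted
    fraction: float = 1.0
    seed: int | None = None
    mse_scores: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size == 0:
            raise ParameterError("reference set cannot be empty")
        if np.unique(self.indices).size != self.indices.size:
            raise ParameterError("reference indices must be unique")

    def __len__(self) -> int:
        return self.indices.size

    def to_json(self) -> str:
        return json.dumps(
            {
                "strategy": self.strategy,
                "fraction": self.fraction,
                "seed": self.seed,
                "indices": self.indices.tolist(),
                "mse_scores": None if self.mse_scores is None else np.asarray(self.mse_scores).tolist(),
            }
        )


def select_references_random(train_size: int, fraction: float, seed: int) -> np.ndarray:
    """Uniform sample (without replacement) of reference positions."""
    if train_size < 1:
        raise ParameterError("train_size must be ≥ 1")
    size = reference_set_size(train_size, fraction)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(train_size, size=size, replace=False))


def reference_mse_profile(
    model: ObscuredNet, train_codes: np.ndarray, train_phenos: np.ndarray
) -> np.ndarray:
    """Per-candidate mean MSE of predicting every *other* training instance.

    Entry j is the mean over i ≠ j of
    (predict(obscured(g_i, g_j), y_j) − y_i)²; the self term is excluded.
    """
    train_codes = np.asarray(train_codes)
    y = np.asarray(train_phenos, dtype=float)
    n = train_codes.shape[0]
    if n < 2:
        raise ParameterError("MSE profile undefined for a training fold of size 1")
    profile = np.empty(n)
    for j in range(n):
        bits = obscure_rows(train_codes, train_codes[j])
        preds = model.predict_batch(bits, np.full(n, y[j]))
        sq = (preds - y) ** 2
        profile[j] = (sq.sum() - sq[j]) / (n - 1)
    return profile


def select_references_targeted(mse_profile: np.ndarray, fraction: float) -> np.ndarray:
    """Positions of the lowest-MSE candidates; ties break to the lower index."""
    profile = np.asarray(mse_profile, dtype=float)
    if not np.isfinite(profile).all():
        raise ParameterError("MSE profile contains non-finite values")
    size = reference_set_size(profile.size, fraction)
    order = np.lexsort((np.arange(profile.size), profile))  # stable in profile, then index
    return np.sort(order[:size])


def build_reference_set(
    train_codes: np.ndarray,
    train_phenos: np.ndarray,
    strategy: str = "all",
    fraction: float = 1.0,
    seed: int | None = None,
    model: ObscuredNet | None = None,
    mse_profile: np.ndarray | None = None,
) -> ReferenceSet:
    """Assemble a :class:`ReferenceSet` under the requested strategy."""
    train_codes = np.asarray(train_codes)
    y = np.asarray(train_phenos, dtype=float)
    n = train_codes.shape[0]
    scores = None
    if strategy == "all":
        idx = np.arange(n)
        fraction = 1.0
    elif strategy == "random":
        if seed is None:
            raise ParameterError("random strategy requires a seed")
        idx = select_references_random(n, fraction, seed)
    elif strategy == "targeted":
        if mse_profile is None:
            if model is None:
                raise ParameterError("targeted strategy requires a model or a precomputed profile")
            mse_profile = reference_mse_profile(model, train_codes, y)
        idx = select_references_targeted(mse_profile, fraction)
        scores = np.asarray(mse_profile)
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")
    return ReferenceSet(
        indices=idx,
        genotypes=train_codes[idx],
        phenotypes=y[idx],
        strategy=strategy,
        fraction=fraction,
        seed=seed,
        mse_scores=scores,
    )


def ensemble_predict(model: ObscuredNet, refs: ReferenceSet, query_genotype: np.ndarray) -> float:
    """Mean of the base model's pair predictions over all references."""
    preds = ensemble_pair_predictions(model, refs, query_genotype)
    return float(np.mean(preds))


def ensemble_pair_predictions(
    model: ObscuredNet, refs: ReferenceSet, query_genotype: np.ndarray
) -> np.ndarray:
    """Individual pair predictions (one per reference) for a single query."""
    query = np.asarray(query_genotype)
    if query.shape[0] != refs.genotypes.shape[1]:
        raise ParameterError(
            f"query has {query.shape[0]} features, references have {refs.genotypes.shape[1]}"
        )
    bits = (refs.genotypes == query[None, :]).astype(np.float64)
    return model.predict_batch(bits, refs.phenotypes)


def ensemble_predict_many(
    model: ObscuredNet, refs: ReferenceSet, queries: np.ndarray
) -> np.ndarray:
    """Ensemble predictions for several query genotypes at once."""
    queries = np.atleast_2d(np.asarray(queries))
    out = np.empty(queries.shape[0])
    for i, q in enumerate(queries):
        out[i] = ensemble_predict(model, refs, q)
    return out


class ObscuredEnsembleModel:
    """fit/predict wrapper bundling base-model training and ensembling.

    ``fit`` trains the base network once on all ordered pairs of the
    training set and freezes the reference instances under the configured
    strategy; ``predict`` averages pair predictions per query.
    """

    def __init__(
        self,
        strategy: str = "all",
        fraction: float = 1.0,
        seed: int = 0,
        net_config: dict | None = None,
    ):
        self.strategy = strategy
        self.fraction = fraction
        self.seed = seed
        self.net_config = dict(net_config or {})
        self.model: ObscuredNet | None = None
        self.refs: ReferenceSet | None = None

    def fit(self, codes: np.ndarray, trait: np.ndarray) -> "ObscuredEnsembleModel":
        from .obscured_net import NetConfig
        from .obscuring import build_pair_dataset

        codes = np.asarray(codes)
        cfg = NetConfig(n_features=codes.shape[1], seed=self.seed, **self.net_config)
        self.model = ObscuredNet(cfg).train(build_pair_dataset(codes, trait))
        self.refs = build_reference_set(
            codes, trait, strategy=self.strategy, fraction=self.fraction,
            seed=self.seed, model=self.model,
        )
        return self

    def predict(self, codes: np.ndarray) -> np.ndarray:
        assert self.model is not None and self.refs is not None, "fit before predict"
        return ensemble_predict_many(self.model, self.refs, codes)
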