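"""Cross-validation harness, metrics, and the experiment sweeps.

Every model is evaluated under one shared fold plan so comparisons are
paired, and every report row carries *both* Pearson correlation and MSE —
the harness cannot emit one without the other, because a strong correlation
with compressed, near-constant predictions is exactly the failure mode the
dual-metric reporting exists to expose. When a model's held-out predictions
are constant, the PCC cell is flagged undefined rather than silently zeroed.

All trait standardization and feature scoring is fit on the training fold
only and applied to the held-out fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import GenotypeMatrix, PhenotypeTable, zscore_apply, zscore_fit
from .ensemble import build_reference_set, ensemble_predict_many, reference_mse_profile
from .errors import ParameterError, ShapeError, UndefinedCorrelationError
from .feature_select import SelectionResult, mi_rank, window_dedup
from .obscured_net import NetConfig, ObscuredNet
from .obscuring import build_pair_dataset, obscure_rows


def pcc(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ShapeError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size < 2:
        raise ParameterError("need at least 2 points for a correlation")
    if np.ptp(a) == 0 or np.ptp(p) == 0:  # constant ⇔ max == min, robust to fp mean error
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return float(sps.pearsonr(a, p).statistic)


def mse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared difference between actual and predicted values."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ShapeError(f"length mismatch: {a.shape} vs {p.shape}")
    return float(np.mean((a - p) ** 2))


@dataclass
class FoldPlan:
    """Partition of individuals into k folds, reusable across all models."""

    k: int
    assignments: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(list(self.assignments.values()), minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ParameterError("fold sizes must differ by at most 1")

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]

    def split(self, individual_ids: list[str], fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train positions, test positions) into ``individual_ids`` order."""
        labels = np.array([self.assignments[i] for i in individual_ids])
        return np.flatnonzero(labels != fold), np.flatnonzero(labels == fold)

    def to_json(self) -> str:
        return json.dumps({"k": self.k, "seed": self.seed, "assignments": self.assignments})

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(k=d["k"], assignments=d["assignments"], seed=d["seed"])


def make_folds(individual_ids: list[str], k: int, seed: int) -> FoldPlan:
    """Seeded shuffle then round-robin assignment into k balanced folds."""
    n = len(individual_ids)
    if k > n:
        raise ParameterError(f"k={k} exceeds {n} individuals")
    if k < 2:
        raise ParameterError("k must be ≥ 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = {individual_ids[idx]: int(pos % k) for pos, idx in enumerate(order)}
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class EvalReport:
    """Tidy per-(model, fold) metrics plus the raw prediction table."""

    metrics: pd.DataFrame
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for col in ("pcc", "mse"):
            if len(self.metrics) and col not in self.metrics.columns:
                raise ParameterError(f"report must carry both metrics; {col!r} missing")


def prepare_fold(
    genos: GenotypeMatrix,
    phenos: PhenotypeTable,
    trait: str,
    train_idx: np.ndarray,
    dedup_w: int | None = None,
    mi_k: int | None = None,
    mi_bins: int = 10,
):
    """Training-fold-only artifacts: z-score stats and the marker selection.

    Nothing here reads held-out rows or phenotypes, which is what makes the
    harness leakage-free by construction.
    """
    y_train_raw = phenos.trait(trait)[train_idx]
    stats = zscore_fit(y_train_raw)
    kept = np.arange(genos.n_markers)
    selection: SelectionResult | None = None
    if dedup_w is not None:
        selection = window_dedup(genos.codes[train_idx], dedup_w)
        kept = selection.kept_indices
    if mi_k is not None:
        k = mi_k
        if k > kept.size:
            warnings.warn(f"requested {k} features but only {kept.size} survive; clipping", stacklevel=2)
            k = kept.size
        mi = mi_rank(genos.codes[np.ix_(train_idx, kept)], zscore_apply(y_train_raw, stats), k, bins=mi_bins)
        selection = SelectionResult(
            kept_indices=kept[mi.kept_indices],
            method="mutual_info",
            scores=mi.scores,
            params={**mi.params, "dedup_w": dedup_w},
        )
        kept = selection.kept_indices
    return stats, kept, selection


def run_cv(
    models: dict,
    genos: GenotypeMatrix,
    phenos: PhenotypeTable,
    trait: str,
    fold_plan: FoldPlan,
    dedup_w: int | None = None,
    mi_k: int | None = None,
    mi_bins: int = 10,
) -> EvalReport:
    """Evaluate every model factory under the shared fold plan.

    ``models`` maps name → zero-argument factory returning an object with
    ``fit(codes, y)`` and ``predict(codes)`` on the standardized trait scale.
    A model failing on a fold is recorded (error column) without disturbing
    the other models.
    """
    rows = []
    preds_rows = []
    ids = genos.individual_ids
    for fold in range(fold_plan.k):
        train_idx, test_idx = fold_plan.split(ids, fold)
        stats, kept, _ = prepare_fold(genos, phenos, trait, train_idx, dedup_w, mi_k, mi_bins)
        y_all = phenos.trait(trait)
        y_train = zscore_apply(y_all[train_idx], stats)
        y_test = zscore_apply(y_all[test_idx], stats)
        Xtr = genos.codes[np.ix_(train_idx, kept)]
        Xte = genos.codes[np.ix_(test_idx, kept)]
        for name, factory in models.items():
            row = {"model": name, "fold": fold, "pcc": np.nan, "mse": np.nan,
                   "pcc_defined": True, "error": None, "n_features": kept.size}
            try:
                model = factory()
                model.fit(Xtr, y_train)
                preds = np.asarray(model.predict(Xte), dtype=float)
                row["mse"] = mse(y_test, preds)
                try:
                    row["pcc"] = pcc(y_test, preds)
                except UndefinedCorrelationError:
                    row["pcc_defined"] = False
                for i, pos in enumerate(test_idx):
                    preds_rows.append(
                        {"model": name, "fold": fold, "individual": ids[pos],
                         "actual": y_test[i], "predicted": preds[i]}
                    )
            except Exception as exc:  # isolate per-model failures
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return EvalReport(metrics=pd.DataFrame(rows), predictions=pd.DataFrame(preds_rows))


def sweep_feature_counts(
    counts: list[int],
    models: dict,
    genos: GenotypeMatrix,
    phenos: PhenotypeTable,
    trait: str,
    fold_plan: FoldPlan,
    dedup_w: int | None = 8,
    mi_bins: int = 10,
) -> EvalReport:
    """Re-run the CV harness at each feature count (fold-scoped MI selection)."""
    frames = []
    preds = []
    for count in counts:
        rep = run_cv(models, genos, phenos, trait, fold_plan,
                     dedup_w=dedup_w, mi_k=int(count), mi_bins=mi_bins)
        m = rep.metrics.copy()
        m["requested_features"] = count
        frames.append(m)
        p = rep.predictions.copy()
        p["requested_features"] = count
        preds.append(p)
    return EvalReport(metrics=pd.concat(frames, ignore_index=True),
                      predictions=pd.concat(preds, ignore_index=True))


def sweep_reference_fractions(
    fractions: list[float],
    strategies: list[str],
    seeds: list[int],
    genos: GenotypeMatrix,
    phenos: PhenotypeTable,
    trait: str,
    fold_plan: FoldPlan,
    net_config: dict | None = None,
    dedup_w: int | None = None,
    mi_k: int | None = None,
    folds: list[int] | None = None,
) -> EvalReport:
    """Evaluate the ensemble across reference fractions and strategies.

    The base network is trained once per fold; fractions and strategies are
    inference-time choices only (the targeted MSE profile is likewise
    computed once per fold and re-thresholded).
    """
    rows = []
    ids = genos.individual_ids
    net_config = dict(net_config or {})
    for fold in folds if folds is not None else range(fold_plan.k):
        train_idx, test_idx = fold_plan.split(ids, fold)
        stats, kept, _ = prepare_fold(genos, phenos, trait, train_idx, dedup_w, mi_k)
        y_all = phenos.trait(trait)
        y_train = zscore_apply(y_all[train_idx], stats)
        y_test = zscore_apply(y_all[test_idx], stats)
        Xtr = genos.codes[np.ix_(train_idx, kept)]
        Xte = genos.codes[np.ix_(test_idx, kept)]
        cfg = NetConfig(n_features=kept.size, **net_config)
        model = ObscuredNet(cfg).train(build_pair_dataset(Xtr, y_train))
        profile = (
            reference_mse_profile(model, Xtr, y_train) if "targeted" in strategies else None
        )
        for fraction in fractions:
            for strategy in strategies:
                for seed in seeds:
                    refs = build_reference_set(
                        Xtr, y_train, strategy=strategy, fraction=fraction,
                        seed=seed, mse_profile=profile,
                    )
                    preds = ensemble_predict_many(model, refs, Xte)
                    row = {"model": "obscured_ensemble", "fold": fold,
                           "fraction": fraction, "strategy": strategy, "seed": seed,
                           "n_references": len(refs), "mse": mse(y_test, preds),
                           "pcc": np.nan, "pcc_defined": True}
                    try:
                        row["pcc"] = pcc(y_test, preds)
                    except UndefinedCorrelationError:
                        row["pcc_defined"] = False
                    rows.append(row)
    return EvalReport(metrics=pd.DataFrame(rows))


def mse_heatmap(
    model: ObscuredNet,
    train_codes: np.ndarray,
    train_phenos: np.ndarray,
    test_codes: np.ndarray,
    test_phenos: np.ndarray,
) -> np.ndarray:
    """Squared-error matrix, rows = training (reference) instances, columns = test.

    Entry (j, t) is the squared error of predicting test instance t from
    reference j alone: (predict(obscured(g_t, g_j), y_j) − y_t)².
    """
    train_codes = np.asarray(train_codes)
    test_codes = np.asarray(test_codes)
    y_train = np.asarray(train_phenos, dtype=float)
    y_test = np.asarray(test_phenos, dtype=float)
    H = np.empty((train_codes.shape[0], test_codes.shape[0]))
    for j in range(train_codes.shape[0]):
        bits = obscure_rows(test_codes, train_codes[j])
        preds = model.predict_batch(bits, np.full(test_codes.shape[0], y_train[j]))
        H[j, :] = (preds - y_test) ** 2
    return H


def dual_metric_experiment(
    genos: GenotypeMatrix,
    phenos: PhenotypeTable,
    trait: str,
    marker_counts: list[int],
    seeds: list[int],
    dedup_w: int = 8,
    k_folds: int = 3,
    net_config: dict | None = None,
) -> pd.DataFrame:
    """Held-out PCC/MSE of the full-reference ensemble at several marker counts.

    For each seed a fresh fold plan is drawn and the first held-out fold is
    evaluated; per-count means across seeds summarize the run. The paired
    metrics at a small and a large marker count show the compressed-
    prediction failure a correlation alone hides.
    """
    rows = []
    ids = genos.individual_ids
    net_config = dict(net_config or {})
    for count in marker_counts:
        for seed in seeds:
            plan = make_folds(ids, k_folds, seed)
            train_idx, test_idx = plan.split(ids, 0)
            stats, kept, _ = prepare_fold(genos, phenos, trait, train_idx, dedup_w, count)
            y_all = phenos.trait(trait)
            y_train = zscore_apply(y_all[train_idx], stats)
            y_test = zscore_apply(y_all[test_idx], stats)
            Xtr = genos.codes[np.ix_(train_idx, kept)]
            Xte = genos.codes[np.ix_(test_idx, kept)]
            cfg = NetConfig(n_features=kept.size, seed=seed, **net_config)
            model = ObscuredNet(cfg).train(build_pair_dataset(Xtr, y_train))
            refs = build_reference_set(Xtr, y_train, strategy="all")
            preds = ensemble_predict_many(model, refs, Xte)
            try:
                r = pcc(y_test, preds)
            except UndefinedCorrelationError:
                r = np.nan
            rows.append({"marker_count": count, "seed": seed, "pcc": r,
                         "mse": mse(y_test, preds),
                         "prediction_sd": float(np.std(preds))})
    return pd.DataFrame(rows)
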