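"""Comparison predictors: ridge regression and GBLUP in closed form, plus a
thin Random Forest wrapper.

GBLUP is solved in genomic-relationship-matrix (GRM) form with a fixed
variance ratio λ standing in for σ²_e/σ²_g rather than a REML estimate: the
harness needs a deterministic, closed-form comparator, and the GRM-form
ridge is algebraically equivalent to ridge regression on centered markers
(the standard kernel/primal duality), which the tests exploit as an oracle.

The GRM follows VanRaden method 1: Z is the dosage matrix centered by twice
the allele frequency and G = ZZᵀ / (2Σ p_j(1−p_j)). Frequencies are always
taken from a declared (training) set so test individuals never leak into the
centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass
class GRM:
    """Genomic relationship matrix plus the allele frequencies that centered it."""

    matrix: np.ndarray
    allele_freqs: np.ndarray


@dataclass
class RidgeModel:
    beta: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta + self.intercept


def ridge_fit(genos: np.ndarray, trait: np.ndarray, lam: float) -> RidgeModel:
    """Closed-form ridge: minimize ||y − Xβ − b||² + λ||β||².

    The intercept is unpenalized (fit as the training mean of y on centered X).
    """
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    X = np.asarray(genos, dtype=float)
    y = np.asarray(trait, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    beta = np.linalg.solve(A, Xc.T @ yc)
    intercept = float(y_mean - x_mean @ beta)
    return RidgeModel(beta=beta, intercept=intercept)


def allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """Per-marker allele frequency p_j from 0/1/2 dosages: mean(dosage)/2."""
    codes = np.asarray(codes, dtype=float)
    if codes.min() < 0 or codes.max() > 2:
        raise ParameterError("VanRaden GRM requires dosage codes in {0, 1, 2}")
    return codes.mean(axis=0) / 2.0


def grm_vanraden(codes: np.ndarray, freqs: np.ndarray | str = "estimate") -> GRM:
    """VanRaden method-1 GRM: G = ZZᵀ / (2 Σ p_j(1−p_j))."""
    codes = np.asarray(codes, dtype=float)
    if isinstance(freqs, str):
        if freqs != "estimate":
            raise ParameterError(f"unknown freqs mode {freqs!r}")
        p = allele_frequencies(codes)
    else:
        p = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0.0:
        raise ParameterError("all markers monomorphic: GRM denominator is zero")
    Z = codes - 2.0 * p[None, :]
    return GRM(matrix=(Z @ Z.T) / denom, allele_freqs=p)


def gblup_predict(
    G: GRM | np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    train_trait: np.ndarray,
    lambda_ratio: float,
) -> np.ndarray:
    """GRM-form mixed-model ridge prediction for the test individuals.

    û_test = G[test, train] (G[train, train] + λI)⁻¹ (y_train − ȳ); the
    prediction adds back the training mean as the fixed intercept.
    """
    if lambda_ratio <= 0:
        raise ParameterError("lambda_ratio must be positive")
    Gm = G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    y = np.asarray(train_trait, dtype=float)
    y_mean = y.mean()
    Gtt = Gm[np.ix_(train_idx, train_idx)]
    alpha = np.linalg.solve(Gtt + lambda_ratio * np.eye(train_idx.size), y - y_mean)
    return Gm[np.ix_(test_idx, train_idx)] @ alpha + y_mean


class GBLUPModel:
    """fit/predict wrapper: training-fold allele frequencies, fixed λ."""

    def __init__(self, lambda_ratio: float = 1.0):
        self.lambda_ratio = lambda_ratio
        self._train_codes: np.ndarray | None = None
        self._y: np.ndarray | None = None
        self._freqs: np.ndarray | None = None

    def fit(self, genos: np.ndarray, trait: np.ndarray) -> "GBLUPModel":
        self._train_codes = np.asarray(genos, dtype=float)
        self._y = np.asarray(trait, dtype=float)
        self._freqs = allele_frequencies(self._train_codes)
        return self

    def predict(self, genos: np.ndarray) -> np.ndarray:
        assert self._train_codes is not None, "fit before predict"
        all_codes = np.vstack([self._train_codes, np.asarray(genos, dtype=float)])
        G = grm_vanraden(all_codes, freqs=self._freqs)
        n_train = self._train_codes.shape[0]
        train_idx = np.arange(n_train)
        test_idx = np.arange(n_train, all_codes.shape[0])
        return gblup_predict(G, train_idx, test_idx, self._y, self.lambda_ratio)


class RandomForestModel:
    """Thin wrapper around scikit-learn's RandomForestRegressor."""

    def __init__(self, n_estimators: int = 100, seed: int = 0):
        from sklearn.ensemble import RandomForestRegressor

        self._rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)

    def fit(self, genos, trait):
        self._rf.fit(np.asarray(genos, dtype=float), np.asarray(trait, dtype=float))
        return self

    def predict(self, genos):
        return self._rf.predict(np.asarray(genos, dtype=float))
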