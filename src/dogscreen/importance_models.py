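"""Parameter-importance models: repeated random-forest regression and per-DOG PLS.

Two complementary views of how much topography (wrinkle wavelength, um),
stiffness (DMT modulus, MPa) and wettability (water contact angle, deg)
contribute to each cell response:

* :func:`fit_rf_repeated` -- the fused screen table is split 75/25 train/test
  ``n_repeats`` times; inside each training portion a k-fold cross-validation
  picks a random-forest hyperparameter setting, the model is refit on the
  full training portion, and R^2, MAE and normalised impurity importances are
  recorded on the held-out quarter.  Aggregates are mean +/- sd over repeats.
* :func:`fit_pls_dog` -- per DOG, a PLS2 regression of the three responses on
  the three SD-scaled surface parameters (zero-SD fixed parameters get unit
  scale so they enter with zero variance), with the number of components
  chosen by leave-one-out cross-validation.  Variable importance per response
  is the signed standardised coefficient normalised so absolute values sum to
  100%; the sign encodes the correlation direction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split

__all__ = [
    "FEATURES",
    "RFProtocol",
    "RFResult",
    "PLSResult",
    "fit_rf_repeated",
    "fit_pls_dog",
    "variable_importance",
]

FEATURES = ("wavelength_um", "stiffness_mpa", "wca_deg")


@dataclass(frozen=True)
class RFProtocol:
    """Protocol for the repeated random-forest regression."""

    features: tuple[str, ...] = FEATURES
    target: str = "median_ctcf_asma"
    n_repeats: int = 100
    test_fraction: float = 0.25
    cv_folds: int = 10
    n_estimators: int = 100
    param_grid: dict = field(default_factory=lambda: {"min_samples_leaf": [1, 4]})
    importance: str = "impurity"  # "impurity" | "permutation"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_repeats < 1 or self.cv_folds < 2:
            raise ValueError("need n_repeats >= 1 and cv_folds >= 2")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")


@dataclass(frozen=True)
class RFResult:
    """Per-repeat held-out metrics and normalised feature importances."""

    protocol: RFProtocol
    r2: np.ndarray  # (n_repeats,)
    mae: np.ndarray
    importances: np.ndarray  # (n_repeats, n_features), each row sums to 1

    @property
    def r2_mean(self) -> float:
        return float(self.r2.mean())

    @property
    def r2_sd(self) -> float:
        return float(self.r2.std(ddof=1)) if self.r2.size > 1 else 0.0

    @property
    def mae_mean(self) -> float:
        return float(self.mae.mean())

    @property
    def mae_sd(self) -> float:
        return float(self.mae.std(ddof=1)) if self.mae.size > 1 else 0.0

    @property
    def importance_mean(self) -> dict:
        return dict(zip(self.protocol.features, self.importances.mean(axis=0)))

    @property
    def importance_sd(self) -> dict:
        sd = self.importances.std(ddof=1, axis=0) if len(self.importances) > 1 else np.zeros(
            len(self.protocol.features)
        )
        return dict(zip(self.protocol.features, sd))

    def importance_ranking(self) -> list[str]:
        """Features ordered by decreasing mean importance."""
        mean = self.importance_mean
        return sorted(mean, key=mean.get, reverse=True)

    def to_dict(self) -> dict:
        return dict(
            target=self.protocol.target,
            n_repeats=self.protocol.n_repeats,
            r2_mean=self.r2_mean, r2_sd=self.r2_sd,
            mae_mean=self.mae_mean, mae_sd=self.mae_sd,
            importance_mean={k: float(v) for k, v in self.importance_mean.items()},
            importance_sd={k: float(v) for k, v in self.importance_sd.items()},
            r2=self.r2.tolist(), mae=self.mae.tolist(),
            importances=self.importances.tolist(),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_rf_repeated(merged: pd.DataFrame, protocol: RFProtocol | None = None) -> RFResult:
    """Run the repeated random-forest protocol on the fused screen table.

    Rows with a missing target are dropped; missing feature values are an
    error.  A constant target makes R^2 undefined and raises ``ValueError``.
    """
    protocol = protocol or RFProtocol()
    cols = list(protocol.features) + [protocol.target]
    df = merged.dropna(subset=[protocol.target])
    if df[list(protocol.features)].isna().any().any():
        raise ValueError("missing feature values in the screen table")
    X = df[list(protocol.features)].to_numpy(dtype=float)
    y = df[protocol.target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant target: R^2 undefined")

    r2s, maes, imps = [], [], []
    for rep in range(protocol.n_repeats):
        seed = protocol.base_seed + rep
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=protocol.test_fraction, random_state=seed
        )
        rf = RandomForestRegressor(n_estimators=protocol.n_estimators, random_state=seed)
        search = GridSearchCV(
            rf,
            protocol.param_grid,
            cv=KFold(protocol.cv_folds, shuffle=True, random_state=seed),
            scoring="neg_mean_absolute_error",
            n_jobs=None,
        )
        search.fit(X_tr, y_tr)
        model = search.best_estimator_  # refit on the full training portion
        pred = model.predict(X_te)
        r2s.append(r2_score(y_te, pred))
        maes.append(mean_absolute_error(y_te, pred))
        if protocol.importance == "permutation":
            pi = permutation_importance(model, X_te, y_te, n_repeats=5, random_state=seed)
            imp = np.clip(pi.importances_mean, 0.0, None)
        else:
            imp = model.feature_importances_
        s = imp.sum()
        imps.append(imp / s if s > 0 else np.full_like(imp, 1.0 / imp.size))
    return RFResult(protocol, np.array(r2s), np.array(maes), np.array(imps))


# ---------------------------------------------------------------------------
# Per-DOG PLS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PLSResult:
    """Per-DOG PLS fit summary with signed variable importance in percent."""

    dog: str
    n_components: int
    predictors: tuple[str, ...]
    responses: tuple[str, ...]
    coefficients: np.ndarray  # (n_predictors, n_responses), standardised scale
    importance: pd.DataFrame  # predictors x responses, signed %, sum(|.|) = 100 per column
    r2: dict  # response -> in-sample R^2
    loo_rmsep: np.ndarray  # RMSEP per candidate component count

    def to_dict(self) -> dict:
        return dict(
            dog=self.dog,
            n_components=self.n_components,
            predictors=list(self.predictors),
            responses=list(self.responses),
            coefficients=self.coefficients.tolist(),
            importance={r: self.importance[r].to_dict() for r in self.responses},
            r2={k: float(v) for k, v in self.r2.items()},
            loo_rmsep=self.loo_rmsep.tolist(),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _sd_scale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns by their SD; zero-SD columns get unit scale.

    The unit-scale (offset) rule leaves a fixed parameter as an all-zero
    column: it enters the model with zero variance and ends up with ~zero
    importance instead of producing a division by zero.
    """
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (M - mu) / sd_safe, mu, sd_safe


def _pls_coefficients(X: np.ndarray, Y: np.ndarray, n_components: int) -> np.ndarray:
    """Standardised-scale PLS2 coefficient matrix, shape (n_features, n_targets)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X, Y)
    coef = np.asarray(pls.coef_)
    if coef.shape == (Y.shape[1], X.shape[1]):  # sklearn >= 1.1 is (targets, features)
        coef = coef.T
    return coef


def fit_pls_dog(
    table: pd.DataFrame,
    dog: str | None = None,
    predictors: tuple[str, ...] = FEATURES,
    responses: tuple[str, ...] = ("density", "median_ctcf_asma", "median_ctcf_col1"),
    max_components: int = 3,
) -> PLSResult:
    """Fit the per-DOG PLS and compute signed variable importances.

    *table* is one DOG's merged rows (or pass ``dog`` to subset).  Rows with
    any missing value in the used columns are dropped.  The component count
    is the argmin of the leave-one-out root-mean-squared prediction error
    over 1..max_components (capped at n_samples - 1).
    """
    df = table[table["dog"] == dog] if dog is not None else table
    dog_name = dog if dog is not None else (df["dog"].iloc[0] if "dog" in df else "")
    df = df.dropna(subset=[*predictors, *responses])
    if len(df) < 3:
        raise ValueError(f"too few complete rows ({len(df)}) for PLS")
    X_raw = df[list(predictors)].to_numpy(dtype=float)
    Y_raw = df[list(responses)].to_numpy(dtype=float)
    Xs, _, _ = _sd_scale(X_raw)
    Ys, y_mu, y_sd = _sd_scale(Y_raw)

    n = len(df)
    k_max = int(min(max_components, n - 1, Xs.shape[1]))
    rmsep = np.empty(k_max)
    for ki in range(1, k_max + 1):
        sq = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            coef = _pls_coefficients(Xs[mask], Ys[mask], ki)
            pred = (Xs[i] - Xs[mask].mean(axis=0)) @ coef + Ys[mask].mean(axis=0)
            sq += float(np.sum((Ys[i] - pred) ** 2))
        rmsep[ki - 1] = np.sqrt(sq / (n * Ys.shape[1]))
    n_components = int(np.argmin(rmsep)) + 1

    coef = _pls_coefficients(Xs, Ys, n_components)
    fitted = Xs @ coef
    r2 = {
        resp: float(r2_score(Ys[:, j], fitted[:, j])) for j, resp in enumerate(responses)
    }
    imp = variable_importance(coef, predictors, responses)
    return PLSResult(
        dog_name, n_components, tuple(predictors), tuple(responses), coef, imp, r2, rmsep
    )


def variable_importance(
    coefficients: np.ndarray,
    predictors: tuple[str, ...] = FEATURES,
    responses: tuple[str, ...] = ("density", "median_ctcf_asma", "median_ctcf_col1"),
) -> pd.DataFrame:
    """Signed variable importance in percent from standardised PLS coefficients.

    For each response, importance_j = 100 * beta_j / sum_k |beta_k|, so
    absolute importances sum to exactly 100 per response and the sign
    preserves the correlation direction.  All-zero coefficients for a
    response are an error (importance undefined).
    """
    B = np.asarray(coefficients, dtype=float)
    if B.shape != (len(predictors), len(responses)):
        raise ValueError(f"coefficient shape {B.shape} != ({len(predictors)}, {len(responses)})")
    denom = np.abs(B).sum(axis=0)
    if np.any(denom == 0):
        bad = [responses[j] for j in np.flatnonzero(denom == 0)]
        raise ValueError(f"all-zero coefficients for response(s) {bad}: importance undefined")
    return pd.DataFrame(100.0 * B / denom, index=list(predictors), columns=list(responses))
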