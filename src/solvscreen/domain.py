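"""Leverage-based applicability domain and Williams-plot diagnostics.

A query is interpolative for the ensemble when its leverage (hat value) on
the intercept-augmented descriptor design matrix does not exceed the warning
leverage h* = 3(p+1)/n and its standardized residual stays within +/-3. The
domain is shared by all ensemble members, since every network sees the same
descriptor design.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted


@dataclass
class ADReport:
    leverages: np.ndarray
    warning_leverage: float
    std_residuals: np.ndarray
    inside_domain: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "record_id": np.arange(len(self.leverages)),
            "leverage": self.leverages,
            "std_residual": self.std_residuals,
            "inside_domain": self.inside_domain,
        })


class LeverageDomain(BaseEstimator):
    """Hat-value applicability domain, scikit-learn style.

    ``fit(X)`` stores the training design; ``leverage(Xq)`` returns hat
    values h_q = x_q (X'X)^-1 x_q' on the intercept-augmented design.
    """

    def __init__(self, add_intercept: bool = True, on_singular: str = "error"):
        self.add_intercept = add_intercept
        self.on_singular = on_singular

    def _augment(self, X: np.ndarray) -> np.ndarray:
        if self.add_intercept:
            return np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        xa = self._augment(X)
        self.n_train_ = X.shape[0]
        xtx = xa.T @ xa
        self.rank_ = int(np.linalg.matrix_rank(xtx))
        if self.rank_ < xa.shape[1]:
            # exact collinearity (e.g. relative descriptors summing to one
            # alongside the intercept): leverages remain well defined as the
            # projection onto the design column space via the pseudo-inverse
            if self.on_singular == "error":
                raise ValueError(
                    "training design matrix is rank-deficient; check the descriptors "
                    "for collinearity (constant or duplicated columns)")
            if self.on_singular != "pinv":
                raise ValueError(f"on_singular must be 'error' or 'pinv', "
                                 f"got {self.on_singular!r}")
            self.xtx_inv_ = np.linalg.pinv(xtx)
        else:
            self.xtx_inv_ = np.linalg.inv(xtx)
        p_plus_1 = xa.shape[1]
        self.warning_leverage_ = 3.0 * p_plus_1 / self.n_train_
        return self

    def leverage(self, X) -> np.ndarray:
        check_is_fitted(self, "xtx_inv_")
        xa = self._augment(check_array(X))
        return np.einsum("ij,jk,ik->i", xa, self.xtx_inv_, xa)

    def predict(self, X) -> np.ndarray:
        """True where the query leverage is within the warning leverage."""
        return self.leverage(X) <= self.warning_leverage_


def hat_values(train_features, query_features, add_intercept: bool = True) -> np.ndarray:
    """Leverages of query rows on the (intercept-augmented) training design."""
    dom = LeverageDomain(add_intercept=add_intercept).fit(train_features)
    return dom.leverage(query_features)


def williams_report(ensemble, features, targets,
                    add_intercept: bool = True) -> ADReport:
    """Williams-plot data for the fitted ensemble on a labelled dataset.

    Residuals are taken from the range-filtered ensemble mean prediction and
    standardized by their own standard deviation; a record is inside the
    domain iff h <= h* and |standardized residual| <= 3. The seven-descriptor
    design carries an exact dependency (the relative energies sum to one), so
    leverages are computed through the pseudo-inverse.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    dom = LeverageDomain(add_intercept=add_intercept, on_singular="pinv").fit(features)
    h = dom.leverage(features)
    res = ensemble.predict(features) - targets
    sd = res.std()
    std_res = res / sd if sd > 0 else np.zeros_like(res)
    inside = (h <= dom.warning_leverage_) & (np.abs(std_res) <= 3.0)
    return ADReport(leverages=h, warning_leverage=float(dom.warning_leverage_),
                    std_residuals=std_res, inside_domain=inside)
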