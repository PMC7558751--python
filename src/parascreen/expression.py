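"""Classify genes by expression behavior across a cell-line panel.

Each gene is summarized by the mean and standard deviation of its log2(TPM)
expression across cell lines, and the joint (mean, SD) cloud is modeled as
a three-component full-covariance Gaussian mixture.  The components map to
biology by a deterministic rule: the component with the highest SD-axis
center is "sometimes" expressed (variable, often tissue-specific); of the
two low-variance components, the one with lower mean expression is "never"
expressed and the other "constitutive".
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .exceptions import ConfigError
from .io import GeneMatrix

CLASS_LABELS = ("never", "sometimes", "constitutive")


def summarize_expression(expr: GeneMatrix) -> pd.DataFrame:
    """Per-gene mean and sample SD of log2 TPM across cell lines."""
    if expr.value_kind != "log2_tpm":
        raise ValueError(f"expected log2_tpm matrix, got {expr.value_kind}")
    if expr.values.shape[1] < 2:
        raise ValueError("need >= 2 cell lines to compute an SD")
    return pd.DataFrame(
        {
            "mean": expr.values.mean(axis=1),
            "sd": expr.values.std(axis=1, ddof=1),
        }
    )


@dataclasses.dataclass
class ExpressionGMM:
    """A fitted mixture plus the provenance needed to reuse it."""

    model: GaussianMixture
    converged: bool
    seed: int

    @property
    def means_(self) -> np.ndarray:
        return self.model.means_

    @property
    def weights_(self) -> np.ndarray:
        return self.model.weights_

    @property
    def covariances_(self) -> np.ndarray:
        return self.model.covariances_

    def parameters(self) -> dict:
        return {
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "covariances": self.covariances_.tolist(),
            "converged": bool(self.converged),
            "seed": self.seed,
        }


def fit_expression_gmm(
    summary: pd.DataFrame,
    n_components: int = 3,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
) -> ExpressionGMM:
    """EM fit of a full-covariance bivariate mixture on (mean, SD).

    Runs ``n_init`` random restarts and keeps the best log-likelihood.
    """
    if len(summary) < 10 * n_components:
        raise ConfigError(
            f"need >= {10 * n_components} genes to fit {n_components} components"
        )
    X = summary[["mean", "sd"]].to_numpy()
    model = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=n_init,
        tol=tol,
        random_state=seed,
        max_iter=500,
    ).fit(X)
    if not model.converged_:
        raise ConfigError(
            "EM did not converge; lower tol or increase max_iter "
            f"(lower bound {model.lower_bound_:.4f})"
        )
    return ExpressionGMM(model, bool(model.converged_), seed)


def component_labels(fit: ExpressionGMM) -> dict[int, str]:
    """Map mixture components to never/sometimes/constitutive.

    The SD axis is decisive first: the component whose center has the
    largest SD coordinate is "sometimes".  The remaining two are split by
    mean expression.  Exact ties make the fit ambiguous and raise.
    """
    means = fit.means_
    if means.shape[0] != 3:
        raise ValueError("label mapping is defined for 3 components")
    sd_centers = means[:, 1]
    order_sd = np.argsort(sd_centers)
    if sd_centers[order_sd[2]] == sd_centers[order_sd[1]]:
        raise ConfigError("ambiguous fit: tied SD-axis centers")
    sometimes = int(order_sd[2])
    rest = [i for i in range(3) if i != sometimes]
    if means[rest[0], 0] == means[rest[1], 0]:
        raise ConfigError("ambiguous fit: tied mean-axis centers")
    rest.sort(key=lambda i: means[i, 0])
    return {rest[0]: "never", sometimes: "sometimes", rest[1]: "constitutive"}


def assign_classes(fit: ExpressionGMM, summary: pd.DataFrame) -> pd.DataFrame:
    """Label each gene by its maximum-posterior component.

    Returns a table with the class, the posterior probability of each named
    class, and the winning posterior.
    """
    labels = component_labels(fit)
    X = summary[["mean", "sd"]].to_numpy()
    posterior = fit.model.predict_proba(X)
    winner = posterior.argmax(axis=1)
    out = pd.DataFrame(index=summary.index)
    out["class"] = [labels[int(c)] for c in winner]
    for comp, name in labels.items():
        out[f"p_{name}"] = posterior[:, comp]
    out["posterior"] = posterior.max(axis=1)
    return out


def classify_expression(
    expr: GeneMatrix, seed: int = 0, n_init: int = 10
) -> tuple[pd.DataFrame, ExpressionGMM]:
    """summarize -> fit -> assign, returning the table and the fit."""
    summary = summarize_expression(expr)
    fit = fit_expression_gmm(summary, seed=seed, n_init=n_init)
    classes = assign_classes(fit, summary)
    return classes.join(summary), fit


def bic_report(
    summary: pd.DataFrame, components: tuple[int, ...] = (2, 3, 4), seed: int = 0
) -> pd.DataFrame:
    """Optional model-selection diagnostic: BIC per component count."""
    X = summary[["mean", "sd"]].to_numpy()
    rows = []
    for k in components:
        model = GaussianMixture(
            n_components=k, covariance_type="full", n_init=5, random_state=seed
        ).fit(X)
        rows.append({"n_components": k, "bic": model.bic(X)})
    return pd.DataFrame(rows)
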