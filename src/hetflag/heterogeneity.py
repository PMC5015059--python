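"""Per-gene expression-heterogeneity classification.

The statistic is *N*, the number of cells in which a gene is expressed
above a positivity threshold (default >3 FPKM, strict).  Restricted to
genes with maximum expression in a moderate window (default 3–30 FPKM,
lower bound strict, upper inclusive), the pooled distribution of N across
genes is bimodal: one population of genes expressed in few cells (high
cell-to-cell heterogeneity) and one expressed in most cells (low
heterogeneity).  A two-component univariate Gaussian mixture is fitted to
the N values by EM; each gene is then flagged

* ``H`` if its posterior probability of the low-mean component exceeds the
  cutoff (default 0.99, strict),
* ``L`` if the posterior of the high-mean component exceeds it,
* ``U`` (uncertain) otherwise.

EM starts from weights (0.5, 0.5) and standard deviations (0.5, 0.5);
component means start at the 25th/75th percentiles of the data by default
(``init="quartile"``) or at two random data points (``init="random"``).
Components are relabelled so that component 1 has the smaller mean, i.e.
component 1 is always the high-heterogeneity population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import ConfigError, DegenerateDataError, NonConvergenceError
from .quantification import ExpressionMatrix

_VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and EM controls for the heterogeneity analysis.

    All expression values are FPKM. ``expr_threshold`` defines positivity
    (strict >), the window ``(window_low, window_high]`` selects analyzable
    genes by their max FPKM over cells, and ``posterior_cutoff`` (strict >)
    separates confident H/L calls from U.
    """

    expr_threshold: float = 3.0
    window_low: float = 3.0
    window_high: float = 30.0
    posterior_cutoff: float = 0.99
    em_tolerance: float = 1e-8
    em_max_iter: int = 1000
    init: str = "quartile"
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.window_low < self.window_high:
            raise ConfigError("require 0 < window_low < window_high")
        if not 0.5 < self.posterior_cutoff < 1:
            raise ConfigError("posterior_cutoff must lie in (0.5, 1)")
        if self.init not in ("quartile", "random"):
            raise ConfigError("init must be 'quartile' or 'random'")
        if self.em_tolerance <= 0 or self.em_max_iter < 1:
            raise ConfigError("invalid EM controls")


@dataclass
class MixtureModel:
    """Fitted two-component Gaussian mixture on the N scale.

    Component 1 is the smaller-mean (high-heterogeneity) component.
    ``loglik_trace`` records the log-likelihood after every EM iteration.
    """

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise NonConvergenceError("mixture weights do not sum to 1")
        if (self.sigmas <= 0).any():
            raise NonConvergenceError("non-positive component sigma")
        if not self.means[0] <= self.means[1]:
            raise NonConvergenceError("components not ordered by mean")


def count_expressing_cells(values: Iterable[float], threshold: float = 3.0) -> int:
    """Number of cells with expression strictly above ``threshold``."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise DegenerateDataError("empty per-cell expression vector")
    if (arr < 0).any():
        raise DegenerateDataError("negative expression values")
    return int((arr > threshold).sum())


def select_window(matrix: ExpressionMatrix,
                  config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Genes whose max FPKM lies in (window_low, window_high], with their
    expressing-cell count N and max FPKM.

    Returns a DataFrame with columns gene_id, n_expressing, max_fpkm.
    Every retained gene has N ≥ 1 because its max already exceeds the
    positivity threshold (window_low ≥ expr_threshold by default).
    """
    if matrix.values.size == 0:
        raise DegenerateDataError("empty expression matrix")
    maxes = matrix.values.max(axis=1)
    keep = (maxes > config.window_low) & (maxes <= config.window_high)
    n = (matrix.values > config.expr_threshold).sum(axis=1)
    return pd.DataFrame({
        "gene_id": np.asarray(matrix.genes, dtype=object)[keep],
        "n_expressing": n[keep].astype(int),
        "max_fpkm": maxes[keep],
    }).reset_index(drop=True)


def _log_density(x: np.ndarray, weights, means, sigmas) -> np.ndarray:
    # (n, 2) component log joint: log λ_k + log φ(x; μ_k, σ_k)
    x = np.asarray(x, dtype=float)[:, None]
    return np.log(weights)[None, :] + norm.logpdf(x, loc=means[None, :],
                                                  scale=sigmas[None, :])


def fit_mixture(n_values: Sequence[float],
                config: AnalysisConfig = AnalysisConfig()) -> MixtureModel:
    """EM fit of a two-component univariate Gaussian mixture to N values.

    Starting point: λ = (0.5, 0.5), σ = (0.5, 0.5), μ at the data's
    25th/75th percentiles (or two random data points for ``init="random"``).
    Iterates until the relative log-likelihood change drops below
    ``config.em_tolerance`` or ``config.em_max_iter`` iterations.  A
    component collapsing onto a point (variance below the floor) or losing
    essentially all weight raises :class:`NonConvergenceError` rather than
    returning a spike solution.
    """
    x = np.asarray(n_values, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise DegenerateDataError(
            f"mixture fit needs at least 10 values, got {x.size}"
        )
    if np.unique(x).size < 2:
        raise DegenerateDataError("mixture fit needs at least 2 distinct values")
    n = x.size

    weights = np.array([0.5, 0.5])
    sigmas = np.array([0.5, 0.5])
    if config.init == "quartile":
        means = np.percentile(x, [25.0, 75.0])
        if means[0] == means[1]:
            means = np.array([x.min(), x.max()], dtype=float)
    else:
        rng = np.random.default_rng(config.seed)
        means = rng.choice(np.unique(x), size=2, replace=False).astype(float)
        means.sort()

    trace = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, config.em_max_iter + 1):
        log_joint = _log_density(x, weights, means, sigmas)
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])  # responsibilities γ

        nk = resp.sum(axis=0)
        if (nk < 1.0).any():
            raise NonConvergenceError(
                f"component weight collapsed below 1/n at iteration {it} "
                f"(effective counts {nk.round(3)})"
            )
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if (var < _VARIANCE_FLOOR).any():
            raise NonConvergenceError(
                f"component variance hit the floor ({_VARIANCE_FLOOR}) at "
                f"iteration {it}: means={means.round(4)}, var={var}"
            )
        sigmas = np.sqrt(var)
        trace.append(ll)

        if np.isfinite(prev_ll) and abs(ll - prev_ll) < config.em_tolerance * (
                abs(prev_ll) + 1e-300):
            converged = True
            break
        prev_ll = ll

    # final log-likelihood at the last parameter update
    final_ll = float(logsumexp(_log_density(x, weights, means, sigmas), axis=1).sum())
    trace.append(final_ll)

    order = np.argsort(means, kind="stable")
    return MixtureModel(
        weights=weights[order], means=means[order], sigmas=sigmas[order],
        log_likelihood=final_ll, n_iterations=it, converged=converged,
        loglik_trace=np.asarray(trace),
    )


def mixture_loglik(x: Sequence[float], weights, means, sigmas) -> float:
    """Log-likelihood of data under an arbitrary two-component mixture
    (shared by tests and diagnostics)."""
    lj = _log_density(np.asarray(x, dtype=float),
                      np.asarray(weights, dtype=float),
                      np.asarray(means, dtype=float),
                      np.asarray(sigmas, dtype=float))
    return float(logsumexp(lj, axis=1).sum())


def posterior_high(model: MixtureModel, n) -> float | np.ndarray:
    """Posterior probability that observation ``n`` belongs to component 1
    (the smaller-mean, high-heterogeneity component)."""
    arr = np.atleast_1d(np.asarray(n, dtype=float))
    lj = _log_density(arr, model.weights, model.means, model.sigmas)
    if not np.isfinite(lj).all():
        raise NonConvergenceError("non-finite mixture density")
    post = np.exp(lj[:, 0] - logsumexp(lj, axis=1))
    return float(post[0]) if np.isscalar(n) or np.ndim(n) == 0 else post


def assign_flag(posterior: float, cutoff: float = 0.99) -> str:
    """H / L / U flag from the high-heterogeneity posterior (strict cutoff)."""
    if not 0.5 < cutoff < 1:
        raise ConfigError("posterior cutoff must lie in (0.5, 1)")
    if not 0 <= posterior <= 1:
        raise ConfigError(f"posterior {posterior} outside [0, 1]")
    if posterior > cutoff:
        return "H"
    if 1 - posterior > cutoff:
        return "L"
    return "U"


@dataclass(frozen=True)
class HeterogeneityRecord:
    gene_id: str
    biotype: str
    n_expressing: int
    max_fpkm: float
    posterior_high: float
    flag: str


def classify_genes(matrix: ExpressionMatrix, biotypes: Mapping[str, str],
                   config: AnalysisConfig = AnalysisConfig(),
                   per_biotype_fit: bool = False,
                   ) -> tuple[pd.DataFrame, MixtureModel | dict[str, MixtureModel]]:
    """Full classification: window selection → pooled mixture fit → flags.

    ``biotypes`` maps gene_id → 'coding'/'noncoding' (genes missing from
    the mapping or labelled otherwise are dropped before the fit).  The
    mixture is fitted on the pooled N values of both biotypes by default;
    ``per_biotype_fit=True`` fits each biotype separately instead.

    Returns (records DataFrame, fitted model[s]).
    """
    windowed = select_window(matrix, config)
    windowed = windowed[windowed["gene_id"].map(
        lambda g: biotypes.get(g) in ("coding", "noncoding"))].reset_index(drop=True)
    if windowed.empty:
        raise DegenerateDataError("no genes in the analysis window")
    windowed["biotype"] = windowed["gene_id"].map(biotypes)

    def _records(df: pd.DataFrame, model: MixtureModel) -> pd.DataFrame:
        post = posterior_high(model, df["n_expressing"].to_numpy())
        df = df.copy()
        df["posterior_high"] = post
        df["flag"] = [assign_flag(p, config.posterior_cutoff) for p in post]
        return df

    if per_biotype_fit:
        models: dict[str, MixtureModel] = {}
        parts = []
        for bt, sub in windowed.groupby("biotype"):
            models[bt] = fit_mixture(sub["n_expressing"].to_numpy(), config)
            parts.append(_records(sub, models[bt]))
        records = pd.concat(parts, ignore_index=True)
        return records, models
    model = fit_mixture(windowed["n_expressing"].to_numpy(), config)
    return _records(windowed, model), model


def heterogeneity_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-biotype counts and fractions of H/L/U flags.

    Also reports the combined low-or-uncertain fraction. Fractions sum to
    1 per biotype (within 1e-12).
    """
    if records.empty:
        raise DegenerateDataError("no heterogeneity records")
    rows = []
    for bt, sub in records.groupby("biotype"):
        total = len(sub)
        counts = sub["flag"].value_counts()
        h, l, u = (int(counts.get(f, 0)) for f in ("H", "L", "U"))
        rows.append({
            "biotype": bt, "n_genes": total,
            "n_H": h, "n_L": l, "n_U": u,
            "frac_H": h / total, "frac_L": l / total, "frac_U": u / total,
            "frac_low_or_uncertain": (l + u) / total,
        })
    return pd.DataFrame(rows)


def model_summary(model: MixtureModel) -> str:
    """Human-readable fit summary (component 1 = high heterogeneity)."""
    lines = [
        "two-component Gaussian mixture on N (expressing-cell counts)",
        f"  lambda = ({model.weights[0]:.6g}, {model.weights[1]:.6g})",
        f"  mu     = ({model.means[0]:.6g}, {model.means[1]:.6g})",
        f"  sigma  = ({model.sigmas[0]:.6g}, {model.sigmas[1]:.6g})",
        f"  log-likelihood = {model.log_likelihood:.6f}",
        f"  iterations = {model.n_iterations}  converged = {model.converged}",
        "  component 1 (smaller mean) = high-heterogeneity population",
    ]
    return "\n".join(lines)
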