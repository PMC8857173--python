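"""Model-fit battery: convergence statistics, information criteria, Brier
score, and the hyperprior sensitivity analysis.

Convergence uses the rank-normalized split R-hat and autocorrelation-based
effective sample size (via ArviZ); the Monte Carlo standard error is the
posterior standard deviation divided by the square root of the effective
sample size, by definition.  Predictive accuracy uses PSIS-LOO-CV (Pareto
smoothed importance sampling, ArviZ's smoother), WAIC and the Brier score;
WAIC/LOO are reported on both the elpd and deviance (-2x) scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import MCMCConfig, ModelSpec, NODES, PosteriorSamples, PriorSpec, build_model, fit_posterior

__all__ = [
    "WaicResult",
    "LooResult",
    "FitDiagnostics",
    "SensitivityResult",
    "rhat",
    "ess_and_mcse",
    "brier_score",
    "waic",
    "psis_loo",
    "diagnose_fit",
    "sensitivity_analysis",
]

PARETO_K_THRESHOLD = 0.7  # points above are flagged unreliable


def _as_chains(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("expected a (chain, draw) array")
    if draws.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    if draws.shape[1] < 4:
        raise ValueError("at least 4 draws per chain are required")
    return draws


def rhat(chains: np.ndarray) -> float:
    """Rank-normalized split potential-scale-reduction statistic.

    Approaches 1 as chains mix.  Zero-variance (constant) chains have no
    defined scale reduction and return NaN — the undefined flag — never 1.
    """
    import arviz as az

    chains = _as_chains(chains)
    if np.ptp(chains) == 0.0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(chains))


def ess_and_mcse(chains: np.ndarray) -> tuple[float, float]:
    """Effective sample size (autocorrelation-based, bulk) and the Monte
    Carlo standard error of the posterior mean, mcse = sd / sqrt(ess)."""
    import arviz as az

    chains = _as_chains(chains)
    if np.ptp(chains) == 0.0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(chains))
    sd = float(np.std(chains, ddof=1))
    return ess, sd / np.sqrt(ess)


def brier_score(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome.

    BS = sum_i (predicted_i - actual_i)^2 / N, in [0, 1]; 0 is a perfect
    probabilistic prediction, 1 the maximally wrong one.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    if predicted.size == 0:
        raise ValueError("empty input")
    if np.any((predicted < 0) | (predicted > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if not np.all(np.isin(actual, (0.0, 1.0))):
        raise ValueError("actual outcomes must be binary 0/1")
    return float(np.mean((predicted - actual) ** 2))


def _flatten_loglik(pointwise_loglik: np.ndarray) -> np.ndarray:
    """(draws, points) or (chain, draw, points) -> (samples, points)."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, points)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood")
    return ll


@dataclass
class WaicResult:
    elpd: float
    se_elpd: float
    p_waic: float
    waic: float  # deviance scale, -2 * elpd
    se: float

    def __iter__(self):  # (waic, se) unpacking
        return iter((self.waic, self.se))


@dataclass
class LooResult:
    elpd: float
    se_elpd: float
    pareto_k: np.ndarray
    looic: float  # deviance scale
    se: float
    n_bad_k: int = 0

    def __iter__(self):  # (elpd_loo, se, pareto_k) unpacking
        return iter((self.elpd, self.se_elpd, self.pareto_k))


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """Widely applicable information criterion from pointwise log-likelihood.

    elpd_i = lppd_i - p_i with lppd_i the log pointwise predictive density
    and penalty p_i the posterior variance of the log-likelihood; reported on
    the deviance scale (-2x) with its standard error, elpd also exposed.
    """
    ll = _flatten_loglik(pointwise_loglik)
    s, n = ll.shape
    lppd = logsumexp(ll, axis=0) - np.log(s)
    p = np.var(ll, axis=0, ddof=1) if s > 1 else np.zeros(n)
    elpd_i = lppd - p
    elpd = float(np.sum(elpd_i))
    se_elpd = float(np.sqrt(n * np.var(elpd_i, ddof=1))) if n > 1 else 0.0
    return WaicResult(
        elpd=elpd,
        se_elpd=se_elpd,
        p_waic=float(np.sum(p)),
        waic=-2.0 * elpd,
        se=2.0 * se_elpd,
    )


def psis_loo(pointwise_loglik: np.ndarray, reff: float = 1.0) -> LooResult:
    """Pareto-smoothed importance-sampling leave-one-out cross-validation.

    Importance ratios per point are smoothed by fitting a generalized Pareto
    distribution to their upper tail (ArviZ smoother); the per-point shape k
    diagnoses reliability (k > 0.7 flagged).  Points whose importance weights
    are exactly uniform (zero-variance log-ratios, e.g. a constant
    log-likelihood) have no tail to fit and get k = 0.
    """
    import arviz as az

    ll = _flatten_loglik(pointwise_loglik)
    s, n = ll.shape
    if s < 100:
        raise ValueError("PSIS tail fitting needs >= 100 draws")
    log_ratios = -ll.T  # (points, samples); sample axis last for the smoother
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(log_ratios, reff=reff)
    lw = np.asarray(lw)
    k = np.asarray(k, dtype=float)
    degenerate = np.ptp(log_ratios, axis=-1) < 1e-12
    k = np.where(degenerate, 0.0, k)
    elpd_i = logsumexp(lw + ll.T, axis=-1)
    elpd = float(np.sum(elpd_i))
    se_elpd = float(np.sqrt(n * np.var(elpd_i, ddof=1))) if n > 1 else 0.0
    return LooResult(
        elpd=elpd,
        se_elpd=se_elpd,
        pareto_k=k,
        looic=-2.0 * elpd,
        se=2.0 * se_elpd,
        n_bad_k=int(np.sum(k > PARETO_K_THRESHOLD)),
    )


@dataclass
class FitDiagnostics:
    """Convergence and fit summary of one posterior sample."""

    rhat: dict[str, float]  # per variable (max over vector elements)
    ess: dict[str, float]  # min over vector elements
    mcse: dict[str, float]
    divergences: int
    loo: LooResult | None
    waic: WaicResult | None
    brier: dict[str, float]  # per node, observed labels only
    max_rhat: float = field(init=False)
    min_ess: float = field(init=False)

    def __post_init__(self):
        finite = [v for v in self.rhat.values() if np.isfinite(v)]
        self.max_rhat = max(finite) if finite else float("nan")
        finite = [v for v in self.ess.values() if np.isfinite(v)]
        self.min_ess = min(finite) if finite else float("nan")

    def to_dict(self) -> dict:
        d = {
            "rhat": self.rhat,
            "ess": self.ess,
            "mcse": self.mcse,
            "divergences": self.divergences,
            "max_rhat": self.max_rhat,
            "min_ess": self.min_ess,
            "brier": self.brier,
        }
        if self.loo is not None:
            d["elpd_loo"] = self.loo.elpd
            d["elpd_loo_se"] = self.loo.se_elpd
            d["looic"] = self.loo.looic
            d["pareto_k_max"] = float(np.max(self.loo.pareto_k)) if self.loo.pareto_k.size else float("nan")
            d["n_bad_pareto_k"] = self.loo.n_bad_k
        if self.waic is not None:
            d["waic"] = self.waic.waic
            d["waic_se"] = self.waic.se
            d["elpd_waic"] = self.waic.elpd
        return d


def _model_variables(ps: PosteriorSamples) -> dict[str, np.ndarray]:
    """Free model parameters as (chain, draw[, k]) arrays, frozen ones skipped."""
    out = {}
    for name, arr in ps.posterior.items():
        if np.ptp(arr) == 0.0:  # frozen constants carry no chains to diagnose
            continue
        out[name] = arr
    return out


def diagnose_fit(ps: PosteriorSamples) -> FitDiagnostics:
    """Full battery on one fit: R-hat/ESS/MCSE per variable, divergence
    count, PSIS-LOO, WAIC and per-node Brier scores."""
    rh, es, mc = {}, {}, {}
    for name, arr in _model_variables(ps).items():
        if arr.ndim == 2:
            arr = arr[:, :, None]
        r_vals, e_vals, m_vals = [], [], []
        for j in range(arr.shape[2]):
            r_vals.append(rhat(arr[:, :, j]))
            e, m = ess_and_mcse(arr[:, :, j])
            e_vals.append(e)
            m_vals.append(m)
        rh[name] = float(np.nanmax(r_vals))
        es[name] = float(np.nanmin(e_vals))
        mc[name] = float(np.nanmax(m_vals))
    ll, _ = ps.pointwise_loglik()
    loo_res = waic_res = None
    if ll.shape[-1] > 0:
        loo_res = psis_loo(ll)
        waic_res = waic(ll)
    brier = {}
    for kk, node in enumerate(NODES):
        obs = ps.y_missing_mask[node] == 0
        if obs.any():
            pred = ps.prob[:, :, obs, kk].mean(axis=(0, 1))
            brier[node] = brier_score(pred, ps.y_obs[node][obs])
    return FitDiagnostics(
        rhat=rh,
        ess=es,
        mcse=mc,
        divergences=int(sum(ps.divergences)),
        loo=loo_res,
        waic=waic_res,
        brier=brier,
    )


@dataclass
class SensitivityResult:
    """Refits under alternative weakly-informative hyperpriors.

    ``predictive_means`` holds the per-compound, per-node posterior-predictive
    mean probabilities per setting (None where a fit failed);
    ``delta_matrix[a, b]`` is the max absolute difference in predictive means
    between settings a and b.
    """

    labels: list[str]
    settings: list[PriorSpec]
    metrics: list[dict | None]
    predictive_means: list[np.ndarray | None]
    delta_matrix: np.ndarray
    errors: dict[str, str]

    @property
    def max_delta(self) -> float:
        off = self.delta_matrix[~np.eye(len(self.labels), dtype=bool)]
        return float(np.nanmax(off)) if off.size else float("nan")


def sensitivity_analysis(
    dm,
    settings: list[PriorSpec],
    mcmc: MCMCConfig,
    labels: list[str] | None = None,
) -> SensitivityResult:
    """Refit the model under each hyperprior setting and compare elpd_loo,
    WAIC, Brier scores and per-compound predictive means.

    A failing setting is recorded and skipped; the rest still run.
    """
    if len(settings) < 2:
        raise ValueError("sensitivity analysis needs at least 2 settings")
    labels = labels or [f"setting_{i}" for i in range(len(settings))]
    metrics: list[dict | None] = []
    means: list[np.ndarray | None] = []
    errors: dict[str, str] = {}
    for lab, prior in zip(labels, settings):
        try:
            model = build_model(dm, ModelSpec(priors=prior))
            ps = fit_posterior(model, mcmc)
            diag = diagnose_fit(ps)
            metrics.append(
                {
                    "elpd_loo": diag.loo.elpd if diag.loo else float("nan"),
                    "waic": diag.waic.waic if diag.waic else float("nan"),
                    **{f"brier_{n}": v for n, v in diag.brier.items()},
                    "divergences": diag.divergences,
                }
            )
            means.append(ps.prob.mean(axis=(0, 1)))  # (n, 4)
        except Exception as exc:  # propagate per setting without aborting
            metrics.append(None)
            means.append(None)
            errors[lab] = f"{type(exc).__name__}: {exc}"
    m = len(settings)
    delta = np.full((m, m), np.nan)
    for a in range(m):
        for b in range(m):
            if means[a] is not None and means[b] is not None:
                delta[a, b] = float(np.max(np.abs(means[a] - means[b]))) if means[a].size else 0.0
    return SensitivityResult(
        labels=labels,
        settings=list(settings),
        metrics=metrics,
        predictive_means=means,
        delta_matrix=delta,
        errors=errors,
    )
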