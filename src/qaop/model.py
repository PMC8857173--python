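"""Nested partial-pooled Bayesian hierarchical model of the DNT qAOP.

The adverse outcome pathway is a fixed chain BDNF -> SYN -> NNF -> DNT.  Each
key event k has a coefficient vector beta_k over its predictor block X_k; all
beta entries are partially pooled through one global pair of hyperpriors,

    mu ~ Normal(0, 0.1),   sigma ~ HalfNormal(1),
    beta_BDNF, beta_SYN, beta_NNF ~ Normal(mu, sigma),

and the linear predictors accumulate downstream along the causal chain:

    theta_BDNF = beta_BDNF . X_BDNF
    theta_SYN  = beta_SYN  . X_SYN + theta_BDNF
    theta_NNF  = beta_NNF  . X_NNF + theta_SYN
    theta_DNT  = theta_BDNF + theta_SYN + theta_NNF

Every binary outcome is Bernoulli(inv_logit(theta)).  Missing predictor cells
are latent values with their own weakly-informative Normal/HalfNormal
imputation hyperpriors, sampled jointly with everything else; missing outcome
labels are marginalized out of the likelihood and imputed from the posterior
predictive.  Sampling uses the package's No-U-Turn sampler with analytic
gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._link import LINK, inv_logit, log_inv_logit
from .dataset import DesignMatrices
from .sampler import NUTSResult, sample_nuts

__all__ = [
    "NODES",
    "BLOCKS",
    "PriorSpec",
    "ModelSpec",
    "MCMCConfig",
    "BlockCensus",
    "QAOPModel",
    "PosteriorSamples",
    "compute_theta_chain",
    "build_model",
    "log_joint_density",
    "fit_posterior",
    "count_parameters",
]

NODES = ("bdnf", "syn", "nnf", "dnt")
BLOCKS = ("bdnf", "syn", "nnf")  # key events carrying a coefficient block

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _normal_logpdf(x, loc, scale):
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -_LOG_SQRT_2PI - np.log(scale) - 0.5 * z * z


def _halfnormal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.log(2.0) - _LOG_SQRT_2PI - np.log(scale) - 0.5 * (x / scale) ** 2
    return np.where(x < 0, -np.inf, out)


@dataclass
class PriorSpec:
    """Weakly-informative hyperprior and imputation-prior scales.

    Defaults: mu ~ Normal(0, 0.1), sigma ~ HalfNormal(1) for the pooled
    coefficients, and the same family for the missing-predictor imputation
    hyperpriors.  Second Normal parameter is a standard deviation.
    """

    hyper_mu_loc: float = 0.0
    hyper_mu_scale: float = 0.1
    hyper_sigma_scale: float = 1.0
    impute_mu_loc: float = 0.0
    impute_mu_scale: float = 0.1
    impute_sigma_scale: float = 1.0

    def __post_init__(self):
        for name in ("hyper_mu_scale", "hyper_sigma_scale", "impute_mu_scale", "impute_sigma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def scaled(self, factor: float) -> "PriorSpec":
        """Same spec with the pooled-coefficient sigma scale multiplied."""
        return PriorSpec(
            hyper_mu_loc=self.hyper_mu_loc,
            hyper_mu_scale=self.hyper_mu_scale,
            hyper_sigma_scale=self.hyper_sigma_scale * factor,
            impute_mu_loc=self.impute_mu_loc,
            impute_mu_scale=self.impute_mu_scale,
            impute_sigma_scale=self.impute_sigma_scale,
        )


@dataclass
class ModelSpec:
    """Model structure: fixed DAG chain, logit link, priors, optional frozen
    parameters (name -> value) for reduced/oracle models."""

    priors: PriorSpec = field(default_factory=PriorSpec)
    link: str = LINK
    frozen: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.link != LINK:
            raise ValueError(f"unsupported link '{self.link}' (generator/fitter share '{LINK}')")


@dataclass
class MCMCConfig:
    seed: int
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10


@dataclass
class BlockCensus:
    """Structural census of the model graph."""

    hyperprior_blocks: int
    coefficient_blocks: int
    likelihood_blocks: int
    imputation_blocks: int  # (mu_Xmiss, sigma_Xmiss) pairs, one per block with gaps
    total_named: int  # hyperprior + coefficient + likelihood blocks
    total_scalar_parameters: int  # free scalars sampled by MCMC


def compute_theta_chain(c1, c2, c3):
    """Chain the per-block contributions c_k = beta_k . X_k row products.

    Returns (theta_bdnf, theta_syn, theta_nnf, theta_dnt); vectorized; the
    adverse-outcome predictor telescopes to 3*c1 + 2*c2 + c3.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    c3 = np.asarray(c3, dtype=float)
    if not (np.all(np.isfinite(c1)) and np.all(np.isfinite(c2)) and np.all(np.isfinite(c3))):
        raise ValueError("non-finite block contribution")
    t_bdnf = c1
    t_syn = c2 + t_bdnf
    t_nnf = c3 + t_syn
    t_dnt = t_bdnf + t_syn + t_nnf
    return t_bdnf, t_syn, t_nnf, t_dnt


class QAOPModel:
    """Compiled model graph: parameter layout, log joint and its gradient."""

    def __init__(self, dm: DesignMatrices, spec: ModelSpec):
        self.dm = dm
        self.spec = spec
        p1, p2, p3 = dm.block_dims
        if not (p1 >= 1 and p2 >= 1 and p3 >= 1):
            raise ValueError("every coefficient block needs at least one predictor")
        ys = dm.y_vectors()
        n = dm.n
        for node, (y, m) in ys.items():
            if y.shape != (n,) or m.shape != (n,):
                raise ValueError(f"outcome vector for '{node}' has wrong shape")
        for name, x, ms in (
            ("bdnf", dm.x_bdnf, dm.miss_bdnf),
            ("syn", dm.x_syn, dm.miss_syn),
            ("nnf", dm.x_nnf, dm.miss_nnf),
        ):
            if x.shape != ms.shape:
                raise ValueError(f"mask/matrix shape mismatch in block '{name}'")

        # missing-cell bookkeeping per block
        self.miss_idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for b, ms in zip(BLOCKS, (dm.miss_bdnf, dm.miss_syn, dm.miss_nnf)):
            rows, cols = np.nonzero(ms)
            if rows.size:
                self.miss_idx[b] = (rows, cols)

        # layout of the free (unconstrained) parameter vector; coefficients
        # and latent predictor cells are sampled non-centered (raw ~ N(0,1),
        # beta = mu + sigma*raw) to avoid funnel geometry — the posterior is
        # identical, only the sampled coordinates differ
        layout: list[tuple[str, int]] = []
        frozen = spec.frozen
        if "mu" not in frozen:
            layout.append(("mu", 1))
        if "sigma" not in frozen:
            layout.append(("log_sigma", 1))
        for b, p in zip(BLOCKS, (p1, p2, p3)):
            if f"beta_{b}" not in frozen:
                layout.append((f"beta_raw_{b}", p))
        for b in BLOCKS:
            if b in self.miss_idx:
                layout.append((f"mu_xmiss_{b}", 1))
                layout.append((f"log_sigma_xmiss_{b}", 1))
                layout.append((f"zmiss_{b}", self.miss_idx[b][0].size))
        self.layout = layout
        self.dim = sum(s for _, s in layout)
        self._slices: dict[str, slice] = {}
        off = 0
        for name, size in layout:
            self._slices[name] = slice(off, off + size)
            off += size

        # observed-outcome masks as float for vectorized residuals
        self._y = {node: ys[node][0].astype(float) for node in NODES}
        self._obs = {node: 1.0 - ys[node][1].astype(float) for node in NODES}

    # -- vector (un)packing ------------------------------------------------

    def unpack(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Free vector -> named natural-scale parameters.

        Applies the exp transform for half-normal scales and the non-centered
        shift/scale for coefficients and latent predictor cells, so the output
        holds ``mu``, ``sigma``, ``beta_*``, ``mu_xmiss_*``, ``sigma_xmiss_*``
        and ``xmiss_*`` on their natural scales (frozen values included).
        """
        out: dict[str, np.ndarray] = {}
        for name, _ in self.layout:
            v = x[self._slices[name]]
            if name.startswith("log_sigma"):
                out[name.replace("log_", "", 1)] = np.exp(v)
            else:
                out[name] = v.copy()
        for name, val in self.spec.frozen.items():
            out[name] = np.atleast_1d(np.asarray(val, dtype=float))
        mu = float(out["mu"][0])
        sigma = float(out["sigma"][0])
        for b in BLOCKS:
            raw = out.pop(f"beta_raw_{b}", None)
            if raw is not None:
                out[f"beta_{b}"] = mu + sigma * raw
        for b in self.miss_idx:
            z = out.pop(f"zmiss_{b}", None)
            if z is not None:
                mum = float(out[f"mu_xmiss_{b}"][0])
                sgm = float(out[f"sigma_xmiss_{b}"][0])
                out[f"xmiss_{b}"] = mum + sgm * z
        return out

    def _param(self, params: dict, name: str, size: int) -> np.ndarray:
        if name not in params:
            raise ValueError(f"missing parameter '{name}'")
        v = np.atleast_1d(np.asarray(params[name], dtype=float))
        if v.size != size:
            raise ValueError(f"parameter '{name}' must have {size} element(s)")
        return v

    # -- densities ---------------------------------------------------------

    def _filled_blocks(self, params: dict) -> dict[str, np.ndarray]:
        xs = {}
        for b, x in zip(BLOCKS, (self.dm.x_bdnf, self.dm.x_syn, self.dm.x_nnf)):
            if b in self.miss_idx:
                x = x.copy()
                rows, cols = self.miss_idx[b]
                x[rows, cols] = self._param(params, f"xmiss_{b}", rows.size)
            xs[b] = x
        return xs

    def log_joint(self, params: dict) -> float:
        """Log joint density at a full named-parameter assignment.

        Includes prior, imputation and observed-outcome likelihood terms;
        returns -inf for any non-positive scale (by contract).
        """
        prior = self.spec.priors
        mu = float(self._param(params, "mu", 1)[0])
        sigma = float(self._param(params, "sigma", 1)[0])
        if sigma <= 0:
            return -np.inf
        lp = float(_normal_logpdf(mu, prior.hyper_mu_loc, prior.hyper_mu_scale))
        lp += float(_halfnormal_logpdf(sigma, prior.hyper_sigma_scale))
        p1, p2, p3 = self.dm.block_dims
        betas = {
            b: self._param(params, f"beta_{b}", p)
            for b, p in zip(BLOCKS, (p1, p2, p3))
        }
        for b in BLOCKS:
            lp += float(np.sum(_normal_logpdf(betas[b], mu, sigma)))
        for b in self.miss_idx:
            mum = float(self._param(params, f"mu_xmiss_{b}", 1)[0])
            sgm = float(self._param(params, f"sigma_xmiss_{b}", 1)[0])
            if sgm <= 0:
                return -np.inf
            lp += float(_normal_logpdf(mum, prior.impute_mu_loc, prior.impute_mu_scale))
            lp += float(_halfnormal_logpdf(sgm, prior.impute_sigma_scale))
            xm = self._param(params, f"xmiss_{b}", self.miss_idx[b][0].size)
            lp += float(np.sum(_normal_logpdf(xm, mum, sgm)))
        if self.dm.n:
            xs = self._filled_blocks(params)
            thetas = compute_theta_chain(
                xs["bdnf"] @ betas["bdnf"],
                xs["syn"] @ betas["syn"],
                xs["nnf"] @ betas["nnf"],
            )
            for node, theta in zip(NODES, thetas):
                y, obs = self._y[node], self._obs[node]
                ll = y * log_inv_logit(theta) + (1.0 - y) * log_inv_logit(-theta)
                lp += float(np.sum(obs * ll))
        return lp

    # -- log density + gradient on the unconstrained vector ----------------

    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Log density and gradient in the sampled (non-centered) coordinates."""
        prior = self.spec.priors
        frozen = self.spec.frozen
        params = self.unpack(x)
        grad = np.zeros(self.dim)
        mu = float(params["mu"][0])
        sigma = float(params["sigma"][0])
        lp = float(_normal_logpdf(mu, prior.hyper_mu_loc, prior.hyper_mu_scale))
        lp += float(_halfnormal_logpdf(sigma, prior.hyper_sigma_scale))
        d_mu = -(mu - prior.hyper_mu_loc) / prior.hyper_mu_scale**2
        d_ls = -(sigma / prior.hyper_sigma_scale) ** 2  # chain rule through exp
        if "sigma" not in frozen:
            lp += np.log(sigma)  # log|d sigma / d log_sigma|
            d_ls += 1.0

        betas = {b: params[f"beta_{b}"] for b in BLOCKS}
        raws = {}
        for b in BLOCKS:
            if f"beta_{b}" in frozen:
                # frozen block: centered prior term conditions mu, sigma
                resid = betas[b] - mu
                lp += float(np.sum(_normal_logpdf(betas[b], mu, sigma)))
                d_mu += float(np.sum(resid)) / sigma**2
                d_ls += float(np.sum(resid**2)) / sigma**2 - len(resid)
            else:
                raw = x[self._slices[f"beta_raw_{b}"]]
                raws[b] = raw
                lp += float(np.sum(_normal_logpdf(raw, 0.0, 1.0)))

        # imputation blocks (non-centered latents)
        d_imp: dict[str, np.ndarray] = {}
        zs = {}
        for b in self.miss_idx:
            mum = float(params[f"mu_xmiss_{b}"][0])
            sgm = float(params[f"sigma_xmiss_{b}"][0])
            z = x[self._slices[f"zmiss_{b}"]]
            zs[b] = z
            lp += float(_normal_logpdf(mum, prior.impute_mu_loc, prior.impute_mu_scale))
            lp += float(_halfnormal_logpdf(sgm, prior.impute_sigma_scale)) + np.log(sgm)
            lp += float(np.sum(_normal_logpdf(z, 0.0, 1.0)))
            d_imp[f"mu_xmiss_{b}"] = np.array(
                [-(mum - prior.impute_mu_loc) / prior.impute_mu_scale**2]
            )
            d_imp[f"log_sigma_xmiss_{b}"] = np.array(
                [-(sgm / prior.impute_sigma_scale) ** 2 + 1.0]
            )
            d_imp[f"zmiss_{b}"] = -z

        d_beta_lik = {b: np.zeros_like(betas[b]) for b in BLOCKS}
        if self.dm.n:
            xs = self._filled_blocks(params)
            c = {b: xs[b] @ betas[b] for b in BLOCKS}
            thetas = dict(zip(NODES, compute_theta_chain(c["bdnf"], c["syn"], c["nnf"])))
            r = {}
            for node in NODES:
                theta = thetas[node]
                y, obs = self._y[node], self._obs[node]
                ll = y * log_inv_logit(theta) + (1.0 - y) * log_inv_logit(-theta)
                lp += float(np.sum(obs * ll))
                r[node] = obs * (y - inv_logit(theta))
            # weights of d lp / d c_k through the telescoped chain
            w = {
                "bdnf": r["bdnf"] + r["syn"] + r["nnf"] + 3.0 * r["dnt"],
                "syn": r["syn"] + r["nnf"] + 2.0 * r["dnt"],
                "nnf": r["nnf"] + r["dnt"],
            }
            for b in BLOCKS:
                d_beta_lik[b] = xs[b].T @ w[b]
                if b in self.miss_idx:
                    rows, cols = self.miss_idx[b]
                    g_cell = betas[b][cols] * w[b][rows]  # d lp / d x_cell
                    sgm = float(params[f"sigma_xmiss_{b}"][0])
                    d_imp[f"zmiss_{b}"] += sgm * g_cell
                    d_imp[f"mu_xmiss_{b}"] += np.sum(g_cell)
                    d_imp[f"log_sigma_xmiss_{b}"] += np.sum(g_cell * zs[b]) * sgm
            # likelihood flows into mu/log_sigma through beta = mu + sigma*raw
            for b in raws:
                d_mu += float(np.sum(d_beta_lik[b]))
                d_ls += float(np.sum(d_beta_lik[b] * raws[b])) * sigma

        # scatter into the free vector
        for name, _ in self.layout:
            sl = self._slices[name]
            if name == "mu":
                grad[sl] = d_mu
            elif name == "log_sigma":
                grad[sl] = d_ls
            elif name.startswith("beta_raw_"):
                b = name.removeprefix("beta_raw_")
                grad[sl] = -raws[b] + sigma * d_beta_lik[b]
            else:
                grad[sl] = d_imp[name]
        return lp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = 0.1 * rng.uniform(-1.0, 1.0, size=self.dim)
        return x


def build_model(dm: DesignMatrices, spec: ModelSpec | None = None) -> QAOPModel:
    """Compile the model graph for a set of design matrices."""
    return QAOPModel(dm, spec or ModelSpec())


def log_joint_density(params: dict, dm: DesignMatrices, spec: ModelSpec | None = None) -> float:
    """Log joint density of a complete named-parameter assignment.

    Explicit operation for oracle testing (grid integration, closed-form
    checks); sigma <= 0 yields -inf by contract.
    """
    return build_model(dm, spec).log_joint(params)


def count_parameters(model: QAOPModel) -> BlockCensus:
    """Structural census: named blocks and free scalar parameters."""
    imput = len(model.miss_idx)
    n_latent = sum(rows.size for rows, _ in model.miss_idx.values())
    p1, p2, p3 = model.dm.block_dims
    total_scalars = 2 + p1 + p2 + p3 + imput * 2 + n_latent
    # frozen parameters are not sampled
    frozen_scalars = 0
    for name, val in model.spec.frozen.items():
        frozen_scalars += np.atleast_1d(np.asarray(val, dtype=float)).size
    return BlockCensus(
        hyperprior_blocks=2,
        coefficient_blocks=3,
        likelihood_blocks=4,
        imputation_blocks=imput,
        total_named=9,
        total_scalar_parameters=total_scalars - frozen_scalars,
    )


@dataclass
class PosteriorSamples:
    """MCMC draws of every model unknown plus derived quantities.

    Arrays are indexed (chain, draw, ...).  ``theta`` and ``prob`` have a
    trailing node axis in the order BDNF, SYN, NNF, DNT; the draw-wise
    identity theta[..., 3] == theta[..., 0] + theta[..., 1] + theta[..., 2]
    holds exactly.  ``y_imputed`` holds posterior-predictive Bernoulli draws
    for the missing outcome labels of each key event.
    """

    posterior: dict[str, np.ndarray]
    theta: np.ndarray
    prob: np.ndarray
    y_imputed: dict[str, np.ndarray]  # node -> (chain, draw, n_missing)
    y_obs: dict[str, np.ndarray]  # node -> observed labels (n,)
    y_missing_mask: dict[str, np.ndarray]  # node -> 0/1 mask (n,)
    divergences: tuple[int, ...]  # per chain, post-warmup
    divergent: np.ndarray  # (chain, draw) flags
    accept_stat: np.ndarray
    seed: int
    warmup: int
    target_accept: float
    compound_names: tuple[str, ...] = ()

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    @property
    def n_compounds(self) -> int:
        return self.theta.shape[2]

    def prob_node(self, node: str) -> np.ndarray:
        return self.prob[..., NODES.index(node)]

    def pointwise_loglik(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """(chain, draw, n_obs) Bernoulli log-likelihoods for observed labels.

        Second element names each column as (node, compound_index).
        """
        cols, labels = [], []
        for k, node in enumerate(NODES):
            obs = np.nonzero(self.y_missing_mask[node] == 0)[0]
            theta = self.theta[:, :, obs, k]
            y = self.y_obs[node][obs]
            ll = y * log_inv_logit(theta) + (1 - y) * log_inv_logit(-theta)
            cols.append(ll)
            labels.extend((node, int(i)) for i in obs)
        if not cols:
            return np.empty((self.n_chains, self.n_draws, 0)), []
        return np.concatenate(cols, axis=2), labels

    def to_inferencedata(self):
        """ArviZ InferenceData view (posterior, sample_stats, log_likelihood)."""
        import arviz as az
        import xarray as xr

        coords = {"compound": list(self.compound_names) or list(range(self.n_compounds)), "node": list(NODES)}
        data_vars = {}
        for name, arr in self.posterior.items():
            if arr.ndim == 2:
                data_vars[name] = (("chain", "draw"), arr)
            else:
                dim = f"{name}_dim"
                coords[dim] = list(range(arr.shape[2]))
                data_vars[name] = (("chain", "draw", dim), arr)
        data_vars["theta"] = (("chain", "draw", "compound", "node"), self.theta)
        data_vars["prob"] = (("chain", "draw", "compound", "node"), self.prob)
        posterior = xr.Dataset(data_vars, coords=coords)
        stats = xr.Dataset(
            {
                "diverging": (("chain", "draw"), self.divergent.astype(bool)),
                "acceptance_rate": (("chain", "draw"), self.accept_stat),
            }
        )
        ll, _ = self.pointwise_loglik()
        loglik = xr.Dataset({"obs": (("chain", "draw", "obs_id"), ll)})
        return az.InferenceData(posterior=posterior, sample_stats=stats, log_likelihood=loglik)

    # -- persistence: npz arrays + JSON metadata ---------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"posterior::{k}": v for k, v in self.posterior.items()}
        arrays["theta"] = self.theta
        arrays["prob"] = self.prob
        arrays["divergent"] = self.divergent
        arrays["accept_stat"] = self.accept_stat
        for node in NODES:
            arrays[f"y_obs::{node}"] = self.y_obs[node]
            arrays[f"y_missing_mask::{node}"] = self.y_missing_mask[node]
        for node, arr in self.y_imputed.items():
            arrays[f"y_imputed::{node}"] = arr
        np.savez(path / "arrays.npz", **arrays)
        meta = {
            "seed": self.seed,
            "warmup": self.warmup,
            "target_accept": self.target_accept,
            "divergences": list(self.divergences),
            "node_order": list(NODES),
            "link": LINK,
            "compound_names": list(self.compound_names),
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text(encoding="utf-8"))
        with np.load(path / "arrays.npz") as z:
            arrays = {k: z[k] for k in z.files}
        posterior = {
            k.split("::", 1)[1]: v for k, v in arrays.items() if k.startswith("posterior::")
        }
        y_obs = {n: arrays[f"y_obs::{n}"] for n in NODES}
        y_mask = {n: arrays[f"y_missing_mask::{n}"] for n in NODES}
        y_imp = {
            k.split("::", 1)[1]: v for k, v in arrays.items() if k.startswith("y_imputed::")
        }
        return cls(
            posterior=posterior,
            theta=arrays["theta"],
            prob=arrays["prob"],
            y_imputed=y_imp,
            y_obs=y_obs,
            y_missing_mask=y_mask,
            divergences=tuple(meta["divergences"]),
            divergent=arrays["divergent"],
            accept_stat=arrays["accept_stat"],
            seed=meta["seed"],
            warmup=meta["warmup"],
            target_accept=meta["target_accept"],
            compound_names=tuple(meta.get("compound_names", ())),
        )


def fit_posterior(model: QAOPModel, mcmc: MCMCConfig) -> PosteriorSamples:
    """Sample the posterior by NUTS; returns draws for every unknown.

    Fixed seed implies reproducible draws (chains run sequentially, one rng
    stream per chain).  Convergence is NOT assumed: run the diagnostics module
    on the result.
    """
    if mcmc.seed is None:
        raise ValueError("seed is mandatory")
    ss = np.random.SeedSequence(mcmc.seed)
    chain_seeds = ss.spawn(mcmc.chains + 1)
    results: list[NUTSResult] = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        x0 = model.initial_point(rng)
        res = sample_nuts(
            model.logp_grad,
            x0,
            n_warmup=mcmc.warmup,
            n_draws=mcmc.draws,
            rng=rng,
            target_accept=mcmc.target_accept,
            max_treedepth=mcmc.max_treedepth,
        )
        results.append(res)

    raw = np.stack([r.draws for r in results])  # (chain, draw, dim)
    nchain, ndraw, _ = raw.shape

    posterior: dict[str, np.ndarray] = {}
    for name, size in model.layout:
        arr = raw[:, :, model._slices[name]]
        key = name.replace("log_", "", 1) if name.startswith("log_sigma") else name
        vals = np.exp(arr) if name.startswith("log_sigma") else arr
        posterior[key] = vals[:, :, 0] if size == 1 else vals
    for name, val in model.spec.frozen.items():
        v = np.atleast_1d(np.asarray(val, dtype=float))
        tiled = np.broadcast_to(v, (nchain, ndraw, v.size)).copy()
        posterior[name] = tiled[:, :, 0] if v.size == 1 else tiled
    # natural-scale views of the non-centered draws
    mu_d, sg_d = posterior["mu"], posterior["sigma"]
    for b in BLOCKS:
        rawname = f"beta_raw_{b}"
        if rawname in posterior:
            rb = posterior.pop(rawname)
            if rb.ndim == 2:
                rb = rb[:, :, None]
            posterior[f"beta_{b}"] = mu_d[:, :, None] + sg_d[:, :, None] * rb
    for b in model.miss_idx:
        zname = f"zmiss_{b}"
        if zname in posterior:
            z = posterior.pop(zname)
            if z.ndim == 2:
                z = z[:, :, None]
            mm = posterior[f"mu_xmiss_{b}"][:, :, None]
            sm = posterior[f"sigma_xmiss_{b}"][:, :, None]
            posterior[f"xmiss_{b}"] = mm + sm * z

    # derived theta/prob draws, filling imputed X cells per draw
    n = model.dm.n
    theta = np.zeros((nchain, ndraw, n, 4))
    if n:
        c_blocks = {}
        betas = {}
        for b, x in zip(BLOCKS, (model.dm.x_bdnf, model.dm.x_syn, model.dm.x_nnf)):
            beta = posterior[f"beta_{b}"]
            if beta.ndim == 2:  # p == 1
                beta = beta[:, :, None]
            betas[b] = beta
            c_blocks[b] = np.einsum("cdp,np->cdn", beta, x)
            if b in model.miss_idx:
                rows, cols = model.miss_idx[b]
                xm = posterior[f"xmiss_{b}"]
                if xm.ndim == 2:
                    xm = xm[:, :, None]
                for k in range(rows.size):
                    c_blocks[b][:, :, rows[k]] += betas[b][:, :, cols[k]] * xm[:, :, k]
        t = compute_theta_chain(c_blocks["bdnf"], c_blocks["syn"], c_blocks["nnf"])
        theta = np.stack(t, axis=-1)
    prob = inv_logit(theta)

    # posterior-predictive draws for missing outcome labels
    pp_rng = np.random.default_rng(chain_seeds[-1])
    y_imputed = {}
    ys = model.dm.y_vectors()
    for k, node in enumerate(NODES[:3]):
        _, mask = ys[node]
        miss = np.nonzero(mask)[0]
        if miss.size:
            p = prob[:, :, miss, k]
            y_imputed[node] = (pp_rng.random(p.shape) < p).astype(np.int8)

    return PosteriorSamples(
        posterior=posterior,
        theta=theta,
        prob=prob,
        y_imputed=y_imputed,
        y_obs={node: ys[node][0].astype(np.int8) for node in NODES},
        y_missing_mask={node: ys[node][1].astype(np.int8) for node in NODES},
        divergences=tuple(r.divergences for r in results),
        divergent=np.stack(
            [np.asarray(r.divergent, dtype=bool) for r in results]
        ),
        accept_stat=np.stack([r.accept_stat for r in results]),
        seed=mcmc.seed,
        warmup=mcmc.warmup,
        target_accept=mcmc.target_accept,
        compound_names=model.dm.compound_names,
    )
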