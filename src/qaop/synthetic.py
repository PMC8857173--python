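"""Synthetic compound datasets drawn from the model's own generative process.

The generator emulates the study design the analysis assumes: per-compound
physicochemical/ADMET predictors and two in vitro assay blocks, binary key
event and adverse-outcome labels generated through the chained logistic
model, and missing-completely-at-random (MCAR) gaps mimicking the real
evidence base (sparse literature BDNF labels, in silico predictions absent
for inorganics, assay inactives treated as missing).  Raw columns are written
on natural scales (µM ECs, percent-like viabilities) so a generated CSV looks
like real data; the true linear predictors are computed from the same
standardized design matrices the fitter will build, keeping generator and
inference exactly consistent.
"""

from __future__ import annotations

import json
from copy import deepcopy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._link import LINK, inv_logit
from .dataset import (
    COLUMNS,
    CompoundRecord,
    DNTDataset,
    PredictorAssignment,
    TEXT_COLUMNS,
    _COL2ATTR,
    build_design_matrices,
    write_dataset,
)
from .model import compute_theta_chain

__all__ = [
    "GeneratorConfig",
    "TrueParameters",
    "DEFAULT_MISSINGNESS",
    "simulate_dataset",
    "simulate_study",
    "apply_missingness",
    "write_fixture",
]

NODES = ("bdnf", "syn", "nnf", "dnt")

#: Default MCAR rates emulating the real evidence base: literature BDNF labels
#: exist for a minority of compounds; in silico ADMET predictions are absent
#: for inorganics; in vitro "inactive" results are treated as missing.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "bdnf_label": 0.55,
    "logd": 0.08,
    "bbb": 0.08,
    "cbrain_cblood": 0.08,
    "pgp_substrate": 0.08,
    "pgp_inhibitor": 0.08,
    "pgp_active": 0.08,
    "syn_label": 0.10,
    "syn_viability": 0.12,
    "syn_ec30_um": 0.12,
    "nnf_label": 0.10,
    "nnf_viability": 0.12,
    "nnf_ec50min_um": 0.12,
    "nnf_ec50max_um": 0.12,
}

# natural-scale (location, scale) used to turn standard-normal draws into
# plausible raw values; EC columns are drawn on the log10 scale
_RAW_SCALES = {
    "logd": (2.0, 2.0),  # LogD at pH 7.4, unitless
    "cbrain_cblood": (-0.3, 0.8),  # log10 of the brain/blood ratio
    "syn_viability": (75.0, 20.0),  # percent of control ATP
    "syn_ec30_um": (0.8, 1.0),  # log10 µM
    "nnf_viability": (70.0, 20.0),
    "nnf_ec50min_um": (0.5, 0.9),  # log10 µM
}


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated dataset.

    ``true_beta`` maps block name ('bdnf','syn','nnf') to an explicit
    coefficient vector; absent blocks are drawn from Normal(true_mu,
    true_sigma).  ``missingness`` maps CSV column -> MCAR rate in [0,1]
    (``dnt_label`` must stay 0: every compound carries an in vivo label).
    """

    n_compounds: int = 60
    true_mu: float = 0.0
    true_sigma: float = 0.5
    true_beta: dict[str, list[float]] | None = None
    assignment: PredictorAssignment = field(default_factory=PredictorAssignment)
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 2:
            raise ValueError("n_compounds must be >= 2 (standardization needs variance)")
        if self.true_sigma <= 0:
            raise ValueError("true_sigma must be positive")
        for col, rate in self.missingness.items():
            if col not in COLUMNS or col in TEXT_COLUMNS:
                raise ValueError(f"missingness rate for unknown/text column '{col}'")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for '{col}' outside [0,1]")
            if col == "dnt_label" and rate > 0:
                raise ValueError("dnt_label cannot be missing (AO label is mandatory)")


@dataclass
class TrueParameters:
    """Ground truth behind one simulated dataset, for recovery experiments."""

    mu: float
    sigma: float
    beta_bdnf: np.ndarray
    beta_syn: np.ndarray
    beta_nnf: np.ndarray
    theta: np.ndarray  # (n, 4) linear predictors, node order bdnf/syn/nnf/dnt
    prob: np.ndarray  # (n, 4) = inv_logit(theta)

    def beta(self, block: str) -> np.ndarray:
        return getattr(self, f"beta_{block}")

    def to_json(self) -> str:
        d = {
            "link": LINK,
            "mu": self.mu,
            "sigma": self.sigma,
            "beta_bdnf": self.beta_bdnf.tolist(),
            "beta_syn": self.beta_syn.tolist(),
            "beta_nnf": self.beta_nnf.tolist(),
            "node_order": list(NODES),
            "theta": self.theta.tolist(),
            "prob": self.prob.tolist(),
        }
        return json.dumps(d, indent=1)


def _draw_records(n: int, rng: np.random.Generator) -> list[CompoundRecord]:
    records = []
    for i in range(n):
        z = {c: rng.normal() for c in _RAW_SCALES}
        lmin = _RAW_SCALES["nnf_ec50min_um"][0] + 0.9 * z["nnf_ec50min_um"]
        spread = abs(rng.normal(0.0, 0.5))
        records.append(
            CompoundRecord(
                name=f"synthetic-{i + 1:03d}",
                cas_rn=f"99999-{i + 1:03d}-0",
                smiles=None,
                dtxsid=None,
                dnt_label=0,  # filled in after the model run
                logd=_RAW_SCALES["logd"][0] + _RAW_SCALES["logd"][1] * z["logd"],
                bbb=int(rng.integers(0, 2)),
                cbrain_cblood=10.0
                ** (
                    _RAW_SCALES["cbrain_cblood"][0]
                    + _RAW_SCALES["cbrain_cblood"][1] * z["cbrain_cblood"]
                ),
                pgp_substrate=int(rng.integers(0, 2)),
                pgp_inhibitor=int(rng.integers(0, 2)),
                pgp_active=int(rng.integers(0, 2)),
                bdnf_label=0,
                syn_label=0,
                syn_viability=_RAW_SCALES["syn_viability"][0]
                + _RAW_SCALES["syn_viability"][1] * z["syn_viability"],
                syn_ec30=10.0
                ** (
                    _RAW_SCALES["syn_ec30_um"][0]
                    + _RAW_SCALES["syn_ec30_um"][1] * z["syn_ec30_um"]
                ),
                nnf_label=0,
                nnf_viability=_RAW_SCALES["nnf_viability"][0]
                + _RAW_SCALES["nnf_viability"][1] * z["nnf_viability"],
                nnf_ec50min=10.0**lmin,
                nnf_ec50max=10.0 ** (lmin + spread),
            )
        )
    return records


def simulate_dataset(cfg: GeneratorConfig) -> tuple[DNTDataset, TrueParameters]:
    """Draw a complete dataset from the generative model.

    Predictors are drawn on natural scales; the linear-predictor chain is
    evaluated on the standardized design matrices (the fitter's view), and the
    four binary outcomes are Bernoulli draws through the shared logit link.
    Identical seed => bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records = _draw_records(cfg.n_compounds, rng)
    ds = DNTDataset(records, provenance=f"simulated (seed={cfg.seed})")
    dm = build_design_matrices(ds, cfg.assignment)

    betas = {}
    for block, p in zip(("bdnf", "syn", "nnf"), dm.block_dims):
        if cfg.true_beta and block in cfg.true_beta:
            b = np.asarray(cfg.true_beta[block], dtype=float)
            if b.shape != (p,):
                raise ValueError(f"true_beta['{block}'] must have length {p}")
        else:
            b = rng.normal(cfg.true_mu, cfg.true_sigma, size=p)
        betas[block] = b

    c1 = dm.x_bdnf @ betas["bdnf"]
    c2 = dm.x_syn @ betas["syn"]
    c3 = dm.x_nnf @ betas["nnf"]
    theta = np.column_stack(compute_theta_chain(c1, c2, c3))
    prob = inv_logit(theta)
    y = (rng.random(prob.shape) < prob).astype(int)
    for i, r in enumerate(records):
        r.bdnf_label = int(y[i, 0])
        r.syn_label = int(y[i, 1])
        r.nnf_label = int(y[i, 2])
        r.dnt_label = int(y[i, 3])
    true = TrueParameters(
        mu=cfg.true_mu,
        sigma=cfg.true_sigma,
        beta_bdnf=betas["bdnf"],
        beta_syn=betas["syn"],
        beta_nnf=betas["nnf"],
        theta=theta,
        prob=prob,
    )
    return ds, true


def apply_missingness(
    ds: DNTDataset, rates: dict[str, float], seed: int
) -> DNTDataset:
    """Blank each eligible cell independently with its column's MCAR rate.

    Returns a new dataset; ``dnt_label`` is never blanked (a positive rate for
    it is a config error).
    """
    for col, rate in rates.items():
        if col not in COLUMNS or col in TEXT_COLUMNS:
            raise ValueError(f"missingness rate for unknown/text column '{col}'")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for '{col}' outside [0,1]")
        if col == "dnt_label" and rate > 0:
            raise ValueError("dnt_label cannot be made missing")
    rng = np.random.default_rng(seed)
    out = deepcopy(ds)
    # iterate columns in schema order so the draw sequence is reproducible
    for col in COLUMNS:
        rate = rates.get(col, 0.0)
        if rate <= 0.0:
            continue
        blank = rng.random(len(out)) < rate
        for i, r in enumerate(out.records):
            if blank[i]:
                setattr(r, _COL2ATTR[col], None)
    out.provenance = ds.provenance + f"; MCAR missingness applied (seed={seed})"
    return out


def simulate_study(cfg: GeneratorConfig) -> tuple[DNTDataset, TrueParameters]:
    """Complete draw + the config's MCAR missingness, in one call."""
    ds, true = simulate_dataset(cfg)
    if cfg.missingness:
        # derived stream, kept below 2**31 for external seed contracts
        ds = apply_missingness(ds, cfg.missingness, seed=(cfg.seed + 1) % (2**31))
    return ds, true


def write_fixture(
    ds: DNTDataset, path: str | Path, true: TrueParameters | None = None
) -> Path:
    """Write the CSV fixture (and ground truth JSON alongside, if given)."""
    path = Path(path)
    write_dataset(ds, path)
    if true is not None:
        path.with_suffix(".true.json").write_text(true.to_json(), encoding="utf-8")
    return path
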