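"""The single link shared by the data generator and the fitter.

The chained linear predictors live on the logit scale; every Bernoulli node
uses probability inv_logit(theta).  Generator and model import this module so
they cannot drift apart.
"""

from __future__ import annotations

import numpy as np

LINK = "logit"


def inv_logit(x):
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def log_inv_logit(x):
    """log(inv_logit(x)) = -log1p(exp(-x)), stable for large |x|."""
    x = np.asarray(x, dtype=float)
    return -np.logaddexp(0.0, -x)
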