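"""Background correction and M-value computation for two-colour arrays.

Observed foreground intensity is modelled as the convolution X = B + S of a
normal background B ~ N(mu, sigma^2) and an exponential true signal S with
mean alpha (the "normexp" model).  Correction replaces each observed value by
the conditional expectation E[S | X = x], which is strictly positive, so the
log-ratio M = log2(red/green) is finite everywhere.

M is oriented so that it always means log2(polysome/subpolysome): arrays
hybridised with the dyes swapped have their M negated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr

logger = logging.getLogger(__name__)

GROUPS = ("tumour", "control")


@dataclass
class ArrayExperiment:
    """Probe x array two-channel intensity container.

    ``red`` / ``green`` are probe x array DataFrames of foreground
    intensities with identical index (probe ids) and columns (array ids).
    ``meta`` is indexed by array id with columns ``group`` (tumour/control),
    ``sample_id``, ``replicate`` and ``dye_swap`` (bool).
    """

    red: pd.DataFrame
    green: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.red.index.equals(self.green.index):
            raise ValueError("red/green probe ordering differs")
        if list(self.red.columns) != list(self.green.columns):
            raise ValueError("red/green array columns differ")
        missing = set(self.red.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"arrays missing from metadata: {sorted(missing)}")
        if (self.red.values < 0).any() or (self.green.values < 0).any():
            raise ValueError("negative intensities")
        groups = set(self.meta.loc[list(self.red.columns), "group"])
        if not {"tumour", "control"} <= groups:
            raise ValueError("need at least one tumour and one control array")

    @property
    def array_ids(self) -> list[str]:
        return list(self.red.columns)


@dataclass
class NormexpParams:
    """Parameters of the normal + exponential convolution model."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")


@dataclass
class MValueTable:
    """Gene x array matrix of log2(polysome/subpolysome) values."""

    values: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("non-finite M values")

    @property
    def tumour_arrays(self) -> list[str]:
        m = self.meta.loc[list(self.values.columns)]
        return list(m.index[m["group"] == "tumour"])

    @property
    def control_arrays(self) -> list[str]:
        m = self.meta.loc[list(self.values.columns)]
        return list(m.index[m["group"] == "control"])


def fit_normexp(intensities: np.ndarray) -> NormexpParams:
    """Method-of-moments fit of the normexp model to one channel.

    With X = B + S, B ~ N(mu, sigma^2), S ~ Exp(mean alpha), the third
    central moment of X is 2*alpha^3 (the normal part is symmetric), the
    variance is sigma^2 + alpha^2 and the mean is mu + alpha.  If the implied
    sigma^2 is non-positive the background is taken as nearly degenerate:
    sigma = 0.1*alpha and mu re-derived from the mean.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 50:
        raise ValueError(f"need >= 50 intensities, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite intensities")
    if (x < 0).any():
        raise ValueError("negative intensities")
    var = float(np.var(x, ddof=1))
    if var <= 0:
        raise ValueError("zero variance: cannot fit normexp")
    m3 = float(stats.moment(x, moment=3))
    if m3 <= 0:
        raise ValueError(
            "non-positive third central moment: no exponential signal component"
        )
    alpha = (m3 / 2.0) ** (1.0 / 3.0)
    sigma2 = var - alpha**2
    if sigma2 <= 0:
        sigma = 0.1 * alpha
    else:
        sigma = float(np.sqrt(sigma2))
    mu = float(np.mean(x)) - alpha
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)


def normexp_correct(x, params: NormexpParams):
    """Conditional expected signal E[S | X = x] under the normexp model.

    Returns ``m + sigma * phi(m/sigma) / Phi(m/sigma)`` with
    ``m = x - mu - sigma^2/alpha``; the Mills-ratio term is evaluated in log
    space so the result stays strictly positive down to very low intensities.
    Monotone nondecreasing in x.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite intensity passed to normexp_correct")
    mu, sigma, alpha = params.mu, params.sigma, params.alpha
    m = x - mu - sigma**2 / alpha
    z = m / sigma
    # log(phi(z)) - log(Phi(z)); log_ndtr is stable for z << 0
    log_mills = stats.norm.logpdf(z) - log_ndtr(z)
    out = m + sigma * np.exp(log_mills)
    # guard the far-left tail where m + sigma*mills underflows to ~0
    tiny = np.finfo(float).tiny
    out = np.maximum(out, tiny)
    return out if out.ndim else float(out)


def fit_channel_params(exp: ArrayExperiment) -> dict[str, dict[str, NormexpParams]]:
    """One NormexpParams per channel per array (dye-specific background)."""
    params: dict[str, dict[str, NormexpParams]] = {}
    for aid in exp.array_ids:
        params[aid] = {
            "red": fit_normexp(exp.red[aid].values),
            "green": fit_normexp(exp.green[aid].values),
        }
        logger.debug("normexp fit %s: %s", aid, params[aid])
    return params


def compute_m_values(
    exp: ArrayExperiment,
    params: dict[str, dict[str, NormexpParams]] | None = None,
    probe_gene_map: pd.Series | None = None,
    center: bool = False,
) -> MValueTable:
    """Background-correct both channels and return the M-value table.

    M = log2(corrected red / corrected green), negated for dye-swapped
    arrays so that M always reads log2(polysome/subpolysome).  Probes mapping
    to the same gene are averaged (arithmetic mean of M); the default
    probe->gene map is the identity.
    """
    if params is None:
        params = fit_channel_params(exp)
    required = {"group", "dye_swap"}
    if not required <= set(exp.meta.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    m_cols = {}
    for aid in exp.array_ids:
        r = normexp_correct(exp.red[aid].values, params[aid]["red"])
        g = normexp_correct(exp.green[aid].values, params[aid]["green"])
        m = np.log2(r / g)
        if bool(exp.meta.loc[aid, "dye_swap"]):
            m = -m
        m_cols[aid] = m
    mtab = pd.DataFrame(m_cols, index=exp.red.index)
    if probe_gene_map is not None:
        mtab = mtab.groupby(probe_gene_map.reindex(mtab.index)).mean()
    mtab.index.name = "gene"
    if center:
        mtab = mtab - mtab.mean(axis=0)
    return MValueTable(values=mtab, meta=exp.meta.copy())
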