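"""Sloan neutral community model: occurrence frequency vs. pool abundance.

The model treats each local community as N individuals renewed by
deaths, with immigration from a metacommunity where taxon i has relative
abundance p_i.  Its prediction for the probability that taxon i is
detected (at detection limit d, one read by default) is

    f_pred_i = 1 - I_d(N*m*p_i, N*m*(1-p_i))

with I the regularized incomplete beta function.  The composite
parameter N*m is fitted by nonlinear least squares of f_pred against the
observed occurrence frequencies.

Two immigration scales are reported.  ``m_sloan`` is the fitted
parameter on the model's own scale (the scale the canonical R
implementation prints).  ``m`` is the per-death immigration probability
of the underlying urn process, obtained from the exact stationary
correspondence I = m*(N-1)/(1-m) of the Moran-with-immigration chain,
i.e. m = N*m_sloan / (N*m_sloan + N - 1).  The two agree closely for
small immigration and diverge as m_sloan approaches 1; reporting the urn
scale makes the estimate directly comparable to a forward simulator's
immigration probability across the whole range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from .containers import CommunityTable


@dataclass
class NeutralFit:
    """Fitted neutral model and per-taxon classification."""

    m: float
    m_sloan: float
    N: int
    r_squared: float
    n_samples: int
    taxa: pd.DataFrame  # p, f_obs, f_pred, envelope_lo, envelope_hi, partition
    boundary_hit: bool = False

    def summary(self) -> dict:
        return {
            "m": self.m,
            "m_sloan": self.m_sloan,
            "N": self.N,
            "r_squared": self.r_squared,
            "n_samples": self.n_samples,
            "n_taxa": len(self.taxa),
            "boundary_hit": self.boundary_hit,
        }


def predict_occurrence(p: np.ndarray, m_sloan: float, N: int, d: float) -> np.ndarray:
    """Detection probability under the neutral model at pool abundance p."""
    p = np.asarray(p, dtype=float)
    a = N * m_sloan * p
    b = N * m_sloan * (1.0 - p)
    return 1.0 - beta_dist.cdf(d, np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def _binomial_envelope(f: np.ndarray, n: int, level: float = 0.95):
    """95% envelope of observed occurrence given predicted frequency f.

    Quantiles of the exact binomial sampling distribution over n
    samples; respects the discreteness of occurrence at k/n, which a
    normal-approximation (Wilson) band does not at the boundaries.
    """
    alpha = (1.0 - level) / 2.0
    lo = binom.ppf(alpha, n, np.clip(f, 0.0, 1.0)) / n
    hi = binom.ppf(1.0 - alpha, n, np.clip(f, 0.0, 1.0)) / n
    # discrete quantiles can exclude the expectation at the boundaries
    return np.minimum(lo, f), np.maximum(hi, f)


def fit_neutral(
    table: CommunityTable,
    *,
    detection_limit: float | None = None,
    metacommunity_p: np.ndarray | None = None,
    method: str = "least_squares",
) -> NeutralFit:
    """Fit the neutral model to an equal-depth community table.

    p_i is the mean over samples of relative abundance (or an explicit
    regional pool via ``metacommunity_p``); f_obs_i the fraction of
    samples where the taxon is detected.  The search for the immigration
    parameter is bracketed in (1e-6, 1] on the model scale; boundary
    hits are flagged.  ``method='binomial_ml'`` maximizes the binomial
    likelihood of detections instead of least squares.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples to fit the neutral model")
    depths = table.depths
    if len(set(depths.tolist())) != 1:
        raise ValueError(
            "neutral model assumes one fixed community size; rarefy to equal "
            f"depth first (depths span {depths.min()}..{depths.max()})"
        )
    N = int(depths[0])
    d = 1.0 / N if detection_limit is None else float(detection_limit)
    rel = table.relative_abundance()
    p = rel.mean(axis=0) if metacommunity_p is None else np.asarray(metacommunity_p)
    f_obs = (table.counts > 0).mean(axis=0)
    n = table.n_samples

    if np.allclose(f_obs, 1.0):
        warnings.warn("all taxa at occurrence 1: R^2 undefined (degenerate SST)")

    if method == "least_squares":
        def objective(ms: float) -> float:
            return float(np.sum((f_obs - predict_occurrence(p, ms, N, d)) ** 2))
    elif method == "binomial_ml":
        k = (table.counts > 0).sum(axis=0)

        def objective(ms: float) -> float:
            fp = np.clip(predict_occurrence(p, ms, N, d), 1e-12, 1 - 1e-12)
            return float(-np.sum(k * np.log(fp) + (n - k) * np.log(1 - fp)))
    else:
        raise ValueError(f"unknown method: {method!r}")

    res = minimize_scalar(objective, bounds=(1e-6, 1.0), method="bounded",
                          options={"xatol": 1e-9})
    m_sloan = float(res.x)
    boundary = m_sloan > 1.0 - 1e-4 or m_sloan < 2e-6
    if boundary:
        warnings.warn(f"immigration estimate at search boundary (m_sloan={m_sloan:.4g})")

    f_pred = predict_occurrence(p, m_sloan, N, d)
    ssr = float(np.sum((f_obs - f_pred) ** 2))
    sst = float(np.sum((f_obs - f_obs.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")

    lo, hi = _binomial_envelope(f_pred, n)
    partition = np.where(
        f_obs < lo - 1e-9, "below", np.where(f_obs > hi + 1e-9, "above", "neutral")
    )
    taxa = pd.DataFrame(
        {
            "p": p,
            "f_obs": f_obs,
            "f_pred": f_pred,
            "envelope_lo": lo,
            "envelope_hi": hi,
            "partition": partition,
        },
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    )
    m_urn = N * m_sloan / (N * m_sloan + N - 1.0)
    return NeutralFit(
        m=m_urn,
        m_sloan=m_sloan,
        N=N,
        r_squared=r2,
        n_samples=n,
        taxa=taxa,
        boundary_hit=boundary,
    )


def neutral_outliers(fit: NeutralFit) -> dict[str, pd.DataFrame]:
    """Taxa outside the 95% neutral envelope.

    'below' taxa occur in fewer samples than their pool abundance
    predicts — under a press disturbance these are candidates for taxa
    that were locally successful in only some communities.
    """
    t = fit.taxa
    return {
        "below": t[t["partition"] == "below"].sort_values("p", ascending=False),
        "above": t[t["partition"] == "above"].sort_values("p", ascending=False),
        "neutral": t[t["partition"] == "neutral"],
    }
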