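"""Rejection ABC with optional local-linear regression adjustment.

Parameter draws whose standardized summary statistics fall closest (in
Euclidean distance) to the observed vector are retained; the accepted draws
form the approximate posterior and are summarised by the median and the
2.5/97.5 percent quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .coalescent import (
    CoalescentModelSpec,
    observed_summary,
    simulate_table,
)


@dataclass
class ABCPosterior:
    accepted: pd.DataFrame        # accepted (possibly adjusted) parameter draws
    median: pd.Series
    ci_low: pd.Series             # 2.5% quantile
    ci_high: pd.Series            # 97.5% quantile
    tolerance: float
    n_sims: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(median=self.median, ci_low=self.ci_low, ci_high=self.ci_high)
        )


class RejectionABC(BaseEstimator):
    """sklearn-style rejection-ABC sampler.

    Parameters
    ----------
    tolerance:
        Fraction of simulations accepted (closest by standardized Euclidean
        distance), in (0, 1].
    adjust:
        "none" or "loclinear" (local-linear regression adjustment of the
        accepted draws, Epanechnikov-weighted).

    Call ``fit(params, stats, observed)`` with the simulation table and the
    observed statistic vector; the posterior lands in ``posterior_``.
    """

    def __init__(self, tolerance: float = 0.005, adjust: str = "none"):
        self.tolerance = tolerance
        self.adjust = adjust

    def fit(self, params: pd.DataFrame, stats, observed) -> "RejectionABC":
        if not 0 < self.tolerance <= 1:
            raise ValueError("tolerance must be in (0, 1]")
        if self.adjust not in ("none", "loclinear"):
            raise ValueError("adjust must be none|loclinear")
        params = pd.DataFrame(params).reset_index(drop=True)
        S = np.asarray(stats, dtype=float)
        obs = np.asarray(observed, dtype=float)
        if S.ndim != 2 or S.shape[1] != obs.shape[0]:
            raise ValueError("observed and simulated statistics must share columns")
        # drop simulations with undefined statistics
        ok = np.isfinite(S).all(axis=1)
        S = S[ok]
        params = params.loc[ok].reset_index(drop=True)
        sd = S.std(axis=0, ddof=0)
        keep_col = sd > 0
        if not keep_col.all():
            warnings.warn("dropping zero-variance summary statistics", stacklevel=2)
        S = S[:, keep_col]
        obs_k = obs[keep_col]
        sd = sd[keep_col]
        dist = np.sqrt((((S - obs_k) / sd) ** 2).sum(axis=1))
        n_keep = max(1, int(round(self.tolerance * len(dist))))
        idx = np.argsort(dist, kind="stable")[:n_keep]
        acc = params.iloc[idx].reset_index(drop=True)
        if self.adjust == "loclinear":
            if n_keep <= S.shape[1] + 1:
                warnings.warn(
                    "too few accepted draws for local-linear adjustment; "
                    "returning unadjusted rejection sample", stacklevel=2,
                )
            else:
                acc = self._loclinear(acc, (S[idx] - obs_k) / sd, dist[idx])
        self.accepted_ = acc
        self.distances_ = dist[idx]
        self.posterior_ = ABCPosterior(
            accepted=acc,
            median=acc.median(),
            ci_low=acc.quantile(0.025),
            ci_high=acc.quantile(0.975),
            tolerance=self.tolerance,
            n_sims=int(len(dist)),
        )
        return self

    @staticmethod
    def _loclinear(acc: pd.DataFrame, dS: np.ndarray, dist: np.ndarray) -> pd.DataFrame:
        """theta* = theta - b^T (s - s_obs), weighted by an Epanechnikov
        kernel on the acceptance distances.  Strictly positive parameters
        are regressed on the log scale (standard for rate-like parameters
        with log-uniform priors) and exponentiated back."""
        d_max = dist.max() if dist.max() > 0 else 1.0
        w = 1.0 - (dist / d_max) ** 2
        w = np.maximum(w, 1e-8)
        X = np.column_stack([np.ones(len(dS)), dS])
        W = np.sqrt(w)[:, None]
        out = {}
        for col in acc.columns:
            y = acc[col].to_numpy(dtype=float)
            logscale = (y > 0).all()
            ty = np.log(y) if logscale else y
            coef, *_ = np.linalg.lstsq(X * W, ty * W[:, 0], rcond=None)
            adj = ty - dS @ coef[1:]
            out[col] = np.exp(adj) if logscale else adj
        return pd.DataFrame(out)


def abc_reject(
    observed,
    params: pd.DataFrame,
    stats,
    tolerance: float = 0.005,
    adjust: str = "none",
) -> ABCPosterior:
    """Functional wrapper over :class:`RejectionABC`."""
    est = RejectionABC(tolerance=tolerance, adjust=adjust).fit(params, stats, observed)
    return est.posterior_


def estimate_migration(
    observed,
    spec: CoalescentModelSpec,
    n_sims: int,
    tolerance: float,
    seed: int,
    adjust: str = "none",
    table: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> ABCPosterior:
    """Posterior for the asymmetric scaled migration rates of an IM model.

    A pre-simulated reference ``table`` can be supplied to amortise the
    simulation cost across several observed datasets.
    """
    if spec.model != "IM":
        raise ValueError("migration estimation needs the IM model")
    params, stats = table if table is not None else simulate_table(spec, n_sims, seed)
    return abc_reject(observed, params, np.asarray(stats), tolerance, adjust)


def estimate_divergence_time(
    observed,
    spec_SI: CoalescentModelSpec,
    n_sims: int,
    tolerance: float,
    seed: int,
    adjust: str = "none",
    table: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> ABCPosterior:
    """Posterior for T_split (coalescent units of 4 N_ref generations)
    under strict isolation."""
    if spec_SI.model != "SI":
        raise ValueError("divergence-time estimation uses the SI model")
    params, stats = table if table is not None else simulate_table(spec_SI, n_sims, seed)
    return abc_reject(observed, params, np.asarray(stats), tolerance, adjust)


def convert_coalescent_time(tau: float, N_ref: float, gen_time_years: float) -> float:
    """Divergence time in years: tau * 4 * N_ref * generation time."""
    if tau < 0 or N_ref < 0 or gen_time_years < 0:
        raise ValueError("inputs must be >= 0")
    return tau * 4.0 * N_ref * gen_time_years


def pseudo_observed(spec: CoalescentModelSpec, seed: int) -> np.ndarray:
    """Summary vector of one dataset simulated at the spec's parameters."""
    return observed_summary(spec, seed)
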