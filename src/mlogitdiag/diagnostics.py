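"""Outlier and influence diagnostics for the fitted multinomial logit.

Per observation (one child, single-trial data, m_i = 1):

* Pearson cell residuals  r_ij = (y_ij - pi_ij) / sqrt(pi_ij), giving both
  a full n x J matrix and scalar summaries per record;
* squared deviance residual  d2_i = -2 log pi_i,observed;
* leverage h_ii, the record's share of the trace of the weighted hat
  matrix H = V^(1/2) X (X'VX)^(-1) X' V^(1/2) built on the stacked
  (J-1)-row-per-record multinomial design with per-record blocks
  V_i = w_i (diag(pi) - pi pi');
* generalized Cook's distance  r_i^2 h_ii / (1 - h_ii)^2.

Cluster-level screening averages d2 and the Cook's distances within each
cluster with an (n_c - 1) denominator (the local-mean convention, which
exceeds the arithmetic mean by n_c/(n_c - 1)), then flags clusters either
by rank (top-k) or by a robust modified z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ClusterDiagnostics",
    "ObsDiagnostics",
    "cluster_mean_cookd",
    "cluster_mean_deviance",
    "compute_cluster_diagnostics",
    "compute_obs_diagnostics",
    "cooks_distance",
    "deviance_residuals",
    "flag_clusters",
    "flag_univariate",
    "leverage",
    "pearson_residuals",
]

#: Default cutoffs: |residual| beyond 2.5 is an outlier; Cook's distance
#: beyond 1 is influential.
RESIDUAL_CUTOFF = 2.5
COOKD_CUTOFF = 1.0


def _indicator(y_idx, J):
    return (y_idx[:, None] == np.arange(J)[None, :]).astype(float)


def pearson_residuals(fit, trial_count="one"):
    """Pearson residual matrix and the observed-cell vector.

    With ``trial_count="one"`` (the default, appropriate for one row per
    child) the cell residual is (y_ij - pi_ij)/sqrt(pi_ij). The
    ``"category_total"`` variant replaces the single trial with the
    category total n_j and is provided only for comparison; it does not
    yield per-child quantities on a common scale.
    """
    P = np.asarray(fit.fitted_probs, dtype=float)
    n, J = P.shape
    y_idx = np.asarray(fit.y_idx)
    obs_p = P[np.arange(n), y_idx]
    if (obs_p <= 0).any():
        raise ValidationError(
            "fitted probability 0 at an observed cell (degenerate fit)"
        )
    Y = _indicator(y_idx, J)
    if trial_count == "one":
        m = np.ones((n, J))
    elif trial_count == "category_total":
        m = np.broadcast_to(Y.sum(axis=0, keepdims=True), (n, J)).copy()
    else:
        raise ValidationError(f"unknown trial_count {trial_count!r}")
    denom = np.sqrt(m * P)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(denom > 0, (Y - m * P) / np.where(denom > 0, denom, 1.0),
                     0.0)
    return R, R[np.arange(n), y_idx]


def deviance_residuals(fit):
    """Squared deviance residuals 2 sum_j y_ij log(y_ij/pi_ij).

    With single-trial data and the 0*log 0 = 0 convention this equals
    -2 log(pi at the observed category); strictly decreasing in that
    probability and 0 only for a perfectly fitted record.
    """
    P = np.asarray(fit.fitted_probs, dtype=float)
    n = P.shape[0]
    obs_p = P[np.arange(n), np.asarray(fit.y_idx)]
    if (obs_p <= 0).any():
        raise ValidationError(
            "fitted probability 0 at an observed cell (degenerate fit)"
        )
    return -2.0 * np.log(obs_p)


def leverage(fit):
    """Per-record leverage from the stacked multinomial hat matrix.

    Each record contributes J-1 rows (the non-reference categories); its
    leverage is the sum of the corresponding diagonal entries of H, so the
    leverages add up to the number of free parameters (J-1)(p+1).
    """
    X, w = fit.effective_design
    P = np.asarray(fit.fitted_probs, dtype=float)
    n, p = X.shape
    J = P.shape[1]
    nonref = [j for j in range(J)
              if fit.categories[j] != fit.reference]
    Pn = P[:, nonref]
    # per-record (J-1)x(J-1) covariance blocks, diag(pi) - pi pi'
    V = -Pn[:, :, None] * Pn[:, None, :]
    idx = np.arange(len(nonref))
    V[:, idx, idx] += Pn
    M = np.einsum("i,iab,ik,il->akbl", w, V, X, X, optimize=True)
    K = len(nonref) * p
    M = M.reshape(K, K)
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "singular information matrix; design columns "
            f"{fit.columns} are collinear"
        )
    Minv4 = Minv.reshape(len(nonref), p, len(nonref), p)
    A = np.einsum("ik,akbl,il->iab", X, Minv4, X, optimize=True)
    h = w * np.einsum("iab,iba->i", V, A, optimize=True)
    return np.clip(h, 0.0, None)


def cooks_distance(pearson_scalar, leverage_values):
    """Generalized Cook's distance r^2 h / (1 - h)^2, elementwise."""
    r = np.asarray(pearson_scalar, dtype=float)
    h = np.asarray(leverage_values, dtype=float)
    if r.shape != h.shape:
        raise ValidationError("residual and leverage vectors are misaligned")
    if (h >= 1.0).any():
        raise ValidationError("leverage >= 1 encountered; Cook's distance undefined")
    return (r ** 2) * h / (1.0 - h) ** 2


@dataclass
class ObsDiagnostics:
    """Per-observation diagnostic vectors, aligned with record order."""

    pearson: np.ndarray          # n x J cell residual matrix
    pearson_obs: np.ndarray      # observed-category cell residual
    pearson_chi2: np.ndarray     # per-record chi-square contribution sum_j r_ij^2
    deviance: np.ndarray         # squared deviance residual
    leverage: np.ndarray
    cookd: np.ndarray
    scalar_residual: str = "chi2"

    def to_frame(self, data):
        flags_r, _ = flag_univariate(np.sqrt(self.deviance), kind="residual")
        flags_c, _ = flag_univariate(self.cookd, kind="cookd")
        return pd.DataFrame({
            "child_id": data.records["child_id"].to_numpy(),
            "cluster_id": data.records["cluster_id"].to_numpy(),
            "pearson_obs": self.pearson_obs,
            "pearson_chi2": self.pearson_chi2,
            "deviance": self.deviance,
            "leverage": self.leverage,
            "cookd": self.cookd,
            "outlier_flag": flags_r,
            "influence_flag": flags_c,
        })


def compute_obs_diagnostics(fit, scalar_residual="chi2"):
    """All per-observation diagnostics for a fitted model.

    ``scalar_residual`` selects the r_i^2 entering Cook's distance:
    ``"chi2"`` (default) uses the record's full Pearson chi-square
    contribution sum_j r_ij^2, which reduces exactly to the binary
    logistic r^2 when J = 2; ``"observed"`` uses the observed-cell
    residual alone.
    """
    R, r_obs = pearson_residuals(fit)
    chi2_i = (R ** 2).sum(axis=1)
    d2 = deviance_residuals(fit)
    h = leverage(fit)
    if scalar_residual == "chi2":
        r2 = chi2_i
    elif scalar_residual == "observed":
        r2 = r_obs ** 2
    else:
        raise ValidationError(f"unknown scalar_residual {scalar_residual!r}")
    cook = cooks_distance(np.sqrt(r2), h)
    return ObsDiagnostics(
        pearson=R, pearson_obs=r_obs, pearson_chi2=chi2_i,
        deviance=d2, leverage=h, cookd=cook, scalar_residual=scalar_residual,
    )


# ---------------------------------------------------------------------------
# cluster-level aggregation
# ---------------------------------------------------------------------------

def _cluster_average(values, data, denominator):
    values = np.asarray(values, dtype=float)
    if len(values) != data.n_records:
        raise ValidationError("diagnostic vector and dataset are misaligned")
    cid = data.records["cluster_id"].to_numpy()
    order = data.clusters["cluster_id"].tolist()
    sums = pd.Series(values).groupby(pd.Series(cid)).sum()
    counts = pd.Series(cid).value_counts()
    out = {}
    for c in order:
        n_c = int(counts[c])
        if denominator == "nc_minus_1":
            if n_c < 2:
                raise ValidationError(
                    f"cluster {c!r} has a single record; the (n_c - 1) "
                    "local mean is undefined"
                )
            out[c] = sums[c] / (n_c - 1)
        elif denominator == "nc":
            out[c] = sums[c] / n_c
        else:
            raise ValidationError(f"unknown denominator {denominator!r}")
    return pd.Series(out, name="value")


def cluster_mean_deviance(deviance, data, denominator="nc_minus_1"):
    """Local mean deviance D_c = sum of member d2 over (n_c - 1)."""
    return _cluster_average(deviance, data, denominator).rename("D_c")


def cluster_mean_cookd(cookd, data, denominator="nc_minus_1"):
    """Cluster-averaged Cook's distance, same denominator convention as D_c."""
    return _cluster_average(cookd, data, denominator).rename("mean_cookd")


def flag_univariate(values, kind, threshold=None):
    """Threshold flags for per-observation statistics.

    ``kind="residual"`` flags |value| beyond 2.5; ``kind="cookd"`` flags
    values beyond 1. Returns the boolean vector and a rule record.
    """
    values = np.asarray(values, dtype=float)
    if kind == "residual":
        cut = RESIDUAL_CUTOFF if threshold is None else float(threshold)
        flags = np.abs(values) > cut
    elif kind == "cookd":
        cut = COOKD_CUTOFF if threshold is None else float(threshold)
        flags = values > cut
    else:
        raise ValidationError(f"unknown flag kind {kind!r}")
    rule = {"kind": kind, "rule": ("|value| > %g" % cut) if kind == "residual"
            else ("value > %g" % cut), "threshold": cut}
    return flags, rule


@dataclass
class FlagResult:
    flags: pd.Series
    table: pd.DataFrame
    rule: dict


def flag_clusters(cluster_stats, method="rank_top_k", k=2, z=3.5):
    """Flag unusual clusters by rank or by robust (modified) z-score.

    ``rank_top_k`` flags the k largest values (the screening used when no
    cutoff is asserted and candidates are compared cluster by cluster);
    ``robust_z`` flags 0.6745*(x - median)/MAD > z. A zero MAD makes the
    z-score degenerate, in which case the method falls back to rank_top_k
    with a warning. A ranked table (descending) is always returned.
    """
    s = pd.Series(cluster_stats).astype(float)
    if method == "robust_z":
        if len(s) < 3:
            raise ValidationError("robust_z needs at least 3 clusters")
        med = s.median()
        mad = (s - med).abs().median()
        if mad == 0:
            warnings.warn("zero MAD; falling back to rank_top_k", stacklevel=2)
            return flag_clusters(s, method="rank_top_k", k=k, z=z)
        mz = 0.6745 * (s - med) / mad
        flags = mz > z
        rule = {"method": "robust_z", "z": float(z)}
    elif method == "rank_top_k":
        k = int(k)
        order = s.sort_values(ascending=False, kind="mergesort")
        flags = pd.Series(False, index=s.index)
        flags.loc[order.index[:k]] = True
        rule = {"method": "rank_top_k", "k": k}
    else:
        raise ValidationError(f"unknown flag method {method!r}")
    table = pd.DataFrame({
        "cluster_id": s.index, "value": s.to_numpy(), "flag": flags.to_numpy()
    }).sort_values("value", ascending=False, kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return FlagResult(flags=flags, table=table, rule=rule)


@dataclass
class ClusterDiagnostics:
    """Per-cluster diagnostic summary with reproducible flagging rules."""

    frame: pd.DataFrame
    outlier_rule: dict
    influence_rule: dict
    denominator: str = "nc_minus_1"


def compute_cluster_diagnostics(obs_diag, data, *, method="rank_top_k",
                                k=2, z=3.5, denominator="nc_minus_1"):
    """Aggregate observation diagnostics to clusters and flag the unusual.

    Returns a :class:`ClusterDiagnostics` whose frame carries cluster_id,
    n_c, D_c (local mean deviance), mean_cookd and the two flags.
    """
    D_c = cluster_mean_deviance(obs_diag.deviance, data, denominator)
    mean_cook = cluster_mean_cookd(obs_diag.cookd, data, denominator)
    out = flag_clusters(D_c, method=method, k=k, z=z)
    infl = flag_clusters(mean_cook, method=method, k=k, z=z)
    counts = data.records["cluster_id"].value_counts()
    frame = pd.DataFrame({
        "cluster_id": D_c.index,
        "n_c": [int(counts[c]) for c in D_c.index],
        "D_c": D_c.to_numpy(),
        "mean_cookd": mean_cook.to_numpy(),
        "outlier_flag": out.flags.reindex(D_c.index).to_numpy(),
        "influence_flag": infl.flags.reindex(D_c.index).to_numpy(),
    })
    return ClusterDiagnostics(
        frame=frame, outlier_rule=out.rule, influence_rule=infl.rule,
        denominator=denominator,
    )
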