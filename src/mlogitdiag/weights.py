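"""Sampling weights and finite-population correction for the two-stage design.

Each child in cluster ``c`` carries the design weight ``w_i = N_c / n_c``,
the inverse of the within-cluster sampling fraction (``N_c`` under-five
children in the cluster population, ``n_c`` sampled). Strata enter the
analysis through jackknife variance grouping, not through extra weight
factors. The finite population correction ``sqrt((N - n)/(N - 1))`` is
computed for reporting; with the national population it is essentially 1
and is not applied to the estimates.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import ValidationError


def compute_weights(data):
    """Design weights w_i = N_c / n_c, aligned with record order.

    Raises if any record's cluster is missing from the cluster table or has
    a non-positive sample size.
    """
    clu = data.clusters
    n_c = clu["sample_size"].to_numpy(dtype=float)
    N_c = clu["population_size"].to_numpy(dtype=float)
    bad = (n_c <= 0) | ~np.isfinite(N_c)
    if bad.any():
        cid = clu["cluster_id"].to_numpy()[bad][0]
        raise ValidationError(f"cluster {cid!r} has invalid N_c or n_c")
    per_cluster = dict(zip(clu["cluster_id"], N_c / n_c))
    try:
        w = data.records["cluster_id"].map(per_cluster).to_numpy(dtype=float)
    except Exception as exc:  # pragma: no cover - defensive
        raise ValidationError(str(exc))
    if np.isnan(w).any():
        cid = data.records.loc[np.isnan(w), "cluster_id"].iloc[0]
        raise ValidationError(f"cluster {cid!r} absent from cluster table")
    return w


def compute_fpc(population, sample):
    """Finite population correction sqrt((N - n) / (N - 1)).

    ``1 <= sample <= population`` and ``population >= 2`` are required;
    equals 1 exactly when a single unit is sampled and 0 for a census.
    """
    N, n = int(population), int(sample)
    if N < 2:
        raise ValidationError("population must be at least 2")
    if not 1 <= n <= N:
        raise ValidationError("sample size must lie in [1, population]")
    return math.sqrt((N - n) / (N - 1))


def normalize_weights(w, mode="raw"):
    """Return weights as-is (``raw``) or scaled to mean one (``mean_one``).

    Mean-one scaling does not change the weighted pseudo-likelihood argmax;
    it only stabilises the optimisation scale.
    """
    w = np.asarray(w, dtype=float)
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValidationError("weights must be positive and finite")
    if mode == "raw":
        return w.copy()
    if mode == "mean_one":
        return w / w.mean()
    raise ValidationError(f"unknown weight normalisation mode {mode!r}")
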