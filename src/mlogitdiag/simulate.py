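"""DHS-like synthetic data: two-stage stratified cluster samples with known
coefficients and injectable outlier/influential clusters.

The generator emulates the structure of a national demographic survey
kids-recode extract: clusters (enumeration areas) are assigned to the
urban/rural strata, each contributes a small sample of children, and each
child carries ten categorical socio-demographic covariates plus a
three-level birth-weight outcome drawn from the multinomial logit
probabilities implied by a known coefficient matrix. Cluster population
sizes N_c are synthesised so the design weights N_c/n_c vary across
clusters. Covariate marginals default to the published national
distribution of the ten covariates; outcome intercepts can be calibrated
so overall LBW/NBW/HBW shares match the national 16.61/72.16/11.23 split.

Contamination injects the kind of unusual community reported in field
data: clusters whose children are all of normal-to-high birth weight and
share an atypical covariate signature (first birth order, non-caesarean,
singleton).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .datamodel import (
    COVARIATE_LEVELS,
    OUTCOME_LEVELS,
    ModelSpec,
    SurveyDataset,
)
from .exceptions import ValidationError
from .model import build_design, predict_probs

__all__ = [
    "ContaminationSpec",
    "SyntheticConfig",
    "TABLE1_COVARIATE_COUNTS",
    "TABLE1_OUTCOME_COUNTS",
    "apply_contamination",
    "generate",
    "intercept_calibrated_beta",
    "table1_marginals",
]

#: National outcome counts (n = 11,680): 16.61% / 72.16% / 11.23%.
TABLE1_OUTCOME_COUNTS = {"LBW": 1940, "NBW": 8428, "HBW": 1312}

#: National level counts for the ten covariates. Each map is normalised by
#: its own total when used as a sampling marginal.
TABLE1_COVARIATE_COUNTS = {
    "mother_age_group": {"<20": 962, "20-34": 8478, "35-49": 2240},
    "birth_order": {"1": 2825, "2-3": 4432, "4-5": 2779, "6+": 1644},
    "education": {"none": 1206, "primary": 7529, "secondary": 2703,
                  "higher": 242},
    "wealth": {"poor": 4711, "rich": 2229, "richer": 4740},
    "residence": {"urban": 2164, "rural": 9516},
    "smokes": {"no": 11619, "yes": 61},
    "twin": {"no": 11446, "yes": 234},
    "anc_visits": {"<3": 1389, "3-7": 10084, ">7": 207},
    "sex": {"female": 5932, "male": 5748},
    "caesarean": {"no": 10817, "yes": 827},
}

#: Gram distributions per category: mean, sd and truncation interval kept
#: strictly inside each WHO band so outcome/grams stay consistent.
_GRAM_PARAMS = {
    "LBW": (2150.0, 350.0, 600.0, 2499.9),
    "NBW": (3250.0, 400.0, 2500.0, 4000.0),
    "HBW": (4350.0, 300.0, 4000.1, 5800.0),
}


def table1_marginals():
    """Level-probability vectors (level order as declared) per covariate."""
    out = {}
    for name, counts in TABLE1_COVARIATE_COUNTS.items():
        total = float(sum(counts.values()))
        out[name] = np.array(
            [counts[lv] / total for lv in COVARIATE_LEVELS[name]]
        )
    return out


def intercept_calibrated_beta(spec, counts=None):
    """Coefficient matrix with zero slopes and intercepts set to the log
    share ratios of the national outcome counts against the reference."""
    counts = TABLE1_OUTCOME_COUNTS if counts is None else counts
    n_cols = 1 + sum(
        len(COVARIATE_LEVELS[t]) - 1 for t in spec.terms
    )
    nonref = [c for c in OUTCOME_LEVELS if c != spec.outcome_reference]
    B = np.zeros((len(nonref), n_cols))
    for r, cat in enumerate(nonref):
        B[r, 0] = np.log(counts[cat] / counts[spec.outcome_reference])
    return B


@dataclass
class ContaminationSpec:
    """How and how many clusters to contaminate.

    Modes (combinable by passing a tuple):

    * ``all_normal_high`` — every LBW outcome in the cluster is resampled
      to NBW or HBW in proportion to their overall shares in the dataset;
    * ``covariate_atypical`` — the ``forced_covariates`` (default: first
      birth order, non-caesarean, singleton) overwrite the cluster's
      records;
    * ``category_shift`` — all outcomes in the cluster are redrawn from
      the overall outcome shares with ``shift`` added to the log-shares
      (default pushes strongly toward HBW).
    """

    n_outlier_clusters: int = 2
    mode: object = "all_normal_high"
    forced_covariates: dict = None
    shift: tuple = (0.0, 0.0, 2.0)

    def __post_init__(self):
        if self.n_outlier_clusters < 0:
            raise ValidationError("n_outlier_clusters must be non-negative")
        modes = (self.mode,) if isinstance(self.mode, str) else tuple(self.mode)
        for m in modes:
            if m not in ("all_normal_high", "category_shift",
                         "covariate_atypical"):
                raise ValidationError(f"unknown contamination mode {m!r}")
        self.mode = modes
        if self.forced_covariates is None:
            self.forced_covariates = {
                "birth_order": "1", "caesarean": "no", "twin": "no",
            }
        for name, level in self.forced_covariates.items():
            if name not in COVARIATE_LEVELS:
                raise ValidationError(f"unknown covariate {name!r}")
            if level not in COVARIATE_LEVELS[name]:
                raise ValidationError(
                    f"level {level!r} is not a level of {name!r}"
                )
        if len(self.shift) != len(OUTCOME_LEVELS):
            raise ValidationError("shift needs one entry per outcome category")


@dataclass
class SyntheticConfig:
    """Generator settings (defaults mirror the national survey design)."""

    n_clusters: int = 850
    cluster_size_range: tuple = (7, 25)
    urban_fraction: float = 0.185
    population_multiplier_range: tuple = (50.0, 150.0)
    covariate_marginals: dict = None
    model: ModelSpec = None
    true_beta: np.ndarray = None
    contamination: ContaminationSpec = None
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model is None:
            self.model = ModelSpec(terms=list(COVARIATE_LEVELS))
        marg = table1_marginals()
        if self.covariate_marginals:
            for name, probs in self.covariate_marginals.items():
                if name not in COVARIATE_LEVELS:
                    raise ValidationError(f"unknown covariate {name!r}")
                marg[name] = np.asarray(probs, dtype=float)
        self.covariate_marginals = marg
        if self.true_beta is None:
            self.true_beta = intercept_calibrated_beta(self.model)
        self.true_beta = np.asarray(self.true_beta, dtype=float)

    def validate(self):
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be positive")
        lo, hi = self.cluster_size_range
        if lo < 2 or hi < lo:
            raise ValidationError(
                "cluster_size_range must satisfy 2 <= min <= max (the local "
                "mean deviance divides by n_c - 1)"
            )
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValidationError("urban_fraction must lie in [0, 1]")
        mlo, mhi = self.population_multiplier_range
        if mlo < 1.0 or mhi < mlo:
            raise ValidationError("population_multiplier_range invalid")
        for name, probs in self.covariate_marginals.items():
            probs = np.asarray(probs, dtype=float)
            if (probs < 0).any():
                raise ValidationError(f"negative marginal for {name!r}")
            if len(probs) != len(COVARIATE_LEVELS[name]):
                raise ValidationError(
                    f"marginal for {name!r} has the wrong number of levels"
                )
            if abs(probs.sum() - 1.0) > 1e-12:
                raise ValidationError(
                    f"marginal for {name!r} does not sum to 1"
                )
        n_cols = 1 + sum(len(COVARIATE_LEVELS[t]) - 1 for t in self.model.terms)
        if self.true_beta.shape != (2, n_cols):
            raise ValidationError(
                f"true_beta must have shape (2, {n_cols}) for this model"
            )
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must lie in [0, 1)")
        if (self.contamination is not None
                and self.contamination.n_outlier_clusters >= self.n_clusters):
            raise ValidationError(
                "n_outlier_clusters must be smaller than n_clusters"
            )
        return self


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a = special.ndtr((lo - mean) / sd)
    b = special.ndtr((hi - mean) / sd)
    u = rng.random(size)
    x = mean + sd * special.ndtri(a + u * (b - a))
    return np.clip(x, lo, hi)


def _draw_grams(rng, outcomes):
    grams = np.empty(len(outcomes))
    for cat, (mu, sd, lo, hi) in _GRAM_PARAMS.items():
        mask = outcomes == cat
        if mask.any():
            grams[mask] = _truncated_normal(rng, mu, sd, lo, hi, mask.sum())
    return grams


def generate(config):
    """Generate a synthetic SurveyDataset and the ground truth behind it.

    Returns ``(data, truth)`` where ``truth`` records the true coefficient
    matrix, the contaminated cluster ids (possibly empty) and the seed.
    Identical config and seed give a bit-identical dataset; each cluster
    draws from its own spawned random substream, so contaminating some
    clusters leaves all others byte-for-byte unchanged.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    spawned = ss.spawn(config.n_clusters + 3)
    root = np.random.default_rng(spawned[0])
    rng_outlier = np.random.default_rng(spawned[1])
    rng_missing = np.random.default_rng(spawned[2])
    cluster_seeds = spawned[3:]

    n = config.n_clusters
    cluster_ids = [f"c{i + 1:04d}" for i in range(n)]
    strata = np.where(root.random(n) < config.urban_fraction, "urban", "rural")
    lo, hi = config.cluster_size_range
    sizes = root.integers(lo, hi + 1, size=n)
    mult = root.uniform(*config.population_multiplier_range, size=n)
    N_c = np.maximum(np.rint(mult * sizes).astype(int), sizes)

    spec = config.model
    B = config.true_beta
    ref_idx = OUTCOME_LEVELS.index(spec.outcome_reference)
    marg = config.covariate_marginals

    frames = []
    for c in range(n):
        rng = np.random.default_rng(cluster_seeds[c])
        n_c = int(sizes[c])
        cols = {
            "child_id": [f"{cluster_ids[c]}-{i + 1:03d}" for i in range(n_c)],
            "cluster_id": [cluster_ids[c]] * n_c,
            "stratum": [strata[c]] * n_c,
        }
        for name in COVARIATE_LEVELS:
            levels = COVARIATE_LEVELS[name]
            cols[name] = rng.choice(levels, size=n_c, p=marg[name])
        # residence is a cluster-level trait: tie it to the stratum
        cols["residence"] = [strata[c]] * n_c
        frame = pd.DataFrame(cols)
        # levels can be legitimately absent from a small cluster; the
        # design here only evaluates probabilities, nothing is estimated
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = build_design(frame, spec)
        P = predict_probs(B, design.X, reference=ref_idx, n_categories=3)
        u = rng.random(n_c)
        idx = (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
        outcomes = np.array(OUTCOME_LEVELS, dtype=object)[idx]
        frame["outcome"] = outcomes
        frame["birth_weight_grams"] = _draw_grams(rng, outcomes)
        frames.append(frame)
    records = pd.concat(frames, ignore_index=True)
    clusters = pd.DataFrame({
        "cluster_id": cluster_ids,
        "stratum": strata,
        "population_size": N_c,
        "sample_size": sizes,
    })
    data = SurveyDataset.from_frames(records, clusters, validate=False)

    outlier_ids = []
    if config.contamination is not None and \
            config.contamination.n_outlier_clusters > 0:
        pick = rng_outlier.choice(
            n, size=config.contamination.n_outlier_clusters, replace=False
        )
        outlier_ids = sorted(cluster_ids[i] for i in pick)
        data = apply_contamination(
            data, config.contamination, outlier_ids, seed=config.seed
        )

    if config.missing_fraction > 0:
        m = int(round(config.missing_fraction * data.n_records))
        rows = rng_missing.choice(data.n_records, size=m, replace=False)
        rec = data.records
        rec.loc[rows, "birth_weight_grams"] = np.nan
        rec.loc[rows, "outcome"] = None

    data.validate()
    truth = {
        "true_beta": B.copy(),
        "outlier_ids": list(outlier_ids),
        "model_terms": list(spec.terms),
        "seed": config.seed,
    }
    return data, truth


def apply_contamination(data, spec, cluster_ids, seed):
    """Apply a contamination spec to the named clusters only.

    Every record outside the named clusters is returned unchanged. Each
    contaminated cluster uses its own deterministic substream derived from
    ``seed`` and its position in the (sorted) id list. Gram values are
    redrawn whenever an outcome changes so the WHO-category consistency
    invariant keeps holding.
    """
    known = set(data.clusters["cluster_id"])
    for cid in cluster_ids:
        if cid not in known:
            raise ValidationError(f"unknown cluster id {cid!r}")
    if not cluster_ids:
        return SurveyDataset.from_frames(data.records, data.clusters,
                                         validate=False)
    rec = data.records.copy()
    counts = rec["outcome"].value_counts()
    nbw, hbw = float(counts.get("NBW", 0)), float(counts.get("HBW", 0))
    if nbw + hbw == 0:
        raise ValidationError("dataset has no NBW/HBW outcomes to resample to")
    p_nbw = nbw / (nbw + hbw)
    shares = np.array([counts.get(c, 0) for c in OUTCOME_LEVELS], dtype=float)
    shares = shares / shares.sum()
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5EED])
    streams = ss.spawn(len(cluster_ids))
    for cid, sub in zip(sorted(cluster_ids), streams):
        rng = np.random.default_rng(sub)
        in_c = (rec["cluster_id"] == cid).to_numpy()
        if "covariate_atypical" in spec.mode:
            for name, level in spec.forced_covariates.items():
                rec.loc[in_c, name] = level
        if "category_shift" in spec.mode:
            logits = np.log(shares) + np.asarray(spec.shift, dtype=float)
            p = np.exp(logits - special.logsumexp(logits))
            idx = rng.choice(len(OUTCOME_LEVELS), size=in_c.sum(), p=p)
            new = np.array(OUTCOME_LEVELS, dtype=object)[idx]
            present = rec.loc[in_c, "outcome"].notna().to_numpy()
            rows = np.flatnonzero(in_c)[present]
            rec.loc[rows, "outcome"] = new[present]
            rec.loc[rows, "birth_weight_grams"] = _draw_grams(
                rng, rec.loc[rows, "outcome"].to_numpy(dtype=object)
            )
        if "all_normal_high" in spec.mode:
            is_lbw = in_c & (rec["outcome"] == "LBW").to_numpy()
            if is_lbw.any():
                new = np.where(
                    rng.random(is_lbw.sum()) < p_nbw, "NBW", "HBW"
                ).astype(object)
                rows = np.flatnonzero(is_lbw)
                rec.loc[rows, "outcome"] = new
                rec.loc[rows, "birth_weight_grams"] = _draw_grams(rng, new)
    return SurveyDataset.from_frames(rec, data.clusters, validate=False)
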