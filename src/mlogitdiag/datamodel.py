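"""Domain model for clustered child birth-weight survey data.

The unit of analysis is one child (one row). Children are nested in survey
clusters (enumeration areas), each cluster belonging to one stratum
(urban/rural). Birth weight is analysed as a three-level outcome following
the WHO cut-points: low (< 2,500 g), normal (2,500-4,000 g, boundaries
inclusive) and high (> 4,000 g).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import LinkageError, SchemaError, ValidationError

#: Outcome categories in fixed storage order (category index 1, 2, 3).
OUTCOME_LEVELS = ["LBW", "NBW", "HBW"]

#: Stratum labels of the two-stage stratified design.
STRATA = ["urban", "rural"]

#: The ten socio-demographic covariates and their level sets. The first
#: level of each covariate is its default modelling reference level.
COVARIATE_LEVELS = {
    "mother_age_group": ["<20", "20-34", "35-49"],
    "birth_order": ["1", "2-3", "4-5", "6+"],
    "education": ["none", "primary", "secondary", "higher"],
    "wealth": ["poor", "rich", "richer"],
    "residence": ["urban", "rural"],
    "smokes": ["no", "yes"],
    "twin": ["no", "yes"],
    "anc_visits": ["<3", "3-7", ">7"],
    "sex": ["female", "male"],
    "caesarean": ["no", "yes"],
}

_RECORD_ID_COLS = ["child_id", "cluster_id", "stratum"]
_CLUSTER_COLS = ["cluster_id", "stratum", "population_size", "sample_size"]

#: Tokens treated as missing when reading CSV files.
NA_TOKENS = ["", "NA"]


def categorize_birth_weight(grams):
    """Map birth weight in grams to the WHO category labels.

    Scalar or array input. Weights below 2,500 g are LBW, above 4,000 g are
    HBW and everything in between (boundaries included) is NBW. Missing
    (NaN) weights map to missing outcomes.
    """
    g = np.asarray(grams, dtype=float)
    out = np.full(g.shape, None, dtype=object)
    finite = np.isfinite(g)
    if np.any(g[finite] <= 0):
        raise ValidationError("birth_weight_grams must be positive")
    out[finite & (g < 2500)] = "LBW"
    out[finite & (g >= 2500) & (g <= 4000)] = "NBW"
    out[finite & (g > 4000)] = "HBW"
    if np.ndim(grams) == 0:
        return out.item()
    return pd.array(out, dtype=object)


@dataclass
class ModelSpec:
    """Specification of one multinomial-logit model.

    Parameters
    ----------
    terms : list of str
        Covariate names entering the model, in design-matrix order.
    references : dict, optional
        Reference level per covariate; defaults to the first declared level
        of each covariate (the levels marked as baselines in the source
        survey tabulations).
    outcome_reference : str
        Outcome category used as the model baseline (default ``"LBW"`` so
        coefficients exponentiate to relative risk ratios of NBW and HBW
        versus low birth weight).
    """

    terms: list = field(default_factory=list)
    references: dict = field(default_factory=dict)
    outcome_reference: str = "LBW"
    include_intercept: bool = True

    def __post_init__(self):
        if self.outcome_reference not in OUTCOME_LEVELS:
            raise ValidationError(
                f"unknown outcome reference {self.outcome_reference!r}"
            )
        if not self.include_intercept:
            raise ValidationError("the model always includes an intercept")
        for t in self.terms:
            if t not in COVARIATE_LEVELS:
                raise ValidationError(f"unknown model term {t!r}")
        refs = {}
        for t in self.terms:
            ref = self.references.get(t, COVARIATE_LEVELS[t][0])
            if ref not in COVARIATE_LEVELS[t]:
                raise ValidationError(
                    f"reference level {ref!r} not a level of {t!r}"
                )
            refs[t] = ref
        self.references = refs

    def dropped(self, terms_to_drop):
        """Return a copy of the spec without the named terms."""
        drop = set(terms_to_drop)
        return replace(self, terms=[t for t in self.terms if t not in drop])


@dataclass
class SurveyDataset:
    """A validated, positionally ordered survey sample.

    ``records`` has one row per child (columns: child_id, cluster_id,
    stratum, birth_weight_grams, outcome, then the ten covariates);
    ``clusters`` has one row per cluster (cluster_id, stratum,
    population_size N_c, sample_size n_c). Record order is the alignment
    key for every diagnostic vector computed downstream.
    """

    records: pd.DataFrame
    clusters: pd.DataFrame

    @property
    def n_records(self):
        return len(self.records)

    @property
    def n_clusters(self):
        return len(self.clusters)

    def outcome_codes(self):
        """Outcome as integer codes 0/1/2 = LBW/NBW/HBW; -1 where missing."""
        cat = pd.Categorical(self.records["outcome"], categories=OUTCOME_LEVELS)
        return np.asarray(cat.codes)

    @classmethod
    def from_frames(cls, records, clusters, validate=True):
        records = records.reset_index(drop=True).copy()
        clusters = clusters.reset_index(drop=True).copy()
        if "birth_weight_grams" not in records.columns:
            records["birth_weight_grams"] = np.nan
        records["birth_weight_grams"] = pd.to_numeric(
            records["birth_weight_grams"]
        )
        if "outcome" not in records.columns:
            records["outcome"] = categorize_birth_weight(
                records["birth_weight_grams"].to_numpy(dtype=float)
            )
        data = cls(records=records, clusters=clusters)
        if validate:
            data.validate()
        return data

    def validate(self):
        rec, clu = self.records, self.clusters
        for col in _RECORD_ID_COLS + list(COVARIATE_LEVELS):
            if col not in rec.columns:
                raise SchemaError(f"records table is missing column {col!r}")
        for col in _CLUSTER_COLS:
            if col not in clu.columns:
                raise SchemaError(f"clusters table is missing column {col!r}")

        for name, levels in COVARIATE_LEVELS.items():
            bad = ~rec[name].isin(levels)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"invalid level {rec[name].iloc[row]!r} for covariate "
                    f"{name!r} at record row {row}"
                )
        bad = ~rec["stratum"].isin(STRATA)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"invalid stratum {rec['stratum'].iloc[row]!r} at record row {row}"
            )
        ok_outcome = rec["outcome"].isin(OUTCOME_LEVELS) | rec["outcome"].isna()
        if not ok_outcome.all():
            row = int(np.flatnonzero(~ok_outcome)[0])
            raise ValidationError(
                f"invalid outcome {rec['outcome'].iloc[row]!r} at record row {row}"
            )
        grams = rec["birth_weight_grams"].to_numpy(dtype=float)
        has_g = np.isfinite(grams)
        if has_g.any():
            expected = categorize_birth_weight(grams[has_g])
            observed = rec.loc[has_g, "outcome"].to_numpy(dtype=object)
            bad = observed != np.asarray(expected, dtype=object)
            if bad.any():
                row = int(np.flatnonzero(has_g)[np.flatnonzero(bad)[0]])
                raise ValidationError(
                    f"outcome {observed[np.flatnonzero(bad)[0]]!r} inconsistent "
                    f"with birth_weight_grams at record row {row}"
                )

        if clu["cluster_id"].duplicated().any():
            dup = clu.loc[clu["cluster_id"].duplicated(), "cluster_id"].iloc[0]
            raise ValidationError(f"duplicate cluster_id {dup!r}")
        n_c = clu["sample_size"].to_numpy()
        N_c = clu["population_size"].to_numpy()
        if (n_c < 1).any():
            raise ValidationError("cluster sample_size must be >= 1")
        if (N_c < n_c).any():
            cid = clu.loc[N_c < n_c, "cluster_id"].iloc[0]
            raise ValidationError(
                f"cluster {cid!r} has sample_size exceeding population_size"
            )
        bad = ~clu["stratum"].isin(STRATA)
        if bad.any():
            raise ValidationError("invalid stratum label in clusters table")

        known = set(clu["cluster_id"])
        missing = ~rec["cluster_id"].isin(known)
        if missing.any():
            cid = rec.loc[missing, "cluster_id"].iloc[0]
            raise LinkageError(
                f"record cluster_id {cid!r} absent from clusters table"
            )
        counts = rec["cluster_id"].value_counts()
        strat = clu.set_index("cluster_id")["stratum"]
        rec_strat = rec.groupby("cluster_id")["stratum"].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else None
        )
        for cid, s in rec_strat.items():
            if s is None or strat[cid] != s:
                raise LinkageError(
                    f"stratum mismatch between records and clusters for {cid!r}"
                )
        for cid, n in counts.items():
            if int(strat.index.isin([cid]).any()) and int(
                clu.loc[clu["cluster_id"] == cid, "sample_size"].iloc[0]
            ) != int(n):
                raise LinkageError(
                    f"cluster {cid!r} sample_size does not match its record count"
                )
        orphan = ~clu["cluster_id"].isin(set(rec["cluster_id"]))
        if orphan.any():
            cid = clu.loc[orphan, "cluster_id"].iloc[0]
            raise LinkageError(f"cluster {cid!r} has no records")
        return self


def read_dataset(records_path, clusters_path):
    """Read and validate a records CSV and a clusters CSV.

    The records file must carry child_id, cluster_id, stratum, the ten
    covariates and at least one of outcome / birth_weight_grams; if the
    outcome column is absent it is derived from grams via the WHO
    cut-points. Missing values are empty cells or the token ``NA``.
    """
    rec = pd.read_csv(
        records_path, dtype=str, keep_default_na=False, na_values=NA_TOKENS
    )
    clu = pd.read_csv(
        clusters_path, dtype=str, keep_default_na=False, na_values=NA_TOKENS
    )
    for col in _RECORD_ID_COLS + list(COVARIATE_LEVELS):
        if col not in rec.columns:
            raise SchemaError(f"records file is missing column {col!r}")
    if "outcome" not in rec.columns and "birth_weight_grams" not in rec.columns:
        raise SchemaError(
            "records file needs an 'outcome' or 'birth_weight_grams' column"
        )
    for col in _CLUSTER_COLS:
        if col not in clu.columns:
            raise SchemaError(f"clusters file is missing column {col!r}")
    if "birth_weight_grams" in rec.columns:
        rec["birth_weight_grams"] = pd.to_numeric(rec["birth_weight_grams"])
    clu["population_size"] = pd.to_numeric(clu["population_size"]).astype(int)
    clu["sample_size"] = pd.to_numeric(clu["sample_size"]).astype(int)
    return SurveyDataset.from_frames(rec, clu)


def drop_missing_outcome(data):
    """Drop records whose outcome is missing; recompute cluster sizes.

    Returns the filtered dataset and the number of dropped records.
    Clusters left without any record are removed from the cluster table.
    """
    keep = data.records["outcome"].notna()
    dropped = int((~keep).sum())
    if not keep.any():
        raise ValidationError("all records have missing outcome; nothing to analyse")
    rec = data.records.loc[keep].reset_index(drop=True)
    counts = rec["cluster_id"].value_counts()
    clu = data.clusters[data.clusters["cluster_id"].isin(counts.index)].copy()
    clu["sample_size"] = clu["cluster_id"].map(counts).astype(int)
    clu["population_size"] = np.maximum(clu["population_size"], clu["sample_size"])
    return SurveyDataset.from_frames(rec, clu.reset_index(drop=True)), dropped


def write_table(table, path, sig_digits=6):
    """Write any tabular result as CSV with a header row.

    Floats are rendered with ``sig_digits`` significant digits; missing
    values are written as empty cells.
    """
    df = pd.DataFrame(table)
    df.to_csv(path, index=False, float_format=f"%.{int(sig_digits)}g")


def write_dataset(data, records_path, clusters_path, sig_digits=10):
    """Write a SurveyDataset to a records CSV and a clusters CSV."""
    cols = _RECORD_ID_COLS + ["birth_weight_grams", "outcome"] + list(COVARIATE_LEVELS)
    write_table(data.records[cols], records_path, sig_digits=sig_digits)
    write_table(data.clusters[_CLUSTER_COLS], clusters_path, sig_digits=sig_digits)
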