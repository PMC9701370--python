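"""Descriptive tables, index plots and the end-to-end pipeline.

The crosstab mirrors the usual survey-report layout: one row per covariate
level with its total count and share, the outcome split within the level
as row percentages, and a Pearson chi-square test of association on the
count table. Index plots scatter a diagnostic against observation or
cluster identifiers with optional cutoff lines. ``run_pipeline`` chains
reading, filtering, weighting, the AIC model ladder, diagnostics, cluster
flagging and plotting into one reproducible report bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from . import diagnostics as diag_mod
from .datamodel import (
    COVARIATE_LEVELS,
    OUTCOME_LEVELS,
    SurveyDataset,
    drop_missing_outcome,
    read_dataset,
    write_table,
)
from .exceptions import MlogitDiagError, SchemaError, ValidationError
from .model import goodness_of_fit, select_model
from .weights import compute_fpc, compute_weights

__all__ = ["CrosstabResult", "crosstab", "plot_index", "run_pipeline"]


@dataclass
class CrosstabResult:
    """Level-by-outcome table with row percentages and a chi-square test."""

    covariate: str
    table: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    warning: str = None

    def format_p(self, floor=1e-4):
        if self.p_value is None:
            return ""
        return "<0.0001" if self.p_value < floor else f"{self.p_value:.4f}"


def crosstab(data, covariate=None, percent_basis="unweighted", w=None):
    """Outcome distribution overall (``covariate=None``) or per level.

    Counts are raw record counts; percentages use raw counts
    (``"unweighted"``, the default) or design-weighted sums
    (``"weighted"``). The chi-square test is the ordinary Pearson test on
    the unweighted count table; a warning is attached when any expected
    cell count falls below 1.
    """
    if percent_basis not in ("unweighted", "weighted"):
        raise ValidationError(f"unknown percent basis {percent_basis!r}")
    rec = data.records[data.records["outcome"].notna()]
    if percent_basis == "weighted":
        wv = compute_weights(data) if w is None else np.asarray(w, float)
        wv = wv[data.records["outcome"].notna().to_numpy()]
    else:
        wv = np.ones(len(rec))
    outcome = pd.Categorical(rec["outcome"], categories=OUTCOME_LEVELS)

    def _row(mask, label):
        n = int(mask.sum())
        wsum = float(wv[mask].sum())
        row = {"level": label, "n": n}
        for cat in OUTCOME_LEVELS:
            cmask = mask & (np.asarray(outcome) == cat)
            row[f"{cat}_n"] = int(cmask.sum())
            row[f"{cat}_pct"] = (
                100.0 * wv[cmask].sum() / wsum if wsum > 0 else np.nan
            )
        return row

    if covariate is None:
        all_mask = np.ones(len(rec), dtype=bool)
        row = _row(all_mask, "overall")
        row["total_pct"] = 100.0
        table = pd.DataFrame([row])
        return CrosstabResult(covariate="overall", table=table,
                              chi2=None, df=None, p_value=None)

    if covariate not in COVARIATE_LEVELS:
        raise ValidationError(f"unknown covariate {covariate!r}")
    levels = [lv for lv in COVARIATE_LEVELS[covariate]
              if (rec[covariate] == lv).any()]
    if len(levels) < 2:
        raise ValidationError(
            f"covariate {covariate!r} has a single observed level; "
            "chi-square has 0 degrees of freedom"
        )
    values = rec[covariate].to_numpy(dtype=object)
    total_w = float(wv.sum())
    rows = []
    counts = np.zeros((len(levels), len(OUTCOME_LEVELS)))
    for i, lv in enumerate(levels):
        mask = values == lv
        row = _row(mask, lv)
        row["total_pct"] = 100.0 * float(wv[mask].sum()) / total_w
        rows.append(row)
        counts[i] = [row[f"{c}_n"] for c in OUTCOME_LEVELS]
    table = pd.DataFrame(rows)
    keep = counts.sum(axis=0) > 0
    chi2, p, df, expected = stats.chi2_contingency(
        counts[:, keep], correction=False
    )
    warning = None
    if (expected < 1).any():
        warning = "expected cell count below 1; chi-square unreliable"
        warnings.warn(f"{covariate}: {warning}", stacklevel=2)
    return CrosstabResult(covariate=covariate, table=table, chi2=float(chi2),
                          df=int(df), p_value=float(p), warning=warning)


def plot_index(values, ids, path, thresholds=None, ylabel="value",
               title=None, xlabel="index"):
    """Scatter a diagnostic against its observation/cluster index.

    ``thresholds`` draws horizontal reference lines (e.g. +-2.5 for
    residuals, 1 for Cook's distance). The file is written to ``path``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("nothing to plot: empty input")
    x = np.arange(len(values))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(x, values, s=8, alpha=0.7, edgecolors="none")
    for t in (thresholds or []):
        ax.axhline(t, color="crimson", linestyle="--", linewidth=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    n_ticks = min(len(values), 8)
    if n_ticks > 1:
        pos = np.linspace(0, len(values) - 1, n_ticks).astype(int)
        ax.set_xticks(pos)
        ax.set_xticklabels([str(np.asarray(ids)[i]) for i in pos],
                           rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except MlogitDiagError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc
    except OSError as exc:
        raise SchemaError(f"[stage {name}] {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(records, clusters, specs, outdir, *, weighting="pseudo",
                 vcov="jackknife", flag_method="rank_top_k", k=2, z=3.5,
                 scalar_residual="chi2", fpc_population=None,
                 make_plots=True):
    """Run the full analysis and write the report bundle to ``outdir``.

    ``records``/``clusters`` are CSV paths or a pre-built
    :class:`SurveyDataset` (pass the dataset as ``records`` with
    ``clusters=None``). ``specs`` is the ordered model ladder. Emits the
    descriptive table, model comparison, per-observation and per-cluster
    diagnostics CSVs, index plots and a JSON summary; the whole bundle is
    deterministic given the inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if isinstance(records, SurveyDataset):
        data = records
    else:
        data = _stage("data_model", read_dataset, records, clusters)
    data, dropped = _stage("data_model", drop_missing_outcome, data)
    w = _stage("weights", compute_weights, data)

    tabs = []
    for cov in COVARIATE_LEVELS:
        try:
            res = _stage("descriptives", crosstab, data, cov)
        except ValidationError:
            continue
        t = res.table.copy()
        t.insert(0, "covariate", cov)
        t["chi2"] = res.chi2
        t["p_value"] = res.p_value
        tabs.append(t)
    overall = crosstab(data).table.copy()
    overall.insert(0, "covariate", "overall")
    table1 = pd.concat([overall] + tabs, ignore_index=True)
    write_table(table1, outdir / "table1.csv")

    selection = _stage("mnlogit", select_model, data, specs, w,
                       weighting=weighting, vcov=vcov)
    best = selection.best
    coef_rows = []
    for i, res in enumerate(selection.results):
        if res is None:
            continue
        ct = res.coef_table()
        ct.insert(0, "model", i)
        ct["aic"] = res.aic
        coef_rows.append(ct)
    write_table(pd.concat(coef_rows, ignore_index=True),
                outdir / "model_comparison.csv")

    obs = _stage("diagnostics", diag_mod.compute_obs_diagnostics, best,
                 scalar_residual=scalar_residual)
    gof_stat, gof_df, gof_p = _stage("mnlogit", goodness_of_fit, obs, best)
    clus = _stage("diagnostics", diag_mod.compute_cluster_diagnostics,
                  obs, data, method=flag_method, k=k, z=z)
    write_table(obs.to_frame(data), outdir / "obs_diagnostics.csv")
    write_table(clus.frame, outdir / "cluster_diagnostics.csv")

    if make_plots:
        rec_ids = data.records["child_id"].to_numpy()
        plot_index(np.sqrt(obs.deviance), rec_ids,
                   outdir / "fig_obs_deviance.png",
                   thresholds=[diag_mod.RESIDUAL_CUTOFF],
                   ylabel="deviance residual", title="Observation outliers")
        plot_index(obs.cookd, rec_ids, outdir / "fig_obs_cookd.png",
                   thresholds=[diag_mod.COOKD_CUTOFF],
                   ylabel="Cook's distance", title="Observation influence")
        cids = clus.frame["cluster_id"].to_numpy()
        plot_index(clus.frame["D_c"], cids,
                   outdir / "fig_cluster_deviance.png",
                   ylabel="local mean deviance D_c",
                   title="Cluster outliers", xlabel="cluster")
        plot_index(clus.frame["mean_cookd"], cids,
                   outdir / "fig_cluster_cookd.png",
                   ylabel="cluster mean Cook's distance",
                   title="Cluster influence", xlabel="cluster")

    flagged_infl = clus.frame.loc[clus.frame["influence_flag"],
                                  "cluster_id"].tolist()
    flagged_out = clus.frame.loc[clus.frame["outlier_flag"],
                                 "cluster_id"].tolist()
    summary = {
        "n_records": data.n_records,
        "n_clusters": data.n_clusters,
        "dropped_missing_outcome": dropped,
        "weighting": weighting,
        "aic": [None if r is None else r.aic for r in selection.results],
        "selected_model": selection.best_index,
        "selected_terms": best.spec.terms,
        "goodness_of_fit": {"statistic": gof_stat, "df": gof_df, "p": gof_p},
        "influential_clusters": flagged_infl,
        "outlier_clusters": flagged_out,
        "outlier_rule": clus.outlier_rule,
        "influence_rule": clus.influence_rule,
    }
    if fpc_population is not None:
        summary["fpc"] = compute_fpc(fpc_population, data.n_records)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    return summary
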