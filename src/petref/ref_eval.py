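"""Reference-region evaluation: age-effect ranking, SUVR, group contrasts.

Candidate regions are ranked by how little age explains their quantitative
uptake (ascending r2_age); the top-ranked region is the best candidate
intensity-normalization (SUVR reference) region.  Group comparisons
standardize SUVR to the control group (z-scores) and test pairwise
differences among control, MCI and AD with Welch t-tests in the
AD-susceptible targets (posterior cingulate, precuneus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rank_regions",
    "compute_suvr",
    "whole_brain_reference",
    "group_compare",
    "plot_ranking",
    "plot_group_scores",
    "DEFAULT_TARGETS",
]

DEFAULT_TARGETS = ("posteriorcingulate", "precuneus")


def rank_regions(regression_results: pd.DataFrame) -> pd.DataFrame:
    """Rank regions ascending by r2_age within each measure.

    Ties are broken alphabetically by region name; ranks are 1..n per
    measure.  Input is the frame produced by ``roi_stats.regress_all``.
    """
    if regression_results["region"].nunique() < 2:
        raise ValueError("need at least 2 regions to rank")
    out = []
    for measure, grp in regression_results.groupby("measure", sort=True):
        g = grp.sort_values(["r2_age", "region"], kind="stable").reset_index(drop=True)
        g["rank"] = np.arange(1, len(g) + 1)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _wide(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    sel = table[table["measure"] == measure]
    return sel.pivot(index="subject_id", columns="region", values="value")


def compute_suvr(region_table: pd.DataFrame, reference, measure="cmrg_pvc") -> pd.DataFrame:
    """Per-subject SUVR: value(region) / value(reference region).

    ``reference`` is a region name present in the table, or a per-subject
    Series (e.g. a whole-brain mean).  Subjects whose reference value is not
    positive are excluded.  Returns long-format rows with measure
    'suvr_<measure>'.
    """
    wide = _wide(region_table, measure)
    if isinstance(reference, str):
        if reference not in wide.columns:
            raise KeyError(f"reference region '{reference}' not in table")
        ref = wide[reference]
    else:
        ref = pd.Series(reference).reindex(wide.index)
    bad = ~(ref > 0)
    if bad.any():
        wide = wide[~bad]
        ref = ref[~bad]
    suvr = wide.div(ref, axis=0)
    long = suvr.reset_index().melt(id_vars="subject_id", var_name="region", value_name="value")
    long["measure"] = f"suvr_{measure}"
    return long[["subject_id", "region", "measure", "value"]]


def whole_brain_reference(region_table: pd.DataFrame, measure="cmrg_pvc") -> pd.Series:
    """Volume-weighted mean over all candidate regions, per subject.

    The weights are the subject's regional volumes (measure 'volume' in the
    same table), so the reference equals pooling at the voxel level.
    """
    vals = _wide(region_table, measure)
    vols = _wide(region_table, "volume").reindex(index=vals.index, columns=vals.columns)
    if vols.isna().all().all():
        vols = pd.DataFrame(1.0, index=vals.index, columns=vals.columns)
    w = vols.to_numpy()
    v = vals.to_numpy()
    ok = np.isfinite(v) & np.isfinite(w)
    num = np.where(ok, v * w, 0.0).sum(axis=1)
    den = np.where(ok, w, 0.0).sum(axis=1)
    return pd.Series(num / den, index=vals.index, name="whole_brain")


def group_compare(suvr_table: pd.DataFrame, subjects: pd.DataFrame,
                  targets=DEFAULT_TARGETS, alpha=0.05,
                  groups=("control", "MCI", "AD")) -> pd.DataFrame:
    """Control-referenced z-scores and pairwise Welch t-tests per target.

    Returns one row per (target, pair) with the Welch t statistic, two-sided
    p-value, mean z per group and a significance flag at ``alpha``.
    """
    grp = subjects.set_index("subject_id")["group"]
    rows = []
    for target in targets:
        sel = suvr_table[suvr_table["region"].str.contains(target)]
        if sel.empty:
            raise KeyError(f"target region '{target}' not found in SUVR table")
        per_sub = sel.groupby("subject_id")["value"].mean()  # pool L/R if split
        g = grp.reindex(per_sub.index)
        by = {name: per_sub[g == name].to_numpy() for name in groups}
        for name, v in by.items():
            if len(v) < 2:
                raise ValueError(f"group '{name}' has fewer than 2 subjects")
        mu, sd = by[groups[0]].mean(), by[groups[0]].std(ddof=1)
        z = {name: (v - mu) / sd for name, v in by.items()}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                t, p = stats.ttest_ind(by[a], by[b], equal_var=False)
                rows.append({
                    "target": target, "group_a": a, "group_b": b,
                    "t": float(t), "p_value": float(p),
                    "mean_z_a": float(z[a].mean()), "mean_z_b": float(z[b].mean()),
                    "significant": bool(p < alpha),
                })
    return pd.DataFrame(rows)


def plot_ranking(ranking: pd.DataFrame, measure: str, ax=None, highlight="pons"):
    """Bar plot of r2_age in rank order for one measure."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    g = ranking[ranking["measure"] == measure].sort_values("rank")
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    colors = ["crimson" if highlight in r else "steelblue" for r in g["region"]]
    ax.bar(np.arange(len(g)), g["r2_age"], color=colors)
    ax.set_xticks(np.arange(len(g)))
    ax.set_xticklabels(g["region"], rotation=90, fontsize=5)
    ax.set_ylabel("age effect size $r^2$")
    ax.set_title(measure)
    return ax


def plot_group_scores(suvr_table: pd.DataFrame, subjects: pd.DataFrame,
                      target: str, ax=None, groups=("control", "MCI", "AD")):
    """Strip plot of control-referenced z-scores per group for one target."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grp = subjects.set_index("subject_id")["group"]
    sel = suvr_table[suvr_table["region"].str.contains(target)]
    per_sub = sel.groupby("subject_id")["value"].mean()
    g = grp.reindex(per_sub.index)
    ctrl = per_sub[g == groups[0]]
    mu, sd = ctrl.mean(), ctrl.std(ddof=1)
    rng = np.random.default_rng(0)
    for k, name in enumerate(groups):
        v = (per_sub[g == name] - mu) / sd
        ax.scatter(k + rng.uniform(-0.15, 0.15, len(v)), v, s=12, alpha=0.7)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(groups)
    ax.set_ylabel("SUVR z-score (vs control)")
    ax.set_title(target)
    return ax
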