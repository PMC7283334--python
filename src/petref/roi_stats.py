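"""ROI statistics: regional averaging, laterality merging, and age+sex
multiple regression with LMG relative-importance decomposition.

The LMG share of a predictor is its incremental R^2 averaged over all
predictor orderings.  With the two predictors age and sex:

    r2_age = 1/2 * [ R2({age}) + ( R2({age,sex}) - R2({sex}) ) ]

and analogously for sex, so the shares sum exactly to the full-model R^2.
The reported p-value is the two-sided t-test of the age coefficient in the
full model (the decomposition itself carries no test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "roi_means",
    "region_table_rows",
    "laterality_merge",
    "relative_importance",
    "regress_all",
]


@dataclass
class RegressionResult:
    region: str
    measure: str
    r2_age: float
    r2_sex: float
    total_r2: float
    p_age: float
    n: int


def roi_means(volume, atlas, validity_mask=None) -> pd.DataFrame:
    """Mean of valid voxels per candidate region.

    Returns a frame (region, value, n_voxels, n_valid); a region with no
    valid voxels gets value NaN.  NaNs in the input are treated as invalid.
    """
    vol = np.asarray(volume, dtype=float)
    labels = atlas.labels
    ok = np.isfinite(vol)
    if validity_mask is not None:
        ok &= np.asarray(validity_mask, dtype=bool)
    nlab = int(labels.max()) + 1
    lab_ok = labels[ok].ravel()
    sums = np.bincount(lab_ok, weights=vol[ok].ravel(), minlength=nlab)
    n_valid = np.bincount(lab_ok, minlength=nlab)
    n_all = np.bincount(labels.ravel(), minlength=nlab)
    cand = atlas.candidates
    ids = cand["region_id"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n_valid[ids] > 0, sums[ids] / np.maximum(n_valid[ids], 1), np.nan)
    return pd.DataFrame({
        "region": cand["name"].to_numpy(),
        "value": means,
        "n_voxels": n_all[ids],
        "n_valid": n_valid[ids],
    })


def region_table_rows(subject_id, means: pd.DataFrame, measure: str, atlas) -> pd.DataFrame:
    """Long-format RegionTable rows for one subject and one measure."""
    cand = atlas.candidates.set_index("name")
    df = means.copy()
    df["subject_id"] = subject_id
    df["measure"] = measure
    df["base"] = cand.loc[df["region"], "base"].to_numpy()
    df["hemisphere"] = cand.loc[df["region"], "hemisphere"].to_numpy()
    return df[["subject_id", "region", "base", "hemisphere", "measure", "value"]]


def laterality_merge(table: pd.DataFrame, alpha=0.05):
    """Pool left/right homologues whose paired difference is not significant.

    For each (base, measure) with left and right rows, a paired two-sided
    t-test across subjects on (left - right) decides: p >= alpha (or p
    undefined, e.g. identical sides) merges the pair into one row per subject
    -- volume-weighted mean for intensity measures, sum for volume -- while
    p < alpha keeps the sides separate.  Midline regions pass through.

    Returns (merged table, decisions frame).
    """
    req = {"subject_id", "region", "base", "hemisphere", "measure", "value"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    vols = table[table["measure"] == "volume"].set_index(["subject_id", "region"])["value"]
    out_rows, decisions = [], []
    for (base, measure), grp in table.groupby(["base", "measure"], sort=True):
        hemis = set(grp["hemisphere"])
        if hemis == {"midline"} or len(hemis) == 1:
            out_rows.append(grp)
            continue
        piv = grp.pivot(index="subject_id", columns="hemisphere", values="value")
        if piv[["left", "right"]].isna().any().any():
            missing = piv.index[piv[["left", "right"]].isna().any(axis=1)].tolist()
            raise ValueError(f"unpaired left/right rows for '{base}' ({measure}): {missing}")
        diff = piv["left"] - piv["right"]
        if np.allclose(diff, 0):
            p = np.nan  # identical sides: treated as non-significant
        else:
            p = float(stats.ttest_rel(piv["left"], piv["right"]).pvalue)
        merge = not (p < alpha)  # NaN compares False -> merge
        decisions.append((base, measure, p, merge))
        if not merge:
            out_rows.append(grp)
            continue
        if measure == "volume":
            merged = piv["left"] + piv["right"]
        else:
            lv = vols.reindex(
                pd.MultiIndex.from_product([piv.index, [f"left_{base}"]])
            ).to_numpy()
            rv = vols.reindex(
                pd.MultiIndex.from_product([piv.index, [f"right_{base}"]])
            ).to_numpy()
            if np.isnan(lv).any() or np.isnan(rv).any():
                lv = rv = np.ones(len(piv))  # no volumes available: plain mean
            merged = (piv["left"] * lv + piv["right"] * rv) / (lv + rv)
        out_rows.append(pd.DataFrame({
            "subject_id": piv.index,
            "region": base,
            "base": base,
            "hemisphere": "merged",
            "measure": measure,
            "value": np.asarray(merged),
        }))
    merged_table = pd.concat(out_rows, ignore_index=True)
    dec = pd.DataFrame(decisions, columns=["base", "measure", "p_value", "merged"])
    return merged_table, dec


def _r2(y, X):
    """R^2 of OLS with intercept; X is (n, k) without the constant column."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / ss_tot


def relative_importance(values, ages, sexes, region="", measure="") -> RegressionResult:
    """Fit value ~ age + sex and decompose R^2 into LMG shares.

    ``sexes`` may be 'M'/'F' strings or a 0/1 indicator.  Rows with missing
    values are dropped (complete-case).  A constant response yields zero
    shares and an undefined (NaN) p-value.
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(ages, dtype=float)
    sex = np.asarray(sexes)
    if sex.dtype.kind in "UOS":
        sex = (sex == "F").astype(float)
    sex = sex.astype(float)
    keep = np.isfinite(y) & np.isfinite(age) & np.isfinite(sex)
    y, age, sex = y[keep], age[keep], sex[keep]
    n = len(y)
    if n < 4:
        raise ValueError(f"need at least 4 complete cases, got {n}")
    if np.ptp(age) == 0 or np.ptp(sex) == 0:
        raise ValueError("predictors must be non-constant")
    if np.ptp(y) == 0:
        return RegressionResult(region, measure, 0.0, 0.0, 0.0, np.nan, n)
    r2_full = _r2(y, np.column_stack([age, sex]))
    r2_a = _r2(y, age[:, None])
    r2_s = _r2(y, sex[:, None])
    lmg_age = 0.5 * (r2_a + (r2_full - r2_s))
    lmg_sex = 0.5 * (r2_s + (r2_full - r2_a))
    # two-sided t-test of the age coefficient in the full model
    A = np.column_stack([np.ones(n), age, sex])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = n - 3
    sigma2 = float((resid**2).sum()) / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    tstat = beta[1] / np.sqrt(cov[1, 1])
    p_age = 2.0 * stats.t.sf(abs(tstat), dof)
    return RegressionResult(region, measure, float(lmg_age), float(lmg_sex),
                            float(r2_full), float(p_age), n)


def regress_all(region_table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-region, per-measure age+sex regression over subjects.

    ``region_table`` is long format (subject_id, region, measure, value);
    ``covariates`` has subject_id, age, sex.  Missing regional values drop the
    subject for that region only.
    """
    cov = covariates.set_index("subject_id")
    rows = []
    for (region, measure), grp in region_table.groupby(["region", "measure"], sort=True):
        sub = cov.loc[grp["subject_id"]]
        try:
            res = relative_importance(grp["value"], sub["age"], sub["sex"],
                                      region=region, measure=measure)
        except ValueError:
            continue
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
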