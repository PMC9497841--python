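"""Intra-recording / intra-patient stability and the hypothesis-test battery.

The coefficient of variation (CV = sigma/mu, in %) quantifies index dispersion
across segments within a recording (intra-recording) and across the per-site
means within a patient (intra-patient), with and without low-quality segments
discarded. Kruskal-Wallis compares recording sites within a patient,
Breusch-Pagan screens for heteroscedasticity across groups, and Mann-Whitney
compares ParAF vs PerAF per site with the per-window p-values averaged — a
reporting convention, not a combined inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

INDEX_COLS = ("SE", "DET")


def coefficient_of_variation(values) -> float:
    """100 x sample SD (n-1 denominator) / mean; NaN when the mean is 0."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("CV needs at least 2 values")
    mu = v.mean()
    if mu == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mu)


def _usable(table: pd.DataFrame, w: int, use_discards: bool) -> pd.DataFrame:
    t = table[table["w"] == w]
    if use_discards:
        t = t[t["quality"] == 1]
    return t.dropna(subset=list(INDEX_COLS), how="all")


def intra_recording_cv(
    table: pd.DataFrame, index: str, w: int, use_discards: bool
) -> dict[str, float]:
    """CV across segments within each recording, averaged over recordings.

    Returns ``{"overall": %, "ParAF": %, "PerAF": %}``. Recordings with fewer
    than two usable segments are skipped. ``use_discards`` excludes
    zero-quality segments before computing the CV.
    """
    t = _usable(table, w, use_discards).dropna(subset=[index])
    per_rec = []
    for (_, _), grp in t.groupby(["patient_id", "site"]):
        if len(grp) < 2 or grp[index].mean() == 0:
            continue
        per_rec.append((grp["af_type"].iloc[0], coefficient_of_variation(grp[index])))
    if not per_rec:
        raise ValueError("no recording with >= 2 usable segments")
    df = pd.DataFrame(per_rec, columns=["af_type", "cv"])
    out = {"overall": float(df["cv"].mean())}
    for af, grp in df.groupby("af_type"):
        out[af] = float(grp["cv"].mean())
    out["n_recordings"] = len(df)
    out["n_per_class"] = df["af_type"].value_counts().to_dict()
    return out


def intra_patient_cv(
    table: pd.DataFrame, index: str, w: int, use_discards: bool
) -> dict[str, float]:
    """CV across the per-site mean index values within each patient, averaged
    over patients; patients with fewer than two sites are skipped."""
    t = _usable(table, w, use_discards).dropna(subset=[index])
    site_means = (
        t.groupby(["patient_id", "af_type", "site"])[index].mean().reset_index()
    )
    per_pat = []
    for (_, af), grp in site_means.groupby(["patient_id", "af_type"]):
        if len(grp) < 2 or grp[index].mean() == 0:
            continue
        per_pat.append((af, coefficient_of_variation(grp[index])))
    if not per_pat:
        raise ValueError("no patient with >= 2 sites")
    df = pd.DataFrame(per_pat, columns=["af_type", "cv"])
    out = {"overall": float(df["cv"].mean())}
    for af, grp in df.groupby("af_type"):
        out[af] = float(grp["cv"].mean())
    out["n_patients"] = len(df)
    return out


def stability_report(table: pd.DataFrame, windows=(1, 2, 4)) -> pd.DataFrame:
    """CV with/without discards and the relative change DeltaCV (%) per
    (index, w, scope); the shape of the intra-recording / intra-patient
    stability tables."""
    rows = []
    for scope, fn in (("intra_recording", intra_recording_cv), ("intra_patient", intra_patient_cv)):
        for index in INDEX_COLS:
            for w in windows:
                try:
                    cv_no = fn(table, index, w, use_discards=False)
                    cv_yes = fn(table, index, w, use_discards=True)
                except ValueError:
                    continue
                for cls in ("overall", "ParAF", "PerAF"):
                    a, b = cv_no.get(cls), cv_yes.get(cls)
                    if a is None or b is None:
                        continue
                    rows.append(
                        {
                            "scope": scope,
                            "index": index,
                            "w": w,
                            "class": cls,
                            "cv_no_discard_pct": a,
                            "cv_discard_pct": b,
                            "delta_cv_pct": 100.0 * (b - a) / a if a else float("nan"),
                        }
                    )
    return pd.DataFrame(rows)


def kruskal_wallis_sites(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis across a patient's recording sites.

    ``groups`` maps site -> segment index values. Returns H, p and an
    ``unreliable`` flag set when any group has fewer than 5 values (the
    chi-square approximation is then inaccurate).
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 sites with >= 2 values each")
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        h, p = 0.0, 1.0  # identical groups: no rank variation
    else:
        h, p = stats.kruskal(*arrays)
    return {"H": float(h), "p": float(p), "unreliable": any(len(a) < 5 for a in arrays)}


def breusch_pagan(values, labels) -> dict:
    """Breusch-Pagan homoscedasticity test across groups.

    Values are regressed on group indicators; the squared residuals are then
    regressed on the same design and LM = n R-squared is referred to a
    chi-square. Returns NaN p (flagged undefined) when residual variance is 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 groups")
    dummies = pd.get_dummies(pd.Series(labels), drop_first=True, dtype=float)
    exog = sm.add_constant(dummies.to_numpy())
    resid = sm.OLS(values, exog).fit().resid
    if np.allclose(resid, 0):
        return {"lm": float("nan"), "p": float("nan"), "undefined": True}
    lm, p, _, _ = sm.stats.diagnostic.het_breuschpagan(resid, exog)
    return {"lm": float(lm), "p": float(p), "undefined": False}


def per_patient_tests(table: pd.DataFrame, index: str, w: int, use_discards: bool = True) -> pd.DataFrame:
    """Kruskal-Wallis (sites within patient) and Breusch-Pagan p per patient."""
    t = _usable(table, w, use_discards).dropna(subset=[index])
    rows = []
    for pid, grp in t.groupby("patient_id"):
        groups = {s: g[index].to_numpy() for s, g in grp.groupby("site")}
        groups = {s: v for s, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        kw = kruskal_wallis_sites(groups)
        all_vals = np.concatenate(list(groups.values()))
        all_labs = np.concatenate([[s] * len(v) for s, v in groups.items()])
        bp = breusch_pagan(all_vals, all_labs)
        rows.append(
            {
                "patient_id": pid,
                "index": index,
                "w": w,
                "kw_p": kw["p"],
                "kw_unreliable": kw["unreliable"],
                "bp_p": bp["p"],
            }
        )
    return pd.DataFrame(rows)


def mann_whitney_sites(
    seg_table: pd.DataFrame,
    rec_table: pd.DataFrame | None = None,
    windows=(1, 2, 4),
    use_discards: bool = True,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney p per (site, index), averaged over window lengths.

    SE/DET are summarized per recording as the mean over usable segments of
    each window length before testing (one value per patient per site), and
    the three per-window p-values are arithmetically averaged. AFCL/DF (when
    ``rec_table`` is given) are tested once on the 16 s values. Sites where a
    class is absent are flagged with NaN.
    """
    rows = []
    for site, site_t in seg_table.groupby("site"):
        for index in INDEX_COLS:
            ps = []
            for w in windows:
                t = _usable(site_t, w, use_discards).dropna(subset=[index])
                per_rec = t.groupby(["patient_id", "af_type"])[index].mean().reset_index()
                x = per_rec.loc[per_rec["af_type"] == "ParAF", index].to_numpy()
                y = per_rec.loc[per_rec["af_type"] == "PerAF", index].to_numpy()
                if len(x) == 0 or len(y) == 0:
                    ps.append(float("nan"))
                    continue
                ps.append(float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue))
            rows.append({"site": site, "index": index, "p": float(np.nanmean(ps)) if not all(np.isnan(ps)) else float("nan")})
    if rec_table is not None:
        for site, site_t in rec_table.groupby("site"):
            for index in ("AFCL_ms", "DF_Hz"):
                t = site_t.dropna(subset=[index])
                x = t.loc[t["af_type"] == "ParAF", index].to_numpy()
                y = t.loc[t["af_type"] == "PerAF", index].to_numpy()
                p = (
                    float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
                    if len(x) and len(y)
                    else float("nan")
                )
                rows.append({"site": site, "index": index, "p": p})
    return pd.DataFrame(rows)
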