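"""Cohort statistics for tissue MPF means.

The analysis battery applied to a cohort table (one row per subject,
columns for group, covariates, and per-tissue mean MPF):

* Shapiro-Wilk normality checks within each group,
* MANCOVA over the three tissue responses with age as covariate,
  summarized by Wilks lambda and Rao's F approximation,
* Tukey HSD post-hoc pairwise tests per tissue,
* Cohen's d and percentage decreases per group contrast,
* Pearson and age-adjusted partial correlations between MPF and clinical
  variables,
* scan-rescan repeatability: Bland-Altman bias and limits of agreement,
  paired t-test, and within-subject coefficient of variation.

Group coding uses treatment contrasts with the control group as
reference; the hypothesis SSCP for each model term is computed by
dropping that term from the full model (Type-III-style).  All tests are
two-tailed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import cohens_d, percent_change

__all__ = [
    "TISSUE_COLUMNS",
    "StatsReport",
    "RepeatabilityReport",
    "shapiro_wilk",
    "mancova",
    "tukey_hsd",
    "pearson_and_partial",
    "repeatability",
    "cohort_stats",
    "bland_altman_plot",
]

#: Cohort-table columns holding the per-tissue mean MPF (percent).
TISSUE_COLUMNS = ("gm_mpf", "pvwgm_mpf", "wm_mpf")

GROUPS = ("control", "sz_positive", "sz_negative")


@dataclass
class StatsReport:
    """Full statistical output over a cohort table (JSON-serializable)."""

    normality: dict = field(default_factory=dict)
    mancova: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    group_summary: dict = field(default_factory=dict)

    def to_json(self, path=None, indent=2):
        payload = json.dumps(asdict(self), indent=indent, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload


@dataclass
class RepeatabilityReport:
    """Scan-rescan agreement per tissue class.

    Per tissue: ``bias`` (mean of rescan minus scan), ``loa`` (bias +/-
    1.96 SD of the paired differences), paired-t p-value, and the
    within-subject coefficient of variation in percent.
    """

    per_tissue: dict = field(default_factory=dict)
    n_pairs: int = 0

    def to_json(self, path=None, indent=2):
        payload = json.dumps(asdict(self), indent=indent, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload


def shapiro_wilk(sample):
    """Shapiro-Wilk normality test, ``(W, p)``; requires 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _sscp_residual(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid.T @ resid


def _wilks_to_f(lam: float, p: int, q: int, v: float):
    """Rao's F approximation for Wilks lambda.

    ``p`` responses, ``q`` hypothesis df, ``v`` error df.  Exact when
    min(p, q) <= 2, which covers 2- and 3-group designs with three tissue
    responses.
    """
    pq = p * q
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    w = v + q - 0.5 * (p + q + 1)
    df1 = pq
    df2 = w * t - 0.5 * pq + 1.0
    lam_t = lam ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    p_value = float(sps.f.sf(f, df1, df2))
    return float(f), int(round(df1)), float(df2), p_value


def mancova(cohort: pd.DataFrame, responses=TISSUE_COLUMNS,
            group_col: str = "group", covariate: str = "age") -> dict:
    """MANCOVA of the tissue responses on group with a covariate.

    Wilks lambda = det(E) / det(E + H) per term, with E the residual SSCP
    of the full model and H the extra residual SSCP when the term is
    dropped.  Returns a dict with a section per term (``group`` and the
    covariate), each holding ``wilks_lambda, F, df1, df2, p``.
    """
    df = cohort.dropna(subset=[*responses, group_col, covariate])
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = len(df)
    p = len(responses)
    counts = df[group_col].value_counts()
    if counts.min() <= p + 2:
        raise ValueError("each group needs more than (responses + 2) subjects")

    y = df[list(responses)].to_numpy(dtype=float)
    dummies = pd.get_dummies(df[group_col], drop_first=True).to_numpy(dtype=float)
    age = df[[covariate]].to_numpy(dtype=float)
    intercept = np.ones((n, 1))
    x_full = np.hstack([intercept, age, dummies])
    rank_full = np.linalg.matrix_rank(x_full)
    v = n - rank_full

    e = _sscp_residual(x_full, y)
    cond = np.linalg.cond(e)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"residual SSCP is singular (condition number {cond:.3g})")

    out = {"n": n, "groups": groups, "error_df": int(v)}
    terms = {
        "group": np.hstack([intercept, age]),
        covariate: np.hstack([intercept, dummies]),
    }
    dfs = {"group": len(groups) - 1, covariate: 1}
    for term, x_red in terms.items():
        h = _sscp_residual(x_red, y) - e
        lam = float(np.linalg.det(e) / np.linalg.det(e + h))
        lam = min(max(lam, np.finfo(float).tiny), 1.0)
        f, df1, df2, p_value = _wilks_to_f(lam, p, dfs[term], v)
        out[term] = {"wilks_lambda": lam, "F": f, "df1": df1, "df2": df2,
                     "p": p_value}
    return out


def tukey_hsd(cohort: pd.DataFrame, response: str,
              group_col: str = "group") -> dict:
    """Tukey HSD adjusted pairwise p-values for one response.

    Unequal group sizes are handled by the Tukey-Kramer form.  Returns
    ``{(group_a, group_b): adjusted_p}`` with groups in sorted order.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = cohort.dropna(subset=[response, group_col])
    sizes = df[group_col].value_counts()
    if len(sizes) < 2 or sizes.min() < 2:
        raise ValueError("need at least two non-empty groups")
    res = pairwise_tukeyhsd(df[response].to_numpy(dtype=float),
                            df[group_col].to_numpy())
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    out = {}
    for _, row in frame.iterrows():
        pair = tuple(sorted((str(row["group1"]), str(row["group2"]))))
        out[pair] = float(row["p-adj"])
    return out


def pearson_and_partial(x, y, z):
    """Pearson r of (x, y) and the partial r controlling for z.

    The partial correlation uses the closed form
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` with its
    p-value from a t distribution on n - 3 df.  Returns
    ``(r, p, partial_r, partial_p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete observations")
    for arr in (x, y, z):
        if np.ptp(arr) == 0:
            raise ValueError("zero-variance input")
    r_xy, p_xy = sps.pearsonr(x, y)
    r_xz, _ = sps.pearsonr(x, z)
    r_yz, _ = sps.pearsonr(y, z)
    pr = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    pr = float(np.clip(pr, -1.0, 1.0))
    dof = n - 3
    if abs(pr) >= 1.0:
        pp = 0.0
    else:
        t = pr * np.sqrt(dof / (1.0 - pr ** 2))
        pp = float(2.0 * sps.t.sf(abs(t), dof))
    return float(r_xy), float(p_xy), pr, pp


def repeatability(scan1: pd.DataFrame, scan2: pd.DataFrame,
                  tissues=TISSUE_COLUMNS) -> RepeatabilityReport:
    """Scan-rescan repeatability metrics per tissue class.

    ``scan1``/``scan2`` are aligned tables of per-subject tissue means.
    Per tissue: bias = mean(scan2 - scan1); limits of agreement = bias
    +/- 1.96 SD(differences); paired t-test on the differences; the
    within-subject SD is ``sqrt(sum(d_i^2) / (2 n))`` and the CoV is
    100 * SD_w / grand mean.
    """
    if len(scan1) != len(scan2):
        raise ValueError("scan tables must be aligned")
    n = len(scan1)
    if n < 3:
        raise ValueError("need at least 3 scan-rescan pairs")
    report = RepeatabilityReport(n_pairs=n)
    for tissue in tissues:
        a = np.asarray(scan1[tissue], dtype=float)
        b = np.asarray(scan2[tissue], dtype=float)
        d = b - a
        bias = float(d.mean())
        sd_d = float(d.std(ddof=1))
        if np.allclose(d, d[0]):
            t_p = float("nan") if np.ptp(d) == 0 and d[0] != 0 else 1.0
            if d[0] != 0:
                t_p = 0.0
        else:
            t_p = float(sps.ttest_rel(b, a).pvalue)
        sd_w = float(np.sqrt(np.sum(d ** 2) / (2.0 * n)))
        grand = float(np.concatenate([a, b]).mean())
        report.per_tissue[tissue] = {
            "bias": bias,
            "sd_diff": sd_d,
            "loa_low": bias - 1.96 * sd_d,
            "loa_high": bias + 1.96 * sd_d,
            "paired_t_p": t_p,
            "within_subject_sd": sd_w,
            "cov_percent": 100.0 * sd_w / grand if grand != 0 else float("nan"),
        }
    return report


def bland_altman_plot(scan1, scan2, tissue: str, ax=None):
    """Bland-Altman plot (mean vs difference) for one tissue; optional."""
    import matplotlib.pyplot as plt

    a = np.asarray(scan1[tissue], dtype=float)
    b = np.asarray(scan2[tissue], dtype=float)
    d = b - a
    m = 0.5 * (a + b)
    bias = d.mean()
    sd_d = d.std(ddof=1)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(m, d)
    for yv, style in ((bias, "-"), (bias + 1.96 * sd_d, "--"),
                      (bias - 1.96 * sd_d, "--")):
        ax.axhline(yv, linestyle=style, color="gray")
    ax.set_xlabel(f"mean {tissue} (%)")
    ax.set_ylabel("rescan - scan (%)")
    return ax


def _effects_section(df: pd.DataFrame, tissues) -> dict:
    """Cohen's d and percent decrease for every group contrast, per tissue."""
    samples = {}
    for g in GROUPS:
        sub = df[df["group"] == g]
        if len(sub):
            samples[g] = sub
    patients = df[df["group"].isin(("sz_positive", "sz_negative"))]
    if len(patients):
        samples["sz_all"] = patients
    contrasts = [("control", "sz_all"), ("control", "sz_positive"),
                 ("control", "sz_negative"), ("sz_positive", "sz_negative")]
    out = {}
    for ref, cmp_ in contrasts:
        if ref not in samples or cmp_ not in samples:
            continue
        for tissue in tissues:
            a = samples[ref][tissue].dropna()
            b = samples[cmp_][tissue].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            key = f"{cmp_}_vs_{ref}:{tissue}"
            out[key] = {
                "percent_decrease": percent_change(a.mean(), b.mean()),
                "cohens_d": cohens_d(a.mean(), a.std(ddof=1), len(a),
                                     b.mean(), b.std(ddof=1), len(b)),
            }
    return out


def cohort_stats(cohort: pd.DataFrame, tissues=TISSUE_COLUMNS,
                 alpha: float = 0.05) -> StatsReport:
    """Run the full statistical battery over a cohort table.

    Normality per group and tissue; MANCOVA (all groups present, plus a
    two-level patients-vs-controls variant when both patient subgroups
    exist); Tukey HSD per tissue; effect sizes and percent decreases per
    contrast; correlations of MPF with clinical variables within patients
    (age, disease duration, onset age, antipsychotic dose) and with age
    within controls, adding age-adjusted partial correlations for the
    clinical variables.
    """
    report = StatsReport()
    df = cohort.copy()

    for g, sub in df.groupby("group"):
        for tissue in tissues:
            vals = sub[tissue].dropna()
            if 3 <= len(vals) <= 5000 and np.ptp(vals) > 0:
                w, p = shapiro_wilk(vals)
                report.normality[f"{g}:{tissue}"] = {"W": w, "p": p}

    for g in df["group"].unique():
        sub = df[df["group"] == g]
        report.group_summary[str(g)] = {
            "n": int(len(sub)),
            **{tissue: {"mean": float(sub[tissue].mean()),
                        "sd": float(sub[tissue].std(ddof=1))}
               for tissue in tissues},
        }

    try:
        report.mancova["three_group"] = mancova(df, tissues)
    except ValueError as exc:
        report.mancova["three_group"] = {"error": str(exc)}
    two = df.copy()
    two["group"] = np.where(two["group"] == "control", "control", "sz_all")
    if two["group"].nunique() == 2:
        try:
            report.mancova["patients_vs_controls"] = mancova(two, tissues)
        except ValueError as exc:
            report.mancova["patients_vs_controls"] = {"error": str(exc)}

    if df["group"].nunique() >= 2:
        for tissue in tissues:
            try:
                pair_p = tukey_hsd(df, tissue)
            except ValueError:
                continue
            report.pairwise[tissue] = {f"{a}|{b}": p for (a, b), p in pair_p.items()}

    report.effects = _effects_section(df, tissues)

    patients = df[df["group"].isin(("sz_positive", "sz_negative"))]
    clinical = [c for c in ("age", "disease_duration", "onset_age",
                            "cpz_equivalent") if c in df.columns]
    for var in clinical:
        for tissue in tissues:
            cols = list(dict.fromkeys([var, tissue, "age"]))
            sub = patients[cols].dropna()
            if len(sub) < 4 or np.ptp(sub[var]) == 0:
                continue
            if var == "age":
                r, p = sps.pearsonr(sub["age"], sub[tissue])
                report.correlations[f"patients:{var}:{tissue}"] = {
                    "r": float(r), "p": float(p)}
            else:
                r, p, pr, pp = pearson_and_partial(sub[var], sub[tissue],
                                                   sub["age"])
                report.correlations[f"patients:{var}:{tissue}"] = {
                    "r": r, "p": p, "partial_r": pr, "partial_p": pp}
    controls = df[df["group"] == "control"]
    if "age" in df.columns and len(controls) >= 4:
        for tissue in tissues:
            sub = controls[["age", tissue]].dropna()
            if len(sub) < 4:
                continue
            r, p = sps.pearsonr(sub["age"], sub[tissue])
            report.correlations[f"controls:age:{tissue}"] = {
                "r": float(r), "p": float(p)}
    return report
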