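"""Cohort-level statistics for ALPS analyses.

Covers the full battery used for ALPS group comparisons: control-based
age adjustment, one-way ANCOVA with Fisher-LSD post-hoc tests and partial
eta-squared effect sizes, partial and Pearson correlations, paired t-tests
with Cohen's d, Bland-Altman method agreement (numeric and percent),
seeded greedy case-control matching, MDS-UPDRS-III subscores, and a
DAT-SPECT-lateralised hemisphere comparison.

Age adjustment removes the normal ageing decline of the index using the
control group only:

    adjusted_i = raw_i - beta * (age_i - mean_age_controls)

with beta the OLS slope of the raw index on age among controls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from dtialps.errors import (
    DegenerateDesignError,
    InputError,
    SchemaError,
)

# MDS-UPDRS III subscore item sets (part-III motor examination items).
# Item 9 appears in both the bradykinesia and axial sets as published;
# kept verbatim (flagged as a possible typo in the source convention).
UPDRS3_SUBSCORE_ITEMS = {
    "tremor": (15, 16, 17, 18),
    "bradykinesia": (2, 4, 5, 6, 7, 8, 9, 14),
    "rigidity": (3,),
    "axial": (1, 9, 10, 11, 12, 13),
}


@dataclass
class AdjustmentModel:
    """Control-fitted linear age model for index adjustment."""

    beta: float  # index units per year
    age_mean: float  # years, mean age of the fitting (control) sample
    reference_group: str = "HC"


@dataclass
class AncovaResult:
    f: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    ss_group: float
    ss_error: float
    adjusted_means: dict[str, float]
    lsd_pairwise_p: dict[tuple[str, str], float]
    lsd_pairwise_t: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class AgreementResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    fraction_outside: float
    slope: float
    slope_p: float
    mode: str  # numeric | percent
    n: int


@dataclass
class CorrelationResult:
    r: float
    df: int
    p: float
    covariates: tuple[str, ...] = ()


def fit_age_adjustment(
    raw: np.ndarray, age: np.ndarray, reference_group: str = "HC"
) -> AdjustmentModel:
    """OLS slope of the raw index on age within the reference (control) group."""
    raw = np.asarray(raw, dtype=float)
    age = np.asarray(age, dtype=float)
    if raw.shape != age.shape or raw.ndim != 1:
        raise InputError("raw indices and ages must be matching 1-D arrays")
    if len(raw) < 3:
        raise DegenerateDesignError("need at least 3 control subjects")
    if np.var(age) == 0:
        raise DegenerateDesignError("control ages have zero variance")
    beta = np.polyfit(age, raw, 1)[0]
    return AdjustmentModel(beta=float(beta), age_mean=float(age.mean()),
                           reference_group=reference_group)


def apply_age_adjustment(
    raw: np.ndarray | float, age: np.ndarray | float, model: AdjustmentModel
) -> np.ndarray | float:
    """adjusted = raw - beta * (age - control mean age)."""
    return np.asarray(raw, dtype=float) - model.beta * (np.asarray(age, dtype=float) - model.age_mean)


def _design(group: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, list[str], np.ndarray]:
    levels = sorted(pd.unique(group))
    n = len(group)
    dummies = np.column_stack([(group == lv).astype(float) for lv in levels[1:]])
    cols = [np.ones((n, 1))]
    if covariates is not None and covariates.size:
        cols.append(covariates)
    X_reduced = np.hstack(cols)
    X_full = np.hstack([X_reduced, dummies])
    return X_full, levels, X_reduced


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def ancova_oneway(
    values,
    group,
    covariates=None,
) -> AncovaResult:
    """One-way ANCOVA: group effect on ``values`` controlling for covariates.

    Covariates enter the linear model before group; the group F statistic
    is the incremental sum of squares of the group dummies over the
    covariate-only model against the full-model error.  LSD post-hoc
    contrasts compare covariate-adjusted group means with the pooled error
    variance and report unadjusted two-tailed p-values (that is what
    Fisher's least-significant-difference method means; no further
    multiplicity correction).  Partial eta^2 = SS_group / (SS_group +
    SS_error).
    """
    y = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if covariates is None:
        covs = None
        n_cov = 0
    else:
        covs = np.asarray(covariates, dtype=float)
        if covs.ndim == 1:
            covs = covs[:, None]
        n_cov = covs.shape[1]
    levels = sorted(pd.unique(group))
    if len(levels) < 2:
        raise DegenerateDesignError("ANCOVA needs at least two groups")
    for lv in levels:
        if (group == lv).sum() < 2:
            raise DegenerateDesignError(f"group {lv!r} has fewer than 2 subjects")

    X_full, levels, X_reduced = _design(group, covs)
    n = len(y)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise DegenerateDesignError("singular ANCOVA design matrix")

    rss_full = _rss(X_full, y)
    rss_reduced = _rss(X_reduced, y)
    df1 = len(levels) - 1
    df2 = n - len(levels) - n_cov
    ss_group = rss_reduced - rss_full
    ss_error = rss_full
    mse = ss_error / df2
    f = (ss_group / df1) / mse if mse > 0 else np.inf
    p = float(sp_stats.f.sf(f, df1, df2))

    # covariate-adjusted means: prediction at the grand covariate mean
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    xtx_inv = np.linalg.pinv(X_full.T @ X_full)
    cov_mean = covs.mean(axis=0) if covs is not None else np.empty(0)
    adjusted_means = {}
    rows = {}
    for i, lv in enumerate(levels):
        row = np.concatenate([[1.0], cov_mean, np.zeros(df1)])
        if i > 0:
            row[1 + n_cov + i - 1] = 1.0
        rows[lv] = row
        adjusted_means[lv] = float(row @ beta)

    lsd_p, lsd_t = {}, {}
    for a, b in itertools.combinations(levels, 2):
        c = rows[a] - rows[b]
        se = float(np.sqrt(mse * c @ xtx_inv @ c))
        t = float(c @ beta) / se
        lsd_t[(a, b)] = t
        lsd_p[(a, b)] = float(2 * sp_stats.t.sf(abs(t), df2))

    eta = partial_eta_squared_from_f(f, df1, df2)
    return AncovaResult(
        f=float(f), df1=df1, df2=df2, p=p, partial_eta_sq=eta,
        ss_group=float(ss_group), ss_error=float(ss_error),
        adjusted_means=adjusted_means, lsd_pairwise_p=lsd_p, lsd_pairwise_t=lsd_t,
    )


def partial_eta_squared_from_f(f: float, df1: int, df2: int) -> float:
    """Partial eta^2 recovered from an F statistic: F*df1 / (F*df1 + df2)."""
    if f < 0 or df1 < 1 or df2 < 1:
        raise InputError("need F >= 0 and dfs >= 1")
    return float(f * df1 / (f * df1 + df2))


def partial_correlation(x, y, covariates=None) -> CorrelationResult:
    """Correlation of x and y after removing linear covariate effects.

    Residualises both variables on the covariates (with intercept) and
    correlates the residuals; df = n - 2 - n_covariates, two-tailed p from
    the t transform r * sqrt(df / (1 - r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        covs = np.ones((n, 1))
        n_cov = 0
    else:
        covs = np.asarray(covariates, dtype=float)
        if covs.ndim == 1:
            covs = covs[:, None]
        n_cov = covs.shape[1]
        covs = np.hstack([np.ones((n, 1)), covs])
    if n <= 2 + n_cov:
        raise DegenerateDesignError("too few observations for the requested covariates")

    def _resid(v):
        beta, *_ = np.linalg.lstsq(covs, v, rcond=None)
        return v - covs @ beta

    rx, ry = _resid(x), _resid(y)
    if np.allclose(rx, rx[0]) or np.allclose(ry, ry[0]):
        raise DegenerateDesignError("constant residuals: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - n_cov
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r ** 2))
        p = float(2 * sp_stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, df=df, p=p)


def cohens_d_from_summary(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Cohen's d with the averaged-variance denominator.

    d = (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2).  This is the
    default paired-comparison effect size here; see
    :func:`paired_t_and_cohens_d` for the d_z alternative.
    """
    denom = np.sqrt((sd_a ** 2 + sd_b ** 2) / 2.0)
    if denom == 0:
        return 0.0
    return float((mean_a - mean_b) / denom)


def paired_t_and_cohens_d(a, b, d_variant: str = "average_variance") -> dict:
    """Paired t-test plus Cohen's d for two paired measurement series.

    ``d_variant``: ``average_variance`` (default) uses
    (mean_a - mean_b)/sqrt((SD_a^2 + SD_b^2)/2); ``dz`` uses
    mean(diff)/SD(diff).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired vectors must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise InputError("need at least 2 pairs")
    diff = a - b
    sd_diff = diff.std(ddof=1)
    if sd_diff == 0:
        # constant differences: t is 0 for identical series, infinite otherwise
        t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        p = 1.0 if diff.mean() == 0 else 0.0
    else:
        t, p = sp_stats.ttest_rel(a, b)
    if d_variant == "average_variance":
        d = cohens_d_from_summary(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1))
    elif d_variant == "dz":
        d = float(diff.mean() / sd_diff) if sd_diff > 0 else 0.0
    else:
        raise InputError(f"unknown Cohen's d variant {d_variant!r}")
    return {"t": float(t), "df": n - 1, "p": float(p), "d": d, "n": n}


def bland_altman(a, b, mode: str = "numeric") -> AgreementResult:
    """Bland-Altman agreement between two paired measurement series.

    Differences are ``a - b`` (percent mode: 100 * (a - b) / pairwise
    mean); limits of agreement are bias +/- 1.96 * SD of the differences.
    Proportional bias is the slope of the differences regressed on the
    pairwise means, with its two-tailed p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired vectors must be 1-D and equal length")
    if mode not in ("numeric", "percent"):
        raise InputError(f"unknown Bland-Altman mode {mode!r}")
    means = (a + b) / 2.0
    diffs = a - b
    if mode == "percent":
        zero = np.flatnonzero(means == 0)
        if zero.size:
            raise InputError(f"zero pairwise mean at indices {zero.tolist()}: percent undefined")
        diffs = 100.0 * diffs / means
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = float(np.mean((diffs < lo) | (diffs > hi)))
    if len(a) > 2 and np.var(means) > 0:
        reg = sp_stats.linregress(means, diffs)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    else:
        slope, slope_p = 0.0, 1.0
    return AgreementResult(
        bias=bias, sd=sd, loa_low=float(lo), loa_high=float(hi),
        fraction_outside=outside, slope=slope, slope_p=slope_p, mode=mode, n=len(a),
    )


def match_case_control(
    cohort: pd.DataFrame,
    case_group: str = "PD",
    other_groups: tuple[str, str] = ("iRBD", "HC"),
    age_tolerance: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Greedy seeded 1:1:1 age/sex matching across three groups.

    Cases are visited in a seed-randomised order; each case claims, from
    every other group, the unused subject of identical sex whose age is
    nearest (and within ``age_tolerance`` years).  Cases lacking a
    complete triplet are dropped, so the returned subset has equal group
    sizes.  Greedy matching never exceeds — and may fall below — the
    exhaustive maximum number of triplets.
    """
    for col in ("subject_id", "group", "age", "sex"):
        if col not in cohort.columns:
            raise SchemaError(f"cohort table lacks column {col!r}")
    groups = (case_group,) + tuple(other_groups)
    for g in groups:
        if not (cohort["group"] == g).any():
            raise InputError(f"group {g!r} has no subjects")
    rng = np.random.default_rng(seed)
    cases = cohort[cohort["group"] == case_group].sample(frac=1.0, random_state=rng.integers(2 ** 31))
    pools = {g: cohort[cohort["group"] == g].copy() for g in other_groups}
    used: dict[str, set] = {g: set() for g in other_groups}
    matched_ids: list[str] = []
    for case in cases.itertuples():
        picks = {}
        for g in other_groups:
            pool = pools[g]
            cand = pool[
                (pool["sex"] == case.sex)
                & ((pool["age"] - case.age).abs() <= age_tolerance)
                & (~pool["subject_id"].isin(used[g]))
            ]
            if cand.empty:
                picks = {}
                break
            # nearest age; deterministic tie-break by subject id
            order = (cand["age"] - case.age).abs()
            best = cand.assign(_d=order).sort_values(["_d", "subject_id"]).iloc[0]
            picks[g] = best["subject_id"]
        if picks:
            matched_ids.append(case.subject_id)
            for g, sid in picks.items():
                used[g].add(sid)
                matched_ids.append(sid)
    if not matched_ids:
        raise InputError("no complete age/sex-matched triplets could be formed")
    return cohort[cohort["subject_id"].isin(matched_ids)].copy()


def updrs_subscores(items: pd.DataFrame, prefix: str = "updrs3_item") -> pd.DataFrame:
    """Tremor / bradykinesia / rigidity / axial sums from part-III items."""
    out = {}
    for name, idx in UPDRS3_SUBSCORE_ITEMS.items():
        cols = [f"{prefix}{i}" for i in idx]
        missing = [c for c in cols if c not in items.columns]
        if missing:
            raise SchemaError(f"missing UPDRS item columns {missing}")
        block = items[cols]
        if (block.to_numpy() < 0).any():
            raise InputError("UPDRS items must be non-negative")
        out[name] = block.sum(axis=1)
    return pd.DataFrame(out, index=items.index)


def hemisphere_asymmetry_test(
    alps_left, alps_right, sbr_left, sbr_right
) -> dict:
    """Paired t of ALPS between the more- and less-denervated hemispheres.

    The hemisphere with the lower SBR Z-score is the more affected one.
    Subjects with exactly tied SBR Z-scores are excluded (count reported).
    """
    alps_left = np.asarray(alps_left, dtype=float)
    alps_right = np.asarray(alps_right, dtype=float)
    sbr_left = np.asarray(sbr_left, dtype=float)
    sbr_right = np.asarray(sbr_right, dtype=float)
    tied = sbr_left == sbr_right
    n_tied = int(tied.sum())
    keep = ~tied
    if not keep.any():
        raise InputError("all subjects have tied SBR Z-scores; no lateralisation")
    more = np.where(sbr_left[keep] < sbr_right[keep], alps_left[keep], alps_right[keep])
    less = np.where(sbr_left[keep] < sbr_right[keep], alps_right[keep], alps_left[keep])
    result = paired_t_and_cohens_d(more, less)
    result["n_tied_excluded"] = n_tied
    return result


def describe_cohort(
    cohort: pd.DataFrame,
    score_columns: tuple[str, ...] = ("moca", "updrs1_total", "updrs2_total", "updrs3_total"),
) -> dict:
    """Demographics table: per-group mean +/- SD, sex chi-square, age ANOVA,
    and age+sex ANCOVA for clinical scores.

    The chi-square uses no continuity correction (plain Pearson statistic).
    """
    for col in ("group", "age", "sex"):
        if col not in cohort.columns:
            raise SchemaError(f"cohort table lacks column {col!r}")
    levels = sorted(pd.unique(cohort["group"]))
    if len(levels) < 2:
        raise DegenerateDesignError("need at least two groups to describe")

    out: dict = {"groups": {}, "tests": {}}
    for g in levels:
        sub = cohort[cohort["group"] == g]
        entry = {
            "n": int(len(sub)),
            "male_n": int((sub["sex"] == "M").sum()),
            "male_pct": float(100 * (sub["sex"] == "M").mean()),
            "age_mean": float(sub["age"].mean()),
            "age_sd": float(sub["age"].std(ddof=1)),
        }
        for col in score_columns:
            if col in cohort.columns:
                entry[f"{col}_mean"] = float(sub[col].mean())
                entry[f"{col}_sd"] = float(sub[col].std(ddof=1))
        out["groups"][g] = entry

    table = pd.crosstab(cohort["group"], cohort["sex"])
    chi2, chi_p, chi_df, _ = sp_stats.chi2_contingency(table, correction=False)
    out["tests"]["sex_chi2"] = {"chi2": float(chi2), "df": int(chi_df), "p": float(chi_p)}

    age_by_group = [cohort.loc[cohort["group"] == g, "age"].to_numpy() for g in levels]
    f, p = sp_stats.f_oneway(*age_by_group)
    out["tests"]["age_anova"] = {"f": float(f), "p": float(p)}

    sex_code = (cohort["sex"] == "M").astype(float).to_numpy()
    covs = np.column_stack([cohort["age"].to_numpy(dtype=float), sex_code])
    for col in score_columns:
        if col in cohort.columns:
            res = ancova_oneway(cohort[col].to_numpy(dtype=float), cohort["group"].to_numpy(), covs)
            out["tests"][f"{col}_ancova"] = {
                "f": res.f, "df1": res.df1, "df2": res.df2, "p": res.p,
                "partial_eta_sq": res.partial_eta_sq,
                "pairwise_p": {f"{a}|{b}": v for (a, b), v in res.lsd_pairwise_p.items()},
            }
    return out


def max_triplet_count(cohort: pd.DataFrame, case_group: str = "PD",
                      other_groups: tuple[str, str] = ("iRBD", "HC"),
                      age_tolerance: float = 8.0) -> int:
    """Exhaustive maximum number of complete matched triplets.

    Exponential search over case/partner assignments; intended for small
    rosters (<= ~12 per group) as a correctness bound on the greedy matcher.
    """
    cases = cohort[cohort["group"] == case_group][["subject_id", "age", "sex"]].to_numpy()
    pools = [
        cohort[cohort["group"] == g][["subject_id", "age", "sex"]].to_numpy()
        for g in other_groups
    ]

    def compatible(case, member):
        return case[2] == member[2] and abs(case[1] - member[1]) <= age_tolerance

    best = 0

    def search(ci: int, used0: frozenset, used1: frozenset, count: int) -> None:
        nonlocal best
        remaining = len(cases) - ci
        if count + remaining <= best:
            return
        if ci == len(cases):
            best = max(best, count)
            return
        case = cases[ci]
        search(ci + 1, used0, used1, count)  # skip this case
        for i, m0 in enumerate(pools[0]):
            if i in used0 or not compatible(case, m0):
                continue
            for j, m1 in enumerate(pools[1]):
                if j in used1 or not compatible(case, m1):
                    continue
                search(ci + 1, used0 | {i}, used1 | {j}, count + 1)

    search(0, frozenset(), frozenset(), 0)
    return best
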