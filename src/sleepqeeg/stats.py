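"""Group-comparison statistics.

Pearson chi-square for categorical tables, Kruskal-Wallis and one-way
ANOVA (from raw data or printed summary statistics) for continuous
variables, covariate-adjusted ANCOVA with Bonferroni-corrected group
tests and pairwise post-hoc contrasts, and 1:k nearest-neighbour
propensity-score matching on a logistic model of binned covariates.

Conventions: chi-square carries no continuity correction; the ANCOVA
group effect is the extra-sum-of-squares F from dropping the group
dummies (equivalent to Type III for a single factor plus covariates);
post-hoc pairwise p values are multiplied by the number of pairs
(6 for four groups) and capped at 1; family-level Bonferroni factors
(x5 over the five bands for total sleep, x10 over the NREM+REM
families) are applied via :func:`bonferroni`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grouping import GROUPS


class DegenerateTableError(ValueError):
    """A contingency table has a zero margin; chi-square is undefined."""


class RankDeficientDesignError(ValueError):
    """The ANCOVA design matrix is collinear."""


class InsufficientControlsError(ValueError):
    """Not enough unique controls for matching without replacement."""


@dataclass
class StatTestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    df: Tuple[float, ...]
    p_raw: float
    test: str
    p_corrected: Optional[float] = None
    correction_factor: Optional[float] = None
    degenerate: bool = False

    def with_correction(self, factor: float) -> "StatTestResult":
        self.p_corrected = bonferroni(self.p_raw, factor)
        self.correction_factor = factor
        return self


def bonferroni(p_raw: float, factor: float) -> float:
    """min(1, p * factor); the family-size multiplier, capped at 1."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p_raw must be in [0, 1], got {p_raw}")
    if factor < 1:
        raise ValueError(f"correction factor must be >= 1, got {factor}")
    return min(1.0, p_raw * factor)


def format_p(p: Optional[float]) -> str:
    """Report-style rendering: values above 0.999 print as ``>0.999``."""
    if p is None:
        return ""
    if p > 0.999:
        return ">0.999"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def pearson_chi_square(table) -> StatTestResult:
    """Pearson chi-square of independence, no continuity correction.

    ``table`` is an r x c array of counts (rows e.g. groups, columns
    categories).  Expected counts come from the margins; a zero margin
    raises :class:`DegenerateTableError`.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts < 0).any() or counts.sum() <= 0:
        raise ValueError("contingency table must hold non-negative counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return StatTestResult(statistic=float(chi2), df=(float(dof),),
                          p_raw=float(p), test="chi2")


def _group_arrays(values, group_labels) -> List[np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    order = [g for g in GROUPS if g in labels] or list(pd.unique(labels))
    return [values[labels == g] for g in order]


def one_way_anova(values, group_labels) -> StatTestResult:
    """Classic one-way fixed-effects ANOVA on raw observations.

    Delegates to the summary-statistic decomposition (identical
    algebra), so degenerate inputs -- equal group means with zero
    within-group variance -- report F = 0 with a degenerate flag
    instead of 0/0.
    """
    groups = _group_arrays(values, group_labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) for g in groups])
    return anova_from_summary(n, means, sds)


def anova_from_summary(n_g, mean_g, sd_g) -> StatTestResult:
    """One-way ANOVA reconstructed from per-group n / mean / SD.

    SSB = sum n_g (m_g - m)^2, SSW = sum (n_g - 1) s_g^2 -- lets printed
    summary rows be re-tested without the raw data.
    """
    n = np.asarray(n_g, dtype=float)
    means = np.asarray(mean_g, dtype=float)
    sds = np.asarray(sd_g, dtype=float)
    if len(n) < 2 or (n < 2).any():
        raise ValueError("summary ANOVA needs >= 2 groups with n_g >= 2")
    grand = np.sum(n * means) / np.sum(n)
    ssb = float(np.sum(n * (means - grand) ** 2))
    ssw = float(np.sum((n - 1) * sds ** 2))
    df_b = len(n) - 1.0
    df_w = float(np.sum(n) - len(n))
    if ssw == 0.0:
        # all within-group variance zero: either perfectly separated
        # (infinite F) or fully degenerate (report 0)
        if ssb == 0.0:
            return StatTestResult(0.0, (df_b, df_w), 1.0, "anova", degenerate=True)
        return StatTestResult(float("inf"), (df_b, df_w), 0.0, "anova",
                              degenerate=True)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return StatTestResult(statistic=float(f), df=(df_b, df_w), p_raw=p, test="anova")


def kruskal_wallis(values, group_labels) -> StatTestResult:
    """Rank-based Kruskal-Wallis H with tie correction, chi-square p."""
    groups = _group_arrays(values, group_labels)
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    df = float(len(groups) - 1)
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return StatTestResult(0.0, (df,), 1.0, "kruskal", degenerate=True)
    h, p = sps.kruskal(*groups)
    return StatTestResult(statistic=float(h), df=(df,), p_raw=float(p),
                          test="kruskal")


# --- ANCOVA ---------------------------------------------------------------

@dataclass
class AncovaResult:
    """Covariate-adjusted group comparison of one outcome."""

    f_statistic: float
    df: Tuple[float, float]
    p_raw: float
    p_corrected: Optional[float]
    correction_factor: Optional[float]
    group_levels: Tuple[str, ...]
    adjusted_means: Dict[str, float]
    coefficients: pd.DataFrame
    posthoc: pd.DataFrame
    n: int

    @property
    def significant_pairs(self) -> List[Tuple[str, str]]:
        sig = self.posthoc[self.posthoc["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


def _incremental_rank_check(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    offending = []
    for j in range(1, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :j]) < j:
            offending.append(names[j - 1])
    raise RankDeficientDesignError(
        f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
        f"collinear column(s): {offending}")


def ancova_group_comparison(outcome, group_labels,
                            covariates: Optional[pd.DataFrame] = None,
                            posthoc_factor: Optional[float] = None,
                            correction_factor: Optional[float] = None,
                            alpha: float = 0.05) -> AncovaResult:
    """Linear-model group comparison adjusted for covariates.

    Fits ``outcome ~ group + covariates`` by OLS; the group effect is
    the extra-sum-of-squares F against the covariate-only model.
    Adjusted group means are model predictions at the covariate means.
    Post-hoc: pairwise contrasts of adjusted means, each two-sided p
    multiplied by the number of pairs (Bonferroni) and capped at 1.
    With no covariates this reduces exactly to one-way ANOVA with
    Bonferroni pairwise comparisons.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    labels = np.asarray(group_labels)
    levels = tuple(g for g in GROUPS if g in labels) or tuple(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("ANCOVA needs a group factor with >= 2 levels")
    k = len(levels)

    dummies = np.column_stack([(labels == g).astype(float) for g in levels[1:]])
    dummy_names = [f"group[{g}]" for g in levels[1:]]
    if covariates is not None and len(covariates.columns):
        C = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        C = np.empty((len(y), 0))
        cov_names = []
    X_full = np.column_stack([np.ones(len(y)), dummies, C])
    names = ["intercept"] + dummy_names + cov_names
    _incremental_rank_check(X_full, names)

    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, np.column_stack([np.ones(len(y)), C])).fit()
    df_num = float(k - 1)
    df_den = float(full.df_resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    degenerate = full.ssr <= 1e-12 * max(tss, 1.0)
    if degenerate:
        # (near-)constant outcome or saturated fit: report a null effect
        f, p_raw = 0.0, 1.0
    else:
        f = max(0.0, (reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
        p_raw = float(sps.f.sf(f, df_num, df_den))

    coef = pd.DataFrame({
        "term": names,
        "estimate": full.params,
        "se": full.bse,
        "t": full.tvalues,
        "p": full.pvalues,
    })

    cov_means = C.mean(axis=0) if C.size else np.empty(0)
    cov_beta = full.params[k:]
    base = float(full.params[0] + cov_means @ cov_beta)
    adjusted = {levels[0]: base}
    for i, g in enumerate(levels[1:]):
        adjusted[g] = base + float(full.params[1 + i])

    if posthoc_factor is None:
        posthoc_factor = comb(k, 2)
    V = np.asarray(full.cov_params())
    rows = []
    for a, b in combinations(levels, 2):
        c = np.zeros(X_full.shape[1])
        if a != levels[0]:
            c[1 + levels[1:].index(a)] += 1.0
        if b != levels[0]:
            c[1 + levels[1:].index(b)] -= 1.0
        diff = float(c @ full.params)
        se = float(np.sqrt(c @ V @ c))
        usable = se > 0 and not degenerate
        t = diff / se if usable else 0.0
        p = float(2.0 * sps.t.sf(abs(t), df_den)) if usable else 1.0
        p_adj = bonferroni(p, posthoc_factor)
        rows.append({"group_a": a, "group_b": b, "diff_adjusted": diff,
                     "se": se, "t": t, "p_raw": p, "p_bonferroni": p_adj,
                     "significant": p_adj < alpha})
    posthoc = pd.DataFrame(rows)

    p_corrected = (bonferroni(p_raw, correction_factor)
                   if correction_factor is not None else None)
    return AncovaResult(
        f_statistic=float(f), df=(df_num, df_den), p_raw=p_raw,
        p_corrected=p_corrected, correction_factor=correction_factor,
        group_levels=levels, adjusted_means=adjusted,
        coefficients=coef, posthoc=posthoc, n=len(y))


# --- propensity matching --------------------------------------------------

AGE_BIN_EDGES = (50.0, 60.0, 70.0)

MATCHING_COVARIATES = ("age", "sex_female", "ahi", "alcohol_per_day",
                       "current_smoking", "tca", "non_tca", "benzodiazepine")


def propensity_design(records: pd.DataFrame) -> pd.DataFrame:
    """Binned covariate design for the propensity model.

    Age enters as four-group dummies (<50, 50-59, 60-69 reference >=70),
    AHI as a binary >15 indicator; sex, smoking, alcohol intake and the
    three medication flags enter directly.
    """
    age = records["age"].to_numpy(dtype=float)
    out = pd.DataFrame(index=records.index)
    out["age_lt50"] = (age < AGE_BIN_EDGES[0]).astype(float)
    out["age_50_59"] = ((age >= AGE_BIN_EDGES[0]) & (age < AGE_BIN_EDGES[1])).astype(float)
    out["age_60_69"] = ((age >= AGE_BIN_EDGES[1]) & (age < AGE_BIN_EDGES[2])).astype(float)
    out["sex_female"] = records["sex_female"].astype(float)
    out["ahi_gt15"] = (records["ahi"].to_numpy(dtype=float) > 15.0).astype(float)
    out["alcohol_per_day"] = records["alcohol_per_day"].astype(float)
    out["current_smoking"] = records["current_smoking"].astype(float)
    for med in ("tca", "non_tca", "benzodiazepine"):
        out[med] = records[med].astype(float)
    return out


@dataclass
class MatchResult:
    """Outcome of 1:k nearest-neighbour matching without replacement."""

    matches: Dict[object, Tuple[object, ...]]
    propensity: pd.Series
    logit: pd.Series
    treated_label: str
    control_label: str
    ratio: int
    seed: int

    @property
    def matched_control_ids(self) -> List[object]:
        return [c for controls in self.matches.values() for c in controls]

    @property
    def n_matched_controls(self) -> int:
        return len(self.matched_control_ids)

    def matched_ids(self) -> List[object]:
        return list(self.matches.keys()) + self.matched_control_ids


def propensity_match(records: pd.DataFrame, treated_label: str,
                     control_label: str, group_col: str = "group",
                     id_col: str = "participant_id", ratio: int = 5,
                     seed: int = 0, allow_partial: bool = False) -> MatchResult:
    """1:``ratio`` nearest-neighbour propensity matching without replacement.

    A logistic regression of treated-vs-control membership on the
    binned covariate design yields each participant's propensity;
    treated participants are processed in descending propensity order
    and each takes the ``ratio`` nearest unused controls by absolute
    logit distance.  Exact distance ties are broken by a seeded random
    ordering, making the selection deterministic given the seed.

    Raises
    ------
    InsufficientControlsError
        If the control pool is smaller than ``ratio x n_treated`` and
        ``allow_partial`` is False.
    """
    from sklearn.linear_model import LogisticRegression

    sub = records[records[group_col].isin([treated_label, control_label])]
    treated_mask = (sub[group_col] == treated_label).to_numpy()
    n_treated = int(treated_mask.sum())
    n_control = len(sub) - n_treated
    if n_treated == 0:
        raise ValueError(f"no participants with group {treated_label!r}")
    if n_control < ratio * n_treated and not allow_partial:
        raise InsufficientControlsError(
            f"matching 1:{ratio} needs {ratio * n_treated} controls, "
            f"only {n_control} available")

    X = propensity_design(sub).to_numpy()
    # C=inf: unpenalised maximum-likelihood fit
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    model.fit(X, treated_mask.astype(int))
    logit = model.decision_function(X)
    prop = 1.0 / (1.0 + np.exp(-logit))

    ids = sub[id_col].to_numpy()
    t_idx = np.flatnonzero(treated_mask)
    c_idx = np.flatnonzero(~treated_mask)
    t_order = t_idx[np.argsort(-prop[t_idx], kind="stable")]

    rng = np.random.default_rng(seed)
    tiebreak = rng.random(len(sub))
    used = np.zeros(len(sub), dtype=bool)
    matches: Dict[object, Tuple[object, ...]] = {}
    for ti in t_order:
        free = c_idx[~used[c_idx]]
        take = min(ratio, len(free))
        dist = np.abs(logit[free] - logit[ti])
        order = np.lexsort((tiebreak[free], dist))
        chosen = free[order[:take]]
        used[chosen] = True
        matches[ids[ti]] = tuple(ids[chosen])

    return MatchResult(
        matches=matches,
        propensity=pd.Series(prop, index=ids, name="propensity"),
        logit=pd.Series(logit, index=ids, name="logit"),
        treated_label=treated_label, control_label=control_label,
        ratio=ratio, seed=seed)
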