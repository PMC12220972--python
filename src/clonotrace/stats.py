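"""Mixed-effects and nonparametric comparison layer.

Cluster-count outcomes (log10-transformed, optionally normalized per
cell) are compared between specimen types or matched statuses with a
linear mixed model: the contrast is a fixed effect and patient a random
intercept, fit by REML.  Nonparametric comparisons dispatch to
Mann-Whitney U (2 unpaired groups), Wilcoxon signed-rank (2 paired),
Kruskal-Wallis or Friedman with Dunn's multiple-comparison z-tests
(>= 3 groups).  FDR control is Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class MixedModelResult:
    coef: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float
    re_var: float
    resid_var: float
    n_obs: int
    contrast: str
    reference: str
    method: str = "REML"
    converged: bool = True
    degenerate: bool = False


@dataclass
class TestResult:
    test_name: str
    statistic: float
    pvalue: float
    n_groups: int
    pairwise: pd.DataFrame | None = field(default=None, repr=False)


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def fit_cluster_count_model(df: pd.DataFrame, value_col: str = "n_clusters",
                            group_col: str = "compartment",
                            patient_col: str = "patient_id",
                            reference: str | None = None,
                            normalize_col: str | None = None,
                            log10: bool = True) -> MixedModelResult:
    """Random-intercept model of (log10) cluster counts on a 2-level contrast.

    The coefficient is the non-reference level minus the reference level
    on the outcome scale.  ``normalize_col`` (e.g. n_cells) divides the
    outcome before the log transform, matching per-cell normalized
    network metrics.  Requires >= 2 patients and both contrast levels;
    a zero-variance outcome returns a degenerate flagged result; a
    non-converged/singular REML fit is flagged, not silently dropped.
    """
    data = df[[patient_col, group_col, value_col]
              + ([normalize_col] if normalize_col else [])].dropna().copy()
    levels = sorted(data[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"contrast must have exactly 2 levels, got {levels}")
    if data[patient_col].nunique() < 2:
        raise ValueError("need >= 2 patients for a random-intercept model")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not among levels {levels}")
    other = next(l for l in levels if l != ref)

    y = data[value_col].astype(float)
    if normalize_col:
        y = y / data[normalize_col].astype(float)
    if log10:
        if (y <= 0).any():
            raise ValueError("outcome must be positive for log10 transform")
        y = np.log10(y)
    x = (data[group_col].astype(str) == other).astype(float)

    if np.ptp(y.to_numpy()) == 0.0:
        return MixedModelResult(
            coef=0.0, se=float("nan"), pvalue=1.0, ci_low=0.0, ci_high=0.0,
            re_var=0.0, resid_var=0.0, n_obs=len(y), contrast=f"{other}-{ref}",
            reference=ref, degenerate=True,
        )

    exog = sm.add_constant(x.to_numpy())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        # a zero patient-variance estimate is legitimate (boundary), not an error
        warnings.filterwarnings("ignore", message="Random effects covariance is singular")
        try:
            fit = sm.MixedLM(y.to_numpy(), exog, groups=data[patient_col].to_numpy()
                             ).fit(reml=True)
        except (ConvergenceWarning, np.linalg.LinAlgError, ValueError):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(y.to_numpy(), exog, groups=data[patient_col].to_numpy()
                                 ).fit(reml=True, method="nm")
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    # small-sample inference: t reference with within-patient df, as in
    # lmerTest-style df corrections (Wald-normal intervals undercover
    # with a handful of patients)
    ddf = max(1, int(len(y)) - int(data[patient_col].nunique()) - 1)
    tcrit = float(sps.t.ppf(0.975, ddf))
    pvalue = float(2.0 * sps.t.sf(abs(coef / se), ddf)) if se > 0 else 1.0
    return MixedModelResult(
        coef=coef, se=se, pvalue=pvalue,
        ci_low=coef - tcrit * se, ci_high=coef + tcrit * se,
        re_var=float(np.asarray(fit.cov_re)[0, 0]), resid_var=float(fit.scale),
        n_obs=int(len(y)), contrast=f"{other}-{ref}", reference=ref,
        converged=converged and bool(getattr(fit, "converged", True)),
    )


def fit_per_phenotype(df: pd.DataFrame, phenotype_col: str = "phenotype",
                      **kwargs) -> pd.DataFrame:
    """Fit the cluster-count model per phenotype; BH-adjust the p-values."""
    rows = []
    for phen, grp in df.groupby(phenotype_col, observed=True):
        try:
            res = fit_cluster_count_model(grp, **kwargs)
        except ValueError as exc:
            rows.append({"phenotype": phen, "coef": np.nan, "se": np.nan,
                         "pvalue": np.nan, "error": str(exc)})
            continue
        rows.append({"phenotype": phen, "coef": res.coef, "se": res.se,
                     "pvalue": res.pvalue, "degenerate": res.degenerate,
                     "converged": res.converged, "error": None})
    out = pd.DataFrame(rows)
    ok = out["pvalue"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = adjust_fdr(out.loc[ok, "pvalue"])
    return out


# ---------------------------------------------------------------------------
# Nonparametric comparisons with Dunn's post hoc
# ---------------------------------------------------------------------------

def _dunn_unpaired(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks after Kruskal-Wallis, Bonferroni adj."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        sigma = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / sigma if sigma > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z,
                     "pvalue": p, "pvalue_adj": min(1.0, p * m)})
    return pd.DataFrame(rows)


def _dunn_paired(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's z-tests on within-block rank sums after Friedman, Bonferroni."""
    mat = np.column_stack(groups)  # blocks x treatments
    b, k = mat.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, mat)
    rank_sums = ranks.sum(axis=0)
    sigma = np.sqrt(b * k * (k + 1) / 6.0)
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        z = (rank_sums[i] - rank_sums[j]) / sigma
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z,
                     "pvalue": p, "pvalue_adj": min(1.0, p * m)})
    return pd.DataFrame(rows)


def nonparam_compare(groups, design: str = "unpaired", labels=None) -> TestResult:
    """Dispatch the appropriate rank test for the design and group count.

    2 unpaired groups: Mann-Whitney U.  2 paired: Wilcoxon signed-rank
    (identical groups give p = 1).  >= 3 groups: Kruskal-Wallis
    (unpaired) or Friedman (paired), each followed by Dunn's
    Bonferroni-adjusted pairwise z-tests.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations")
    if design == "paired" and len({len(g) for g in groups}) != 1:
        raise ValueError("paired design requires aligned, equal-length groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]

    if len(groups) == 2:
        a, b = groups
        if design == "unpaired":
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            return TestResult("mann_whitney", float(stat), float(p), 2)
        diffs = a - b
        if np.all(diffs == 0):
            return TestResult("wilcoxon_signed_rank", 0.0, 1.0, 2)
        stat, p = sps.wilcoxon(a, b)
        return TestResult("wilcoxon_signed_rank", float(stat), float(p), 2)

    if design == "unpaired":
        stat, p = sps.kruskal(*groups)
        pairwise = _dunn_unpaired(groups, labels)
        return TestResult("kruskal_dunn", float(stat), float(p), len(groups), pairwise)
    stat, p = sps.friedmanchisquare(*groups)
    pairwise = _dunn_paired(groups, labels)
    return TestResult("friedman_dunn", float(stat), float(p), len(groups), pairwise)
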