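"""Differential phosphorylation statistics.

Site-wise inference follows the standard small-sample empirical-Bayes scheme
for isobaric-label designs: per-site residual variances are shrunk toward a
prior estimated by moment-matching of log-variances (digamma/trigamma
relations), and the moderated t statistic

    t = (mean_deprived - mean_fed) / (s_tilde * sqrt(1/n1 + 1/n2)),
    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

is referred to a t distribution with d0 + d degrees of freedom. Group-level
comparisons use the Welch two-sample t test (pathway groups) and the
Wilcoxon rank-sum test (kinase-motif groups); multiplicity is controlled by
Benjamini–Hochberg.

Phospho-site fold changes can additionally be adjusted by the matched
protein's fold change estimated from the flow-through fraction, separating
changes in phosphorylation stoichiometry from changes in protein abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import Design, QuantTable, ValidationError


@dataclass(frozen=True)
class EBayesHyper:
    """Prior degrees of freedom and prior variance of the variance model.

    ``d0 = inf`` means all sites share one variance ``s0_sq``; ``d0 = 0``
    means no shrinkage at all.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValidationError(f"prior df must be >= 0, got {self.d0}")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise ValidationError(f"prior variance must be finite positive, got {self.s0_sq}")


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of one two-sample group comparison."""

    label: str
    method: str  # 'welch' or 'wilcoxon'
    n_in: int
    n_out: int
    statistic: float
    p: float
    shift: float  # difference of means (welch) or medians (wilcoxon)
    df: float | None = None  # Satterthwaite df (welch only)
    exact: bool | None = None  # wilcoxon only


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------

def welch_t(x, y, label: str = "") -> GroupTestResult:
    """Welch two-sample t test (unequal variances, unpaired)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_t requires >= 2 values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            # identical constant groups: no evidence of a shift
            return GroupTestResult(label, "welch", len(x), len(y), 0.0, 1.0, 0.0,
                                   df=float(len(x) + len(y) - 2))
        raise ValidationError("welch_t: both groups degenerate with different means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return GroupTestResult(
        label=label,
        method="welch",
        n_in=len(x),
        n_out=len(y),
        statistic=float(res.statistic),
        p=float(res.pvalue),
        shift=float(np.mean(x) - np.mean(y)),
        df=float(res.df),
    )


def wilcoxon_rank_sum(x, y, mode: str = "auto", label: str = "") -> GroupTestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test with midranks for ties.

    ``mode='auto'`` uses exact enumeration when nx + ny <= 12 and there are
    no ties, otherwise the normal approximation with tie and continuity
    corrections. The reported statistic is the rank-sum W of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("wilcoxon_rank_sum requires >= 1 value per group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        use_exact = (len(pooled) <= 12) and not has_ties
    elif mode == "exact":
        if has_ties:
            raise ValidationError("exact rank-sum enumeration is only defined without ties")
        use_exact = True
    elif mode == "approx":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    w = u1 + len(x) * (len(x) + 1) / 2.0
    return GroupTestResult(
        label=label,
        method="wilcoxon",
        n_in=len(x),
        n_out=len(y),
        statistic=w,
        p=float(min(res.pvalue, 1.0)),
        shift=float(np.median(x) - np.median(y)),
        exact=use_exact,
    )


def pathway_group_test(
    fold_changes: pd.Series, membership: set[str], label: str = "pathway"
) -> GroupTestResult:
    """Welch t of member-site fold changes versus non-member sites."""
    fc = fold_changes.dropna()
    members = sorted(membership & set(fc.index))
    others = sorted(set(fc.index) - membership)
    if not members:
        raise ValidationError("pathway group has no tested sites")
    if not others:
        raise ValidationError("pathway complement is empty (membership covers all sites)")
    return welch_t(fc.loc[members].to_numpy(), fc.loc[others].to_numpy(), label=label)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# empirical Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    # starting value from the asymptotic expansion trigamma(x) ~ 1/x + 1/(2x^2)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_ebayes(s2, d) -> EBayesHyper:
    """Estimate (d0, s0^2) by moment-matching of log sample variances.

    The hierarchical model is s^2 | sigma^2 ~ sigma^2 * chi2_d / d with a
    scaled-chi-square variance prior sigma^2 ~ s0^2 * chi2_d0 / d0, so
    z = log(s^2) has
      E[z]   = log s0^2 + g(d) + g(d0),    g(k) = psi(k/2) - log(k/2)
      Var[z] = psi'(d/2) + psi'(d0/2),
    and d0 is identified by inverting the trigamma relation. d may be a
    scalar or per-site array; ``inf`` entries denote exactly observed
    variances (no sampling contribution). If the empirical spread of z does
    not exceed psi'(d/2), d0 is infinite and s0^2 is the geometric-mean-
    based estimate.
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d > 0)
    s2, d = s2[ok], d[ok]
    if s2.size < 20:
        raise ValidationError(f"fit_ebayes needs >= 20 positive finite variances, got {s2.size}")

    finite_d = np.isfinite(d)
    # sampling-moment terms vanish as d -> inf
    bias = np.zeros_like(d)
    tri = np.zeros_like(d)
    half = d[finite_d] / 2.0
    bias[finite_d] = special.digamma(half) - np.log(half)
    tri[finite_d] = special.polygamma(1, half)
    z = np.log(s2)
    e_z = float(np.mean(z))
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(np.mean(tri))
    if excess > 1e-10:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        s0_sq = math.exp(
            e_z - float(np.mean(bias)) - (special.digamma(half_d0) - math.log(half_d0))
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(e_z - float(np.mean(bias)))
    return EBayesHyper(d0=d0, s0_sq=s0_sq)


def posterior_variance(s2, d, hyper: EBayesHyper):
    """Shrunken variance (d0*s0^2 + d*s^2) / (d0 + d), handling d0 in {0, inf}."""
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.isinf(hyper.d0):
        return np.full_like(s2, hyper.s0_sq)
    return (hyper.d0 * hyper.s0_sq + d * s2) / (hyper.d0 + d)


# ---------------------------------------------------------------------------
# moderated site-wise test
# ---------------------------------------------------------------------------

SITE_STAT_COLUMNS = [
    "site_id", "log2fc_raw", "protein_log2fc", "log2fc_adj", "adjusted_flag",
    "n_deprived", "n_fed", "s2", "df_resid", "t_mod", "df_total", "p", "q", "reason",
]


def moderated_test(
    table: QuantTable,
    design: Design,
    hyper: EBayesHyper | None = None,
    *,
    fraction: str = "phospho",
    min_per_condition: int = 2,
) -> pd.DataFrame:
    """Site-wise moderated t test of deprived versus fed on the glog scale.

    Returns one row per site (``SITE_STAT_COLUMNS``). Sites with fewer than
    ``min_per_condition`` finite values in either condition are returned with
    missing statistics and a reason code rather than dropped. If ``hyper``
    is None the shrinkage hyperparameters are fitted from the tested sites'
    residual variances.
    """
    if table.scale_tag != "glog":
        raise ValidationError("moderated_test expects a glog-scale table")
    design.validate(for_stats=True)
    dep = design.channels(fraction, "deprived")
    fed = design.channels(fraction, "fed")
    missing = [c for c in dep + fed if c not in table.values.columns]
    if missing:
        raise ValidationError(f"design channels absent from table: {missing}")

    X = table.values[dep].to_numpy(dtype=float)
    Y = table.values[fed].to_numpy(dtype=float)
    n1 = np.isfinite(X).sum(axis=1)
    n2 = np.isfinite(Y).sum(axis=1)
    testable = (n1 >= min_per_condition) & (n2 >= min_per_condition)

    with np.errstate(invalid="ignore"):
        mx = np.nansum(X, axis=1) / np.maximum(n1, 1)
        my = np.nansum(Y, axis=1) / np.maximum(n2, 1)
        ssx = np.nansum((X - mx[:, None]) ** 2, axis=1)
        ssy = np.nansum((Y - my[:, None]) ** 2, axis=1)
    fc = mx - my
    df_resid = (n1 + n2 - 2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(testable & (df_resid > 0), (ssx + ssy) / df_resid, np.nan)

    if hyper is None:
        hyper = fit_ebayes(s2[testable], df_resid[testable])

    s2_post = posterior_variance(s2, df_resid, hyper)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t_mod = fc / se
    df_total = hyper.d0 + df_resid
    if np.isinf(hyper.d0):
        p = 2.0 * sps.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * sps.t.sf(np.abs(t_mod), df_total)

    out = pd.DataFrame({
        "site_id": table.values.index,
        "log2fc_raw": np.where(testable, fc, np.nan),
        "protein_log2fc": np.nan,
        "log2fc_adj": np.where(testable, fc, np.nan),
        "adjusted_flag": False,
        "n_deprived": n1,
        "n_fed": n2,
        "s2": s2,
        "df_resid": np.where(testable, df_resid, np.nan),
        "t_mod": np.where(testable, t_mod, np.nan),
        "df_total": np.where(testable, df_total, np.nan),
        "p": np.where(testable, p, np.nan),
        "q": np.nan,
        "reason": np.where(testable, "", "insufficient_replication"),
    })
    mask = testable & np.isfinite(out["p"].to_numpy())
    if mask.any():
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out.attrs["ebayes"] = hyper
    return out


def protein_fold_changes(table: QuantTable, design: Design,
                         *, fraction: str = "flowthrough",
                         min_per_condition: int = 2) -> pd.Series:
    """Per-protein deprived−fed mean difference on the glog scale (flow-through)."""
    if table.scale_tag != "glog":
        raise ValidationError("protein_fold_changes expects a glog-scale table")
    dep = design.channels(fraction, "deprived")
    fed = design.channels(fraction, "fed")
    X = table.values[dep].to_numpy(dtype=float)
    Y = table.values[fed].to_numpy(dtype=float)
    n1 = np.isfinite(X).sum(axis=1)
    n2 = np.isfinite(Y).sum(axis=1)
    ok = (n1 >= min_per_condition) & (n2 >= min_per_condition)
    with np.errstate(invalid="ignore"):
        fc = np.nansum(X, axis=1) / np.maximum(n1, 1) - np.nansum(Y, axis=1) / np.maximum(n2, 1)
    return pd.Series(np.where(ok, fc, np.nan), index=table.values.index, name="protein_log2fc")


def adjust_by_protein(
    results: pd.DataFrame,
    site_to_protein: pd.Series | dict,
    protein_fc: pd.Series,
) -> pd.DataFrame:
    """Subtract the matched flow-through protein fold change from each site's.

    Sites whose protein is not quantified in the flow-through keep their raw
    fold change with ``adjusted_flag=False``.
    """
    out = results.copy()
    mapping = pd.Series(site_to_protein)
    proteins = out["site_id"].map(mapping)
    pfc = proteins.map(protein_fc)
    has = pfc.notna() & out["log2fc_raw"].notna()
    out["protein_log2fc"] = pfc.to_numpy()
    out["log2fc_adj"] = np.where(has, out["log2fc_raw"] - pfc, out["log2fc_raw"])
    out["adjusted_flag"] = has.to_numpy()
    return out
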