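"""Per-well statistics: Welch's t with Bonferroni correction and one-way
repeated-measures ANOVA with Greenhouse-Geisser correction.

The statistical unit is always the well or lane (n = number of wells):
pooling all larval measurements within a well first keeps the data points
independent even when wells hold several larvae.  Pairwise epoch contrasts
use a two-tailed unequal-variance (Welch) t-test with a Bonferroni
correction over the declared comparison family; differences are flagged
significant at p < 0.01 (asterisk tier), with a secondary p < 0.05 tier
reported in text form.  Repeated epoch sequences are tested with a one-way
within-subject ANOVA (stimulus as the factor, %up or %CW as the response);
when Mauchly's test rejects sphericity — or always, on request — the
degrees of freedom are scaled by the Greenhouse-Geisser epsilon

    eps = (sum lambda_j)^2 / ((k - 1) * sum lambda_j^2),

with lambda_j the eigenvalues of the double-centered within-subject
covariance matrix, clipped to [1/(k-1), 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

ALPHA_STRICT = 0.01  # asterisk tier
ALPHA_TEXT = 0.05  # text tier


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int = 1
    significant: bool = False  # at the strict tier after adjustment

    def adjusted(self, m: int) -> "TTestResult":
        p_adj = bonferroni([self.p_raw], m)[0]
        return TTestResult(
            t=self.t,
            df=self.df,
            p_raw=self.p_raw,
            p_adjusted=p_adj,
            m_comparisons=m,
            significant=p_adj < ALPHA_STRICT,
        )


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df1: float
    df2: float
    epsilon_gg: float
    df1_gg: float
    df2_gg: float
    p_uncorrected: float
    p_gg: float
    sphericity_W: float
    sphericity_p: float
    correction_applied: bool

    @property
    def p(self) -> float:
        return self.p_gg if self.correction_applied else self.p_uncorrected


def welch_t(sample_a, sample_b) -> TTestResult:
    """Two-tailed Welch (unequal variance) t-test on per-well values.

    Degrees of freedom follow Welch-Satterthwaite.  With zero variance in
    both samples the limiting form applies: equal means give t = 0, p = 1;
    unequal means give |t| = inf, p = 0.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("insufficient n: each sample needs >= 2 wells")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p_raw=1.0, p_adjusted=1.0)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t=t, df=df, p_raw=0.0, p_adjusted=0.0, significant=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
    )


def bonferroni(p_values, m: int) -> list[float]:
    """Multiply each p by the family size m, capped at 1."""
    p_values = list(p_values)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than {len(p_values)} p-values")
    return [min(1.0, float(p) * m) for p in p_values]


def _double_centered_cov(data: np.ndarray) -> np.ndarray:
    s = np.cov(data, rowvar=False, ddof=1)
    row = s.mean(axis=1, keepdims=True)
    col = s.mean(axis=0, keepdims=True)
    return s - row - col + s.mean()


def gg_epsilon(data_matrix) -> float:
    """Greenhouse-Geisser epsilon of an n_subjects x k_levels matrix.

    Equals 1 under exact sphericity (e.g. compound symmetry, or k = 2)
    and reaches its floor 1/(k-1) under maximal violation.
    """
    x = _as_complete_matrix(data_matrix)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    c = _double_centered_cov(x)
    lam = np.linalg.eigvalsh(c)
    lam = np.clip(lam, 0.0, None)  # numerical negatives
    denom = (k - 1) * float(np.sum(lam**2))
    if denom <= 1e-300:
        return 1.0  # degenerate (no within-subject variance): sphericity holds trivially
    eps = float(np.sum(lam)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly(data_matrix) -> tuple[float, float]:
    """Mauchly's sphericity test: (W, p) via the chi-square approximation.

    For k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    x = _as_complete_matrix(data_matrix)
    n, k = x.shape
    if k < 3:
        return 1.0, 1.0
    m = helmert(k, full=False)  # orthonormal contrasts, (k-1) x k
    sc = m @ np.cov(x, rowvar=False, ddof=1) @ m.T
    d = k - 1
    tr = float(np.trace(sc))
    det = float(np.linalg.det(sc))
    if tr <= 0 or det <= 0 or n - 1 < d:
        return 0.0, 0.0  # singular contrast covariance: sphericity untestable/violated
    w = det / (tr / d) ** d
    # two-term Box approximation of the null distribution (as in SPSS/ezANOVA)
    f_corr = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * math.log(w)
    df = d * (d + 1) // 2 - 1
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f_corr) ** 2)
    )
    p1 = float(sps.chi2.sf(chi2, df))
    p2 = float(sps.chi2.sf(chi2, df + 4))
    p = p1 + w2 * (p2 - p1)
    return float(w), float(min(max(p, 0.0), 1.0))


def rm_anova(
    data_matrix,
    always_gg: bool = False,
    sphericity_alpha: float = 0.05,
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a complete n_subjects x k matrix.

    Standard within-subject decomposition: SS_error = SS_total -
    SS_subjects - SS_condition, F = MS_condition / MS_error with
    df = (k-1, (k-1)(n-1)).  The Greenhouse-Geisser corrected p is used
    when Mauchly's test rejects sphericity at ``sphericity_alpha`` or when
    ``always_gg`` is set.
    """
    x = _as_complete_matrix(data_matrix)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    grand = x.mean()
    ss_cond = n * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_error = max(ss_total - ss_cond - ss_subj, 0.0)
    df1 = float(k - 1)
    df2 = float((k - 1) * (n - 1))
    if ss_error <= 1e-300:
        f_stat = 0.0 if ss_cond <= 1e-300 else math.inf
    else:
        f_stat = (ss_cond / df1) / (ss_error / df2)
    eps = gg_epsilon(x)
    w, sph_p = mauchly(x)
    if math.isinf(f_stat):
        p_unc = p_gg = 0.0
    elif f_stat == 0.0:
        p_unc = p_gg = 1.0
    else:
        p_unc = float(sps.f.sf(f_stat, df1, df2))
        p_gg = float(sps.f.sf(f_stat, eps * df1, eps * df2))
    applied = bool(always_gg or (k > 2 and sph_p < sphericity_alpha))
    return RMAnovaResult(
        F=f_stat,
        df1=df1,
        df2=df2,
        epsilon_gg=eps,
        df1_gg=eps * df1,
        df2_gg=eps * df2,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        sphericity_W=w,
        sphericity_p=sph_p,
        correction_applied=applied,
    )


def _as_complete_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an n_subjects x k_levels matrix")
    if np.isnan(x).any():
        raise ValueError("incomplete matrix: every well must be measured at every level")
    return x


@dataclass(frozen=True)
class ComparisonDesign:
    """Declares the planned analysis of a set of per-well epoch summaries.

    ``pairs`` are pairwise epoch contrasts tested with Welch's t and
    Bonferroni-adjusted with family size ``m`` (defaults to the number of
    pairs, matching the published per-experiment families).  ``rm_epochs``
    optionally names a repeated epoch sequence analyzed with the
    within-subject ANOVA.
    """

    metric: str = "pct_cw"  # column of the summary table
    pairs: tuple[tuple[str, str], ...] = ()
    m: int | None = None
    rm_epochs: tuple[str, ...] = ()
    alpha: float = ALPHA_STRICT
    always_gg: bool = False

    @property
    def family_size(self) -> int:
        return self.m if self.m is not None else max(len(self.pairs), 1)


@dataclass
class ComparisonReport:
    pairwise: pd.DataFrame
    anova: RMAnovaResult | None = None
    metric: str = "pct_cw"

    def to_text(self) -> str:
        lines = [f"Pairwise Welch t-tests on {self.metric} (Bonferroni-adjusted):"]
        for _, r in self.pairwise.iterrows():
            star = " *" if r["significant"] else ""
            lines.append(
                f"  {r['epoch_a']} vs {r['epoch_b']}: t({r['df']:.2f}) = {r['t']:.3f}, "
                f"p_raw = {r['p_raw']:.3g}, p_adj = {r['p_adj']:.3g} (m = {r['m']}){star}"
            )
        if self.anova is not None:
            a = self.anova
            lines.append(
                f"RM-ANOVA: F({a.df1_gg:.3f}, {a.df2_gg:.3f}) = {a.F:.3f}, "
                f"eps_GG = {a.epsilon_gg:.3f}, p = {a.p:.3g}"
                + (" [GG-corrected]" if a.correction_applied else "")
            )
        return "\n".join(lines)


def compare_epochs(summaries: pd.DataFrame, design: ComparisonDesign) -> ComparisonReport:
    """Run the declared pairwise and repeated-measures tests on a summary table.

    ``summaries`` needs columns roi, epoch and the design's metric; epochs
    compared pairwise must cover the same set of wells (no imputation).
    """
    needed = {"roi", "epoch", design.metric}
    if not needed.issubset(summaries.columns):
        raise ValueError(f"summary table must have columns {sorted(needed)}")
    known = set(summaries["epoch"].unique())
    for label in [e for pair in design.pairs for e in pair] + list(design.rm_epochs):
        if label not in known:
            raise ValueError(f"unknown epoch label {label!r}; have {sorted(known)}")
    m = design.family_size
    rows = []
    for ea, eb in design.pairs:
        va = _epoch_values(summaries, ea, design.metric)
        vb = _epoch_values(summaries, eb, design.metric)
        if set(va.index) != set(vb.index):
            raise ValueError(f"well sets differ between epochs {ea!r} and {eb!r}")
        res = welch_t(va.to_numpy(), vb.to_numpy()).adjusted(m)
        rows.append(
            {
                "epoch_a": ea,
                "epoch_b": eb,
                "n_a": len(va),
                "n_b": len(vb),
                "t": res.t,
                "df": res.df,
                "p_raw": res.p_raw,
                "p_adj": res.p_adjusted,
                "m": m,
                "significant": res.p_adjusted < design.alpha,
                "significant_text_tier": res.p_adjusted < ALPHA_TEXT,
            }
        )
    pairwise = pd.DataFrame(
        rows,
        columns=[
            "epoch_a", "epoch_b", "n_a", "n_b", "t", "df",
            "p_raw", "p_adj", "m", "significant", "significant_text_tier",
        ],
    )
    anova = None
    if design.rm_epochs:
        mats = []
        wells = None
        for label in design.rm_epochs:
            v = _epoch_values(summaries, label, design.metric)
            if wells is None:
                wells = list(v.index)
            elif set(v.index) != set(wells):
                raise ValueError(f"well sets differ across repeated epochs at {label!r}")
            mats.append(v.loc[wells].to_numpy())
        anova = rm_anova(np.column_stack(mats), always_gg=design.always_gg)
    return ComparisonReport(pairwise=pairwise, anova=anova, metric=design.metric)


def _epoch_values(summaries: pd.DataFrame, epoch: str, metric: str) -> pd.Series:
    sub = summaries[summaries["epoch"] == epoch]
    v = sub.set_index("roi")[metric].astype(float)
    if v.isna().any():
        raise ValueError(f"epoch {epoch!r}: undefined {metric} for wells {list(v[v.isna()].index)}")
    return v
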