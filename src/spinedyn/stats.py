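"""Statistical procedures for group comparison, implemented from first principles.

Every test used by the analysis is implemented here directly from its
defining computation rather than delegated to a statistics package:

* :func:`mann_whitney_u` — rank-sum test with midrank ties; exact two-sided
  p by full enumeration of label assignments for small samples, tie-corrected
  normal approximation otherwise.
* :func:`t_test_unpaired` — pooled-variance two-sided t test.
* :func:`two_way_anova` — two-factor ANOVA with type-II sums of squares
  (robust to unbalanced designs) and optional Tukey HSD pairwise comparisons
  of cell means.
* :func:`rm_mixed_anova` — univariate split-plot repeated-measures ANOVA:
  between-subject factors (plus an additive blocking term such as litter)
  tested against subjects-within-groups error, the within-subject factor
  against the subject × trial residual.  Greenhouse–Geisser correction is
  available as an option.
* :func:`cohens_d`, :func:`pearson_r` — standard effect size and
  product-moment correlation with its t-based p-value.

scipy is used only for reference distribution functions (normal, t, F,
studentized range); all statistics, sums of squares and enumeration are
computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as _dist

from .errors import ValidationError


@dataclass(frozen=True)
class TestResult:
    """Uniform container for a scalar test: statistic, dfs, p, effect size."""

    name: str
    statistic: float
    p_value: float
    df: tuple[float, ...] = ()
    effect_size: float | None = None
    method: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(
                f"p_value out of [0, 1]: {self.p_value}")

    def as_dict(self) -> dict:
        d = {"name": self.name, "statistic": self.statistic,
             "p_value": self.p_value, "method": self.method}
        if self.df:
            d["df"] = list(self.df)
        if self.effect_size is not None:
            d["effect_size"] = self.effect_size
        return d


# ---------------------------------------------------------------------------
# Ranks and Mann-Whitney U
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1.0
        i = j + 1
    return ranks


@lru_cache(maxsize=64)
def _index_combinations(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def mann_whitney_u(x, y, mode: str = "auto",
                   exact_limit: int = 12) -> TestResult:
    """Two-sided Mann–Whitney U test with midrank tie handling.

    ``mode`` is ``"exact"`` (full enumeration of all C(n, n_x) assignments of
    the pooled midranks — a permutation test, valid with ties),
    ``"normal_approx"`` (tie-corrected normal approximation with continuity
    correction), or ``"auto"`` (exact when ``n_x + n_y <= exact_limit``).

    The reported statistic is U of the first sample; the exact two-sided p
    is twice the smaller tail probability, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("mann_whitney_u requires non-empty samples")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)

    if mode == "auto":
        mode = "exact" if n <= exact_limit else "normal_approx"

    if mode == "exact":
        combos = _index_combinations(n, nx)
        u_all = ranks[combos].sum(axis=1) - nx * (nx + 1) / 2
        # Guard float fuzz from midranks before tail comparisons.
        u_all = np.round(u_all * 2) / 2
        u_ref = round(u_obs * 2) / 2
        m = len(u_all)
        p_low = float((u_all <= u_ref).sum()) / m
        p_high = float((u_all >= u_ref).sum()) / m
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(name="Mann-Whitney U", statistic=u_obs, p_value=p,
                          method="exact enumeration")

    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(name="Mann-Whitney U", statistic=u_obs, p_value=1.0,
                          method="normal approximation (degenerate)")
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / math.sqrt(sigma2)
    p = float(min(1.0, 2.0 * _dist.norm.sf(abs(z))))
    return TestResult(name="Mann-Whitney U", statistic=u_obs, p_value=p,
                      method="tie-corrected normal approximation")


# ---------------------------------------------------------------------------
# t test and effect sizes
# ---------------------------------------------------------------------------

def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    ss = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
    return math.sqrt(ss / (nx + ny - 2))


def t_test_unpaired(x, y) -> TestResult:
    """Pooled-variance two-sided t test with df = n_x + n_y − 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("t_test_unpaired requires n >= 2 per sample")
    df = len(x) + len(y) - 2
    sp = _pooled_sd(x, y)
    diff = x.mean() - y.mean()
    if sp == 0:
        if diff == 0:
            return TestResult(name="unpaired t", statistic=0.0, p_value=1.0,
                              df=(float(df),), method="pooled variance")
        raise ValidationError("degenerate variance: zero pooled variance "
                              "with unequal means")
    t = diff / (sp * math.sqrt(1.0 / len(x) + 1.0 / len(y)))
    p = float(min(1.0, 2.0 * _dist.t.sf(abs(t), df)))
    return TestResult(name="unpaired t", statistic=float(t), p_value=p,
                      df=(float(df),), method="pooled variance")


def cohens_d(x, y) -> float:
    """Cohen's d: (mean_x − mean_y) / pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("cohens_d requires n >= 2 per sample")
    sp = _pooled_sd(x, y)
    if sp == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValidationError("cohens_d undefined: zero pooled SD with "
                              "unequal means")
    return float((x.mean() - y.mean()) / sp)


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("pearson_r requires equal-length samples")
    n = len(x)
    if n < 3:
        raise ValidationError("pearson_r requires n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float((xc ** 2).sum() * (yc ** 2).sum()))
    if denom == 0:
        raise ValidationError("pearson_r undefined for constant input")
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(min(1.0, 2.0 * _dist.t.sf(abs(t), n - 2)))
    return TestResult(name="Pearson r", statistic=r, p_value=p,
                      df=(float(n - 2),), effect_size=r,
                      method="t transform")


# ---------------------------------------------------------------------------
# Two-way ANOVA (type II) + Tukey HSD
# ---------------------------------------------------------------------------

def _dummies(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    levels = sorted(pd.unique(labels))
    return np.column_stack([(labels == lv).astype(float)
                            for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))


def _interaction(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    cols = [da[:, i] * db[:, j]
            for i in range(da.shape[1]) for j in range(db.shape[1])]
    return np.column_stack(cols) if cols else np.empty((len(da), 0))


def _rss(y: np.ndarray, *blocks: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit with intercept."""
    X = np.column_stack([np.ones(len(y))] + [b for b in blocks if b.size])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _f_p(ss_effect: float, df_effect: float, ss_error: float,
         df_error: float) -> tuple[float, float]:
    """F statistic and p with guards for degenerate (zero-error) designs."""
    # Tiny negative or positive fuzz from lstsq differences is clipped.
    ss_effect = max(0.0, ss_effect)
    if df_effect <= 0 or df_error <= 0:
        return math.nan, math.nan
    ms_e = ss_error / df_error
    ms_f = ss_effect / df_effect
    if ms_e <= 1e-12 * max(1.0, ms_f):
        if ms_f <= 1e-12:
            return 0.0, 1.0
        return math.inf, 0.0
    f = ms_f / ms_e
    if f < 1e-12:
        f = 0.0
    return f, float(_dist.f.sf(f, df_effect, df_error))


@dataclass(frozen=True)
class TwoWayAnovaResult:
    """Type-II two-way ANOVA table plus optional Tukey HSD comparisons."""

    table: pd.DataFrame
    tukey: pd.DataFrame | None = None


def two_way_anova(values, factor_a, factor_b, tukey: bool = False,
                  names: tuple[str, str] = ("A", "B")) -> TwoWayAnovaResult:
    """Two-factor ANOVA with type-II sums of squares.

    Type-II SS test each main effect adjusted for the other main effect
    (ignoring the interaction) and the interaction adjusted for both mains,
    which is well defined for unbalanced designs.  Requires at least two
    levels per factor and at least one observation per cell.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(y) == len(fa) == len(fb)):
        raise ValidationError("values and factors must have equal length")
    levels_a, levels_b = sorted(pd.unique(fa)), sorted(pd.unique(fb))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValidationError("each factor needs >= 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((fa == la) & (fb == lb)):
                raise ValidationError(f"empty cell: ({la!r}, {lb!r})")

    da, db = _dummies(fa), _dummies(fb)
    dab = _interaction(da, db)
    rss_full, rank_full = _rss(y, da, db, dab)
    rss_ab, _ = _rss(y, da, db)
    rss_a, _ = _rss(y, da)
    rss_b, _ = _rss(y, db)

    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    df_err = len(y) - rank_full

    ss_a = rss_b - rss_ab          # SS(A | B)
    ss_b = rss_a - rss_ab          # SS(B | A)
    ss_ab = rss_ab - rss_full      # SS(AB | A, B)

    rows = []
    for name, ss, df in ((names[0], ss_a, df_a), (names[1], ss_b, df_b),
                         (f"{names[0]}:{names[1]}", ss_ab, df_ab)):
        f, p = _f_p(ss, df, rss_full, df_err)
        rows.append({"effect": name, "ss": max(0.0, ss), "df1": df,
                     "df2": df_err, "F": f, "p_value": p})
    rows.append({"effect": "residual", "ss": rss_full, "df1": df_err,
                 "df2": math.nan, "F": math.nan, "p_value": math.nan})
    table = pd.DataFrame(rows)

    tukey_table = _tukey_hsd(y, fa, fb, rss_full, df_err) if tukey else None
    return TwoWayAnovaResult(table=table, tukey=tukey_table)


def _tukey_hsd(y, fa, fb, ss_err, df_err) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons of the a × b cell means."""
    cells = sorted({(a, b) for a, b in zip(fa, fb)})
    means = {}
    ns = {}
    for c in cells:
        mask = (fa == c[0]) & (fb == c[1])
        means[c] = float(y[mask].mean())
        ns[c] = int(mask.sum())
    mse = ss_err / df_err if df_err > 0 else math.nan
    k = len(cells)
    rows = []
    for c1, c2 in itertools.combinations(cells, 2):
        diff = means[c1] - means[c2]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[c1] + 1.0 / ns[c2])) \
            if mse > 0 else 0.0
        if se == 0:
            q = 0.0 if diff == 0 else math.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(_dist.studentized_range.sf(q, k, df_err))
        rows.append({"cell_1": f"{c1[0]}/{c1[1]}", "cell_2": f"{c2[0]}/{c2[1]}",
                     "mean_diff": diff, "q": q, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Split-plot (mixed) repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_mixed_anova(data: pd.DataFrame, dv: str, subject: str, within: str,
                   between: tuple[str, str] = ("genotype", "treatment"),
                   litter: str | None = "litter",
                   gg_correction: bool = False) -> pd.DataFrame:
    """Univariate split-plot repeated-measures ANOVA.

    Between-subject factors (``between``, e.g. genotype and treatment, plus
    an optional additive blocking term ``litter``) are tested against the
    subjects-within-groups mean square, computed from subject means with
    type-II sums of squares.  The within-subject factor (``within``, e.g.
    trial) is tested against the subject × trial residual.  Every subject
    must be observed at every within level.

    With ``gg_correction`` the within-factor test's degrees of freedom are
    multiplied by the Greenhouse–Geisser epsilon estimated from the
    subject × trial response matrix.
    """
    fa_name, fb_name = between
    needed = [dv, subject, within, fa_name, fb_name] + \
        ([litter] if litter else [])
    for col in needed:
        if col not in data.columns:
            raise ValidationError(f"column {col!r} missing from data")

    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean", dropna=False)
    if wide.isna().any().any():
        missing = [(s, t) for s in wide.index for t in wide.columns
                   if pd.isna(wide.loc[s, t])]
        raise ValidationError(
            f"subjects missing within-levels (subject, {within}): {missing}")
    counts = data.groupby([subject, within]).size()
    if (counts != 1).any():
        dup = counts[counts != 1].index.tolist()
        raise ValidationError(
            f"expected exactly one observation per (subject, {within}); "
            f"offending: {dup}")

    subj_meta = (data[[subject, fa_name, fb_name] +
                      ([litter] if litter else [])]
                 .drop_duplicates(subject).set_index(subject))
    if subj_meta[[fa_name, fb_name]].groupby(level=0).size().max() > 1:
        raise ValidationError("a subject maps to more than one group")
    subj_meta = subj_meta.loc[wide.index]
    cell_sizes = subj_meta.groupby([fa_name, fb_name]).size()
    if (cell_sizes < 2).any():
        raise ValidationError(
            f"need >= 2 subjects per between cell; sizes: {dict(cell_sizes)}")

    Y = wide.to_numpy(dtype=float)          # subjects x trials
    n_subj, T = Y.shape
    subj_means = Y.mean(axis=1)
    grand = Y.mean()

    fa = subj_meta[fa_name].to_numpy()
    fb = subj_meta[fb_name].to_numpy()
    da, db = _dummies(fa), _dummies(fb)
    dab = _interaction(da, db)
    dl = _dummies(subj_meta[litter].to_numpy()) if litter else \
        np.empty((n_subj, 0))

    # Between stratum: OLS on subject means, scaled by T observations each.
    rss_full, rank_full = _rss(subj_means, dl, da, db, dab)
    ss_err_b = T * rss_full
    df_err_b = n_subj - rank_full
    terms = {}
    rss_no_a, _ = _rss(subj_means, dl, db)
    rss_no_b, _ = _rss(subj_means, dl, da)
    rss_mains, _ = _rss(subj_means, dl, da, db)
    terms[fa_name] = (T * (rss_no_a - rss_mains), da.shape[1])
    terms[fb_name] = (T * (rss_no_b - rss_mains), db.shape[1])
    terms[f"{fa_name}:{fb_name}"] = (T * (rss_mains - rss_full), dab.shape[1])
    if litter and dl.shape[1]:
        rss_no_l, _ = _rss(subj_means, da, db, dab)
        terms[litter] = (T * (rss_no_l - rss_full), dl.shape[1])

    rows = []
    for name, (ss, df) in terms.items():
        if df == 0:  # factor with a single level contributes nothing
            continue
        f, p = _f_p(ss, df, ss_err_b, df_err_b)
        rows.append({"effect": name, "ss": max(0.0, ss), "df1": df,
                     "df2": df_err_b, "F": f, "p_value": p,
                     "error_stratum": "between"})
    rows.append({"effect": "subjects(residual)", "ss": ss_err_b,
                 "df1": df_err_b, "df2": math.nan, "F": math.nan,
                 "p_value": math.nan, "error_stratum": "between"})

    # Within stratum.
    trial_means = Y.mean(axis=0)
    ss_trial = n_subj * float(((trial_means - grand) ** 2).sum())
    ss_within_total = float(((Y - subj_means[:, None]) ** 2).sum())
    ss_err_w = ss_within_total - ss_trial
    df_trial = T - 1
    df_err_w = (n_subj - 1) * (T - 1)
    eps = 1.0
    if gg_correction:
        eps = _greenhouse_geisser_epsilon(Y)
    f, p = _f_p(ss_trial, df_trial, ss_err_w, df_err_w)
    if gg_correction and math.isfinite(f) and f > 0:
        p = float(_dist.f.sf(f, df_trial * eps, df_err_w * eps))
    rows.append({"effect": within, "ss": ss_trial, "df1": df_trial * eps,
                 "df2": df_err_w * eps, "F": f, "p_value": p,
                 "error_stratum": "within"})
    rows.append({"effect": f"{subject}:{within}(residual)", "ss": ss_err_w,
                 "df1": df_err_w, "df2": math.nan, "F": math.nan,
                 "p_value": math.nan, "error_stratum": "within"})
    return pd.DataFrame(rows)


def _greenhouse_geisser_epsilon(Y: np.ndarray) -> float:
    """Greenhouse–Geisser sphericity epsilon from the trial covariance."""
    T = Y.shape[1]
    S = np.cov(Y, rowvar=False)
    C = np.eye(T) - np.ones((T, T)) / T
    Sc = C @ S @ C
    num = np.trace(Sc) ** 2
    den = (T - 1) * np.trace(Sc @ Sc)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (T - 1), num / den)))
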