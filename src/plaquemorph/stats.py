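"""Plaque-based and subject-based statistical analysis.

Two regression families probe geometric consistency across plaques of
different sizes: ordinary least-squares lines and allometric power
functions y = a*x^b fitted by least squares in the original scale (log-log
OLS provides the starting point only), so both R-squared values are
comparable. Similarity of 3D shapes forces area ~ volume^(2/3) and
length ~ volume^(1/3), making fitted exponents a direct probe of shape
consistency.

Rank statistics follow the conventions of the clinical analysis they
reproduce: tie-corrected Spearman correlation with "significant"
(rho > 0.5, p < 0.05) and "strong" (rho > 0.8, p < 0.05) labels,
normality-gated descriptives (Shapiro-Wilk for n <= 50, else
Kolmogorov-Smirnov), t versus Mann-Whitney two-group tests, classic Levene
(centre = mean), and the Scheirer-Ray-Hare two-way rank test. No
multiple-testing correction is applied; the report records the number of
tests performed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

__all__ = [
    "FitResult",
    "CorrelationResult",
    "SubjectSummary",
    "GroupTestResult",
    "SRHResult",
    "fit_linear",
    "fit_power",
    "spearman",
    "describe",
    "compare_groups",
    "levene",
    "scheirer_ray_hare",
    "subject_summary",
    "consistency_report",
]

GEOMETRIC_PAIR_COLUMNS = [
    "volume_mm3",
    "surface_area_mm2",
    "length_mm",
    "surface_distance_mm",
    "max_cross_area_mm2",
    "max_cross_diameter_mm",
]

SUMMARY_FIELDS = [
    "TPV", "MPV", "TPSA", "MPSA", "TCV", "TCSA",
    "RTVCP", "RTSACP", "PVSARmax", "PVSARmean", "PVSARmin", "PVSARm",
]


@dataclass
class FitResult:
    """Outcome of a linear or power-function regression."""

    model: str  # "linear" | "power"
    a: float  # intercept (linear) or multiplier (power)
    b: float  # slope or exponent
    r_squared: float
    p_value: float  # of the slope/exponent, two-sided
    n: int

    @property
    def significant(self) -> bool:
        """R-squared > 0.25 and p < 0.05 (strict inequalities)."""
        return self.r_squared > 0.25 and self.p_value < 0.05

    @property
    def strong(self) -> bool:
        """R-squared > 0.64 and p < 0.05."""
        return self.r_squared > 0.64 and self.p_value < 0.05


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    @property
    def label(self) -> str:
        if self.rho > 0.8 and self.p_value < 0.05:
            return "strong"
        if self.rho > 0.5 and self.p_value < 0.05:
            return "significant"
        return "none"


@dataclass
class GroupTestResult:
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p_value: float
    gate_p_values: tuple[float, float]


@dataclass
class SRHResult:
    """Scheirer-Ray-Hare two-way rank test decomposition."""

    H_A: float
    H_B: float
    H_interaction: float
    df_A: int
    df_B: int
    df_interaction: int
    p_A: float
    p_B: float
    p_interaction: float
    ss: dict = field(default_factory=dict)  # SS on ranks per term


@dataclass
class SubjectSummary:
    """Subject-level aggregates of plaque and calcification geometry.

    TPV/TPSA: total plaque volume mm^3 / surface area mm^2; MPV/MPSA:
    their per-plaque maxima; TCV/TCSA: calcification totals; RTVCP/RTSACP:
    calcification-to-plaque ratios; PVSAR*: max/mean/min of the per-plaque
    volume/surface-area ratio and its value in the largest plaque (mm).
    """

    TPV: float
    MPV: float
    TPSA: float
    MPSA: float
    TCV: float
    TCSA: float
    RTVCP: float
    RTSACP: float
    PVSARmax: float
    PVSARmean: float
    PVSARmin: float
    PVSARm: float

    def as_row(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in SUMMARY_FIELDS}


def _check_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x, y


def fit_linear(x, y) -> FitResult:
    """Ordinary least-squares line y = a + b*x with two-sided slope p."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0:
        raise ValueError("x is constant; linear fit undefined")
    res = sps.linregress(x, y)
    return FitResult(
        model="linear",
        a=float(res.intercept),
        b=float(res.slope),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def fit_power(x, y) -> FitResult:
    """Least-squares power fit y = a*x^b in the original scale.

    The exponent is initialized from log-log OLS and refined by nonlinear
    least squares on the untransformed data; R-squared is computed on the
    original scale so it is directly comparable with :func:`fit_linear`.
    The exponent p-value comes from the asymptotic covariance (t with
    n - 2 df, two-sided).
    """
    x, y = _check_xy(x, y)
    bad = np.flatnonzero((x <= 0) | (y <= 0))
    if bad.size:
        raise ValueError(
            f"power fit requires positive data; offending indices {bad.tolist()}"
        )
    lx, ly = np.log(x), np.log(y)
    init = sps.linregress(lx, ly)
    p0 = (float(np.exp(init.intercept)), float(init.slope))

    def model(x_, a_, b_):
        return a_ * np.power(x_, b_)

    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((2, 2), np.nan)
    a_hat, b_hat = float(popt[0]), float(popt[1])
    resid = y - model(x, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    se_b = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    if se_b and np.isfinite(se_b) and se_b > 0:
        t = b_hat / se_b
        p = float(2 * sps.t.sf(abs(t), df=x.size - 2))
    else:
        p = 0.0 if ss_res < 1e-20 * max(ss_tot, 1.0) else np.nan
    return FitResult("power", a_hat, b_hat, r2, p, int(x.size))


def spearman(x, y) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation with the study's labels."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(x.size))


def _normality_p(x: np.ndarray) -> float:
    """Shapiro-Wilk for n <= 50, Kolmogorov-Smirnov (fitted normal) above."""
    x = np.asarray(x, dtype=np.float64)
    if x.size <= 50:
        return float(sps.shapiro(x).pvalue)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def describe(x) -> dict:
    """Normality-gated descriptive summary.

    Normal samples (gate p > 0.05) are expressed as ``mean ± SD``; others
    as ``median (P25, P75)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    p = _normality_p(x)
    gate = "shapiro_wilk" if x.size <= 50 else "kolmogorov_smirnov"
    if p > 0.05:
        text = f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
        fmt = "mean_sd"
    else:
        q25, med, q75 = np.percentile(x, [25, 50, 75])
        text = f"{med:.2f} ({q25:.2f}, {q75:.2f})"
        fmt = "median_iqr"
    return {
        "n": int(x.size),
        "normality_test": gate,
        "normality_p": p,
        "format": fmt,
        "text": text,
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "median": float(np.median(x)),
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
    }


def compare_groups(x, group) -> GroupTestResult:
    """Two-group comparison, t-test iff both groups pass normality.

    Either group failing its normality gate (p <= 0.05) forces the
    two-sided tie-corrected Mann-Whitney U test.
    """
    x = np.asarray(x, dtype=np.float64)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(levels)}")
    g1 = x[group == levels[0]]
    g2 = x[group == levels[1]]
    if g1.size < 3 or g2.size < 3:
        raise ValueError("each group needs at least 3 observations")
    p1, p2 = _normality_p(g1), _normality_p(g2)
    if p1 > 0.05 and p2 > 0.05:
        res = sps.ttest_ind(g1, g2)
        return GroupTestResult("t", float(res.statistic), float(res.pvalue), (p1, p2))
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided")
    return GroupTestResult(
        "mann_whitney", float(res.statistic), float(res.pvalue), (p1, p2)
    )


def levene(x, group) -> float:
    """Classic Levene homogeneity-of-variance p-value (centre = mean)."""
    x = np.asarray(x, dtype=np.float64)
    group = np.asarray(group)
    samples = [x[group == g] for g in pd.unique(group)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for s in samples:
        if s.size < 2:
            raise ValueError("every group needs at least 2 observations")
    return float(sps.levene(*samples, center="mean").pvalue)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def scheirer_ray_hare(value, factor_a, factor_b) -> SRHResult:
    """Scheirer-Ray-Hare nonparametric two-way test on midranks.

    All values are replaced by midranks over the whole sample; sequential
    two-way ANOVA sums of squares (A, then B, then interaction) are
    computed on the ranks, and each term's H = SS / MS_total with
    MS_total = SS_total/(N-1) is referred to chi-square with the term's
    degrees of freedom. The midranks already absorb ties, so no extra tie
    correction is applied to MS_total.
    """
    y = np.asarray(value, dtype=np.float64)
    fa = pd.Categorical(np.asarray(factor_a))
    fb = pd.Categorical(np.asarray(factor_b))
    a, b = len(fa.categories), len(fb.categories)
    if a < 2 or b < 2:
        raise ValueError("both factors need at least 2 levels")
    n = y.size
    if n < a * b + 2:
        raise ValueError("too few observations for the factorial layout")
    r = sps.rankdata(y)
    A = pd.get_dummies(fa, drop_first=True).to_numpy(dtype=float)
    B = pd.get_dummies(fb, drop_first=True).to_numpy(dtype=float)
    AB = np.einsum("ni,nj->nij", A, B).reshape(n, -1)
    one = np.ones((n, 1))
    rss0 = _rss(one, r)  # = SS_total
    rss_a = _rss(np.hstack([one, A]), r)
    rss_ab = _rss(np.hstack([one, A, B]), r)
    rss_full = _rss(np.hstack([one, A, B, AB]), r)
    ss_total = rss0
    ss_a = rss0 - rss_a
    ss_b = rss_a - rss_ab
    ss_int = rss_ab - rss_full
    ms_total = ss_total / (n - 1)
    df_a, df_b, df_int = a - 1, b - 1, (a - 1) * (b - 1)
    if ms_total <= 1e-12 * n * n:  # all values tied: degenerate ranks
        H = (0.0, 0.0, 0.0)
        p = (1.0, 1.0, 1.0)
    else:
        H = (ss_a / ms_total, ss_b / ms_total, ss_int / ms_total)
        p = tuple(float(sps.chi2.sf(h, d)) for h, d in zip(H, (df_a, df_b, df_int)))
    return SRHResult(
        H_A=float(max(H[0], 0.0)),
        H_B=float(max(H[1], 0.0)),
        H_interaction=float(max(H[2], 0.0)),
        df_A=df_a,
        df_B=df_b,
        df_interaction=df_int,
        p_A=p[0],
        p_B=p[1],
        p_interaction=p[2],
        ss={
            "A": ss_a,
            "B": ss_b,
            "interaction": ss_int,
            "within": rss_full,
            "total": ss_total,
        },
    )


def subject_summary(plaques: pd.DataFrame, calcifications: pd.DataFrame | None = None) -> SubjectSummary:
    """Aggregate one subject's plaque/calcification rows.

    *plaques* needs ``volume_mm3`` and ``surface_area_mm2`` columns;
    *calcifications* likewise (may be None or empty: calcification totals
    and ratios are then 0).
    """
    if plaques is None or len(plaques) == 0:
        raise ValueError("subject has no plaques")
    v = plaques["volume_mm3"].to_numpy(dtype=float)
    sa = plaques["surface_area_mm2"].to_numpy(dtype=float)
    vsar = v / sa
    i_max = int(np.argmax(v))
    if calcifications is None or len(calcifications) == 0:
        tcv = tcsa = 0.0
    else:
        tcv = float(calcifications["volume_mm3"].sum())
        tcsa = float(calcifications["surface_area_mm2"].sum())
    tpv = float(v.sum())
    tpsa = float(sa.sum())
    return SubjectSummary(
        TPV=tpv,
        MPV=float(v.max()),
        TPSA=tpsa,
        MPSA=float(sa.max()),
        TCV=tcv,
        TCSA=tcsa,
        RTVCP=tcv / tpv,
        RTSACP=tcsa / tpsa,
        PVSARmax=float(vsar.max()),
        PVSARmean=float(vsar.mean()),
        PVSARmin=float(vsar.min()),
        PVSARm=float(vsar[i_max]),
    )


def _fit_entry(x_name, y_name, x, y) -> dict:
    lin = fit_linear(x, y)
    pw = fit_power(x, y)
    return {
        "x": x_name,
        "y": y_name,
        "linear": lin,
        "power": pw,
        "significant": lin.significant,
        "strong": lin.strong,
    }


def consistency_report(
    plaque_table: pd.DataFrame,
    subject_table: pd.DataFrame,
    covariate_table: pd.DataFrame | None = None,
) -> dict:
    """Full plaque-based and subject-based consistency analysis.

    Produces: (i) linear + power fits over all 15 pairs of the six plaque
    geometric parameters; (ii) plaque-vs-calcification volume/area fits on
    all plaques and on calcified-only plaques; (iii) the VSAR versus total
    calcification volume regression; (iv) the subject-level Spearman matrix
    of covariates against the 12 summary parameters; (v) two-group tests
    for binary covariates; (vi) the Levene-gated Scheirer-Ray-Hare (or
    ANOVA) decomposition of plaque volume by subject and side.

    *plaque_table* needs the geometric metric columns plus ``subject_id``,
    ``side``, ``calc_volume_mm3`` and ``calc_surface_area_mm2``;
    *subject_table* needs ``subject_id`` plus the 12 summary fields.
    """
    missing = [c for c in GEOMETRIC_PAIR_COLUMNS if c not in plaque_table.columns]
    if missing:
        raise ValueError(f"plaque table is missing columns: {missing}")
    n_tests = 0
    report: dict = {}

    pairwise = []
    for xc, yc in itertools.combinations(GEOMETRIC_PAIR_COLUMNS, 2):
        pairwise.append(
            _fit_entry(xc, yc, plaque_table[xc].to_numpy(), plaque_table[yc].to_numpy())
        )
        n_tests += 2
    report["pairwise_fits"] = pairwise

    calc_fits = []
    if {"calc_volume_mm3", "calc_surface_area_mm2"} <= set(plaque_table.columns):
        calcified = plaque_table[plaque_table["calc_volume_mm3"] > 0]
        for name, frame, xc, yc in [
            ("volume_all", plaque_table, "volume_mm3", "calc_volume_mm3"),
            ("area_all", plaque_table, "surface_area_mm2", "calc_surface_area_mm2"),
            ("volume_calcified", calcified, "volume_mm3", "calc_volume_mm3"),
            ("area_calcified", calcified, "surface_area_mm2", "calc_surface_area_mm2"),
        ]:
            if len(frame) >= 3 and frame[yc].gt(0).all():
                entry = _fit_entry(xc, yc, frame[xc].to_numpy(), frame[yc].to_numpy())
            else:
                lin = fit_linear(frame[xc], frame[yc]) if len(frame) >= 3 and frame[xc].nunique() > 1 else None
                entry = {"x": xc, "y": yc, "linear": lin, "power": None,
                         "significant": bool(lin.significant) if lin else False,
                         "strong": bool(lin.strong) if lin else False}
            entry["subset"] = name
            calc_fits.append(entry)
            n_tests += 1
        report["calcification_fits"] = calc_fits

        vsar = plaque_table["volume_mm3"] / plaque_table["surface_area_mm2"]
        report["vsar_fit"] = {
            "x": "calc_volume_mm3",
            "y": "vsar_mm",
            "linear": fit_linear(plaque_table["calc_volume_mm3"], vsar),
        }
        n_tests += 1

    if covariate_table is not None:
        merged = subject_table.merge(covariate_table, on="subject_id")
        numeric = [
            c
            for c in covariate_table.columns
            if c != "subject_id"
            and pd.api.types.is_numeric_dtype(covariate_table[c])
            and covariate_table[c].nunique() > 2
        ]
        binary = [
            c
            for c in covariate_table.columns
            if c != "subject_id" and covariate_table[c].nunique() == 2
        ]
        corr: dict = {}
        for cov in numeric:
            corr[cov] = {}
            for f in SUMMARY_FIELDS:
                if f in merged.columns and merged[f].nunique() > 1 and merged[cov].nunique() > 1:
                    corr[cov][f] = spearman(merged[cov], merged[f])
                    n_tests += 1
        report["covariate_spearman"] = corr

        groups: dict = {}
        for cov in binary:
            groups[cov] = {}
            for f in SUMMARY_FIELDS:
                if f not in merged.columns:
                    continue
                counts = merged[cov].value_counts()
                if len(counts) == 2 and counts.min() >= 3:
                    groups[cov][f] = compare_groups(merged[f], merged[cov])
                    n_tests += 1
        report["group_tests"] = groups

    if {"subject_id", "side"} <= set(plaque_table.columns):
        vols = plaque_table["volume_mm3"].to_numpy()
        side = plaque_table["side"].to_numpy()
        subj = plaque_table["subject_id"].to_numpy()
        n_cells = len(pd.unique(side)) * len(pd.unique(subj))
        if (
            len(pd.unique(side)) >= 2
            and len(pd.unique(subj)) >= 2
            and len(vols) >= n_cells + 2
        ):
            lev_p = levene(vols, side)
            report["levene_p_side"] = lev_p
            report["variance_homogeneous"] = bool(lev_p > 0.05)
            report["srh"] = scheirer_ray_hare(vols, subj, side)
            n_tests += 4
            if report["variance_homogeneous"]:
                # homogeneous variance: parametric two-way ANOVA applies
                import statsmodels.api as sm
                from statsmodels.formula.api import ols

                df = pd.DataFrame({"v": vols, "subj": subj, "side": side})
                try:
                    model = ols("v ~ C(subj) + C(side) + C(subj):C(side)", df).fit()
                    report["anova"] = sm.stats.anova_lm(model, typ=1)
                except Exception:
                    report["anova"] = None

    report["n_tests"] = n_tests
    return report
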