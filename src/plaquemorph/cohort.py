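"""Synthetic cohort tables with known rank-dependence structure.

Emulates the inputs of a subject-based plaque analysis: per-plaque
geometric parameters drawn from log-normal size distributions tied
together by allometric (power-law) relations with multiplicative noise,
and per-subject haematological covariates linked to total plaque burden
through a Gaussian copula so that only the rank (Spearman) dependence is
controlled — matching what such clinical analyses report.

Default parameters are calibrated to a 42-subject carotid cohort: ~2.7
plaques per subject, subject total plaque volume with median ~443 mm^3
(IQR roughly 297-742 mm^3), about half of plaques carrying calcification,
and covariate/size Spearman correlations of the magnitudes reported for
triglycerides (~0.5), total cholesterol (~0.36), folate (~-0.33) and
vitamin B12 (~0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "make_cohort", "DEFAULT_COVARIATES"]

# (target Spearman with TPV, marginal family, marginal params)
DEFAULT_COVARIATES: dict[str, tuple[float, str, tuple[float, float]]] = {
    "TG": (0.50, "lognormal", (np.log(1.32), 0.61)),
    "TC": (0.36, "lognormal", (np.log(4.34), 0.19)),
    "HDL_C": (0.0, "lognormal", (np.log(1.14), 0.19)),
    "LDL_C": (0.10, "normal", (2.81, 0.91)),
    "FOL": (-0.33, "lognormal", (np.log(13.37), 0.83)),
    "VB12": (0.30, "lognormal", (np.log(309.5), 0.90)),
    "FIB": (0.0, "normal", (3.87, 0.86)),
    "UA": (0.0, "normal", (322.52, 105.69)),
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``plaque_count_distribution`` is (mean, dispersion) of the per-subject
    plaque count: 1 + a negative binomial with that mean - 1 and shape
    ``dispersion`` (every subject has at least one plaque).
    ``plaque_volume_lognormal`` is (log-mean, log-sd) of per-plaque volume
    in mm^3. ``covariate_rank_corr`` maps covariate name to the target
    Spearman correlation with subject total plaque volume.
    """

    n_subjects: int = 42
    plaque_count_distribution: tuple[float, float] = (2.67, 1.5)
    plaque_volume_lognormal: tuple[float, float] = (5.2, 0.85)
    calcified_fraction: float = 0.55
    covariate_rank_corr: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        mean, disp = self.plaque_count_distribution
        if mean < 1 or disp <= 0:
            raise ValueError("plaque count mean must be >= 1 and dispersion > 0")
        mu, sd = self.plaque_volume_lognormal
        if sd <= 0:
            raise ValueError("plaque volume log-sd must be positive")
        if not (0 <= self.calcified_fraction <= 1):
            raise ValueError("calcified_fraction must be in [0, 1]")
        if self.covariate_rank_corr is None:
            self.covariate_rank_corr = {
                k: v[0] for k, v in DEFAULT_COVARIATES.items()
            }
        for name, rho in self.covariate_rank_corr.items():
            if not (-1 <= rho <= 1):
                raise ValueError(f"rank correlation for {name} outside [-1, 1]")
            if abs(rho) == 1.0:
                raise ValueError(
                    f"rank correlation of exactly ±1 for {name} is unattainable "
                    "with a noisy marginal"
                )


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based van der Waerden normal scores (ties broken by order)."""
    from scipy import stats as sps

    n = values.size
    ranks = sps.rankdata(values, method="ordinal")
    return sps.norm.ppf((ranks - 0.5) / n)


def _marginal(family: str, params: tuple[float, float], w: np.ndarray) -> np.ndarray:
    loc, scale = params
    if family == "lognormal":
        return np.exp(loc + scale * w)
    if family == "normal":
        return loc + scale * w
    raise ValueError(f"unknown marginal family {family!r}")


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (per-plaque table, per-subject covariate table, true params).

    Plaque volumes are log-normal; downstream geometric parameters follow
    allometric relations with multiplicative log-normal noise; covariates
    achieve their target Spearman correlation with subject TPV in
    expectation via a Gaussian copula on rank-based normal scores (for a
    bivariate normal copula the latent Pearson r giving Spearman rho_s is
    r = 2*sin(pi*rho_s/6)).
    """
    rng = np.random.default_rng(spec.seed)
    count_mean, disp = spec.plaque_count_distribution
    mu_v, sd_v = spec.plaque_volume_lognormal

    extra = count_mean - 1.0
    if extra > 0:
        p_nb = disp / (disp + extra)
        counts = 1 + rng.negative_binomial(disp, p_nb, size=spec.n_subjects)
    else:
        counts = np.ones(spec.n_subjects, dtype=int)

    # allometric links between size and the other geometric parameters;
    # prefactors chosen for a plausibly eccentric (non-spherical) shape
    shape = {
        "c_area": 7.0, "sd_area": 0.10,
        "c_length": 2.2, "sd_length": 0.18,
        "geodesic_excess": 1.15, "sd_geodesic": 0.05,
        "c_cross_area": 1.8, "sd_cross_area": 0.15,
        "sd_diameter": 0.08,
        "ud_log_sd": 0.45,
        "calc_fraction_mean": 0.15, "calc_fraction_logsd": 0.7,
        "c_calc_area": 6.0, "sd_calc_area": 0.12,
    }

    rows = []
    for sid in range(spec.n_subjects):
        k = int(counts[sid])
        v = np.exp(rng.normal(mu_v, sd_v, size=k))
        sa = shape["c_area"] * v ** (2 / 3) * np.exp(rng.normal(0, shape["sd_area"], k))
        ln = shape["c_length"] * v ** (1 / 3) * np.exp(
            rng.normal(0, shape["sd_length"], k)
        )
        gd = ln * shape["geodesic_excess"] * np.exp(
            np.abs(rng.normal(0, shape["sd_geodesic"], k))
        )
        ca = shape["c_cross_area"] * v ** (2 / 3) * np.exp(
            rng.normal(0, shape["sd_cross_area"], k)
        )
        cd = 2 * np.sqrt(ca / np.pi) * np.exp(
            np.abs(rng.normal(0, shape["sd_diameter"], k))
        )
        ud = np.exp(rng.normal(0, shape["ud_log_sd"], k))
        calcified = rng.random(k) < spec.calcified_fraction
        frac = shape["calc_fraction_mean"] * np.exp(
            rng.normal(0, shape["calc_fraction_logsd"], k)
        )
        cv = np.where(calcified, np.minimum(frac, 0.8) * v, 0.0)
        csa = np.where(
            calcified,
            shape["c_calc_area"] * np.maximum(cv, 1e-12) ** (2 / 3)
            * np.exp(rng.normal(0, shape["sd_calc_area"], k)),
            0.0,
        )
        side = rng.choice(["left", "right"], size=k, p=[0.57, 0.43])
        for j in range(k):
            rows.append(
                {
                    "subject_id": sid,
                    "plaque_id": j,
                    "side": side[j],
                    "volume_mm3": v[j],
                    "surface_area_mm2": sa[j],
                    "length_mm": ln[j],
                    "surface_distance_mm": gd[j],
                    "max_cross_area_mm2": ca[j],
                    "max_cross_diameter_mm": cd[j],
                    "ud_ratio": ud[j],
                    "vsar_mm": v[j] / sa[j],
                    "calc_volume_mm3": cv[j],
                    "calc_surface_area_mm2": csa[j],
                }
            )
    plaque_df = pd.DataFrame(rows)

    tpv = plaque_df.groupby("subject_id")["volume_mm3"].sum().reindex(
        range(spec.n_subjects)
    ).to_numpy()
    z = _normal_scores(tpv)
    cov_rows: dict[str, np.ndarray] = {"subject_id": np.arange(spec.n_subjects)}
    for name, rho_s in spec.covariate_rank_corr.items():
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        eps = rng.standard_normal(spec.n_subjects)
        w = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * eps
        family, params = DEFAULT_COVARIATES.get(name, (None, "normal", (0.0, 1.0)))[1:]
        cov_rows[name] = _marginal(family, params, w)
    # binary demographics, independent of geometry
    cov_rows["sex_male"] = (rng.random(spec.n_subjects) < 0.667).astype(int)
    cov_rows["hypertension"] = (rng.random(spec.n_subjects) < 0.762).astype(int)
    cov_rows["diabetes"] = (rng.random(spec.n_subjects) < 0.167).astype(int)
    covariate_df = pd.DataFrame(cov_rows)

    true_params = {
        "plaque_count_distribution": spec.plaque_count_distribution,
        "plaque_volume_lognormal": spec.plaque_volume_lognormal,
        "calcified_fraction": spec.calcified_fraction,
        "covariate_rank_corr": dict(spec.covariate_rank_corr),
        "latent_pearson": {
            k: 2.0 * np.sin(np.pi * v / 6.0)
            for k, v in spec.covariate_rank_corr.items()
        },
        "shape": shape,
        "seed": spec.seed,
    }
    return plaque_df, covariate_df, true_params
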