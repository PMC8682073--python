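"""Synthetic cohort generator and PET utility functions.

The generator emulates the statistical structure of the analysis sample:
87 cognitively normal older adults, roughly a quarter amyloid-positive and a
quarter APOE e4 carriers, with vascular measurements drawn from a Gaussian
copula, a two-component amyloid (PiB DVR) mixture straddling the 1.06
positivity cutoff, tau (FTP SUVR) in entorhinal cortex and inferior temporal
gyrus with a configurable amyloid-group difference, and white-matter lesion
burden whose log ratio to white-matter volume is correlated with the
Framingham risk computed from the generated vascular variables.  The
defaults encode the null scenario for the risk-tau association (zero
correlation), the scenario of primary interest.

The copula correlations and marginal means/SDs are synthetic, plausible
values for an older cohort; they are design constants of the generator, not
estimates of any real sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .framingham import (
    SubjectVitals,
    framingham_cvd_10yr,
    load_framingham_coefficients,
    mean_arterial_pressure,
    resolve_all_conditions,
)

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "gmm_threshold",
    "scanner_harmonize",
    "compute_risk_columns",
]

# latent copula order
_LATENT = ("bmi", "sbp", "pp", "total_chol", "hdl", "ldl",
           "triglycerides", "fasting_glucose", "smoke")


def _default_copula() -> np.ndarray:
    """Plausible pairwise correlations among the latent vascular normals:
    a positive adiposity / pressure / glycaemia block and the usual negative
    HDL-triglyceride relation."""
    p = len(_LATENT)
    C = np.eye(p)
    idx = {v: i for i, v in enumerate(_LATENT)}

    def set_(a, b, rho):
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = rho

    set_("bmi", "sbp", 0.30)
    set_("bmi", "pp", 0.15)
    set_("sbp", "pp", 0.55)
    set_("bmi", "fasting_glucose", 0.35)
    set_("bmi", "triglycerides", 0.30)
    set_("bmi", "hdl", -0.35)
    set_("sbp", "fasting_glucose", 0.20)
    set_("total_chol", "ldl", 0.88)
    set_("total_chol", "hdl", 0.20)
    set_("total_chol", "triglycerides", 0.30)
    set_("ldl", "triglycerides", 0.20)
    set_("hdl", "triglycerides", -0.45)
    set_("fasting_glucose", "triglycerides", 0.25)
    set_("smoke", "hdl", -0.10)
    return C


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; defaults encode the emulated study sample."""

    n_subjects: int = 87
    fraction_female: float = 51 / 87
    fraction_pib_pos: float = 21 / 87
    fraction_e4: float = 23 / 87
    # age: truncated normal calibrated to median 77, IQR 70-83
    age_mean: float = 76.5
    age_sd: float = 9.6
    age_range: tuple = (60.0, 96.0)
    # marginal means/SDs of the vascular variables (synthetic, plausible)
    vascular_means: dict = field(default_factory=lambda: {
        "bmi": 27.5, "sbp": 126.0, "pp": 52.0, "total_chol": 190.0,
        "hdl": 58.0, "ldl": 112.0, "log_triglycerides": math.log(95.0),
        "fasting_glucose": 97.0})
    vascular_sds: dict = field(default_factory=lambda: {
        "bmi": 4.5, "sbp": 16.0, "pp": 12.0, "total_chol": 35.0,
        "hdl": 15.0, "ldl": 30.0, "log_triglycerides": 0.40,
        "fasting_glucose": 15.0})
    fraction_former_smoker: float = 31 / 87
    fraction_current_smoker: float = 1 / 87
    # outcome structure
    suvr_group_effect: float = 0.09
    suvr_cvd_correlation: float = 0.0
    wml_cvd_correlation: float = 0.24
    dvr_neg_mean: float = 0.98
    dvr_neg_sd: float = 0.045
    dvr_pos_mean: float = 1.28
    dvr_pos_sd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_female", "fraction_pib_pos", "fraction_e4",
                     "fraction_former_smoker", "fraction_current_smoker"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("suvr_cvd_correlation", "wml_cvd_correlation"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


def _exact_count_flags(n: int, fraction: float, rng) -> np.ndarray:
    """Binary vector with round(n * fraction) ones in random positions."""
    k = int(round(n * fraction))
    flags = np.zeros(n, bool)
    flags[rng.permutation(n)[:k]] = True
    return flags


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort as a subject-level table.

    Vascular variables come from the Gaussian copula; the Framingham risk is
    computed from them (never drawn directly), and the imaging outcomes are
    then generated conditionally on the standardised risk so the configured
    risk-outcome correlations hold in expectation.
    """
    if config is None:
        config = CohortConfig()
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)

    copula = _default_copula()
    try:
        chol = np.linalg.cholesky(copula)
    except np.linalg.LinAlgError as exc:
        raise ValueError("copula correlation matrix is not positive definite") from exc

    sex = np.where(_exact_count_flags(n, config.fraction_female, rng),
                   "female", "male")
    e4 = _exact_count_flags(n, config.fraction_e4, rng)

    a, b = ((config.age_range[0] - config.age_mean) / config.age_sd,
            (config.age_range[1] - config.age_mean) / config.age_sd)
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)

    z = rng.standard_normal((n, len(_LATENT))) @ chol.T
    lat = {v: z[:, i] for i, v in enumerate(_LATENT)}
    m, s = config.vascular_means, config.vascular_sds

    bmi = np.clip(m["bmi"] + s["bmi"] * lat["bmi"], 16.0, None)
    sbp = np.clip(m["sbp"] + s["sbp"] * lat["sbp"], 85.0, None)
    pp = np.clip(m["pp"] + s["pp"] * lat["pp"], 15.0, None)
    dbp = sbp - pp
    total_chol = np.clip(m["total_chol"] + s["total_chol"] * lat["total_chol"],
                         90.0, None)
    hdl = np.clip(m["hdl"] + s["hdl"] * lat["hdl"], 20.0, None)
    ldl = np.clip(m["ldl"] + s["ldl"] * lat["ldl"], 30.0, None)
    trig = np.exp(m["log_triglycerides"]
                  + s["log_triglycerides"] * lat["triglycerides"])
    glucose = np.clip(m["fasting_glucose"]
                      + s["fasting_glucose"] * lat["fasting_glucose"], 60.0, None)

    # smoking from the latent normal's upper quantiles
    q_cur = stats.norm.ppf(1 - config.fraction_current_smoker)
    q_for = stats.norm.ppf(
        1 - config.fraction_current_smoker - config.fraction_former_smoker)
    smoking = np.where(lat["smoke"] >= q_cur, "current",
                       np.where(lat["smoke"] >= q_for, "former", "never"))

    # self-report flags loosely consistent with the measurements
    def flags(above: np.ndarray, med_rate=0.7, flip=0.10, miss=0.05):
        dx = above ^ (rng.random(n) < flip)
        med = dx & (rng.random(n) < med_rate)
        dx = np.where(rng.random(n) < miss, None, dx).astype(object)
        med = np.where(rng.random(n) < miss, None, med).astype(object)
        return med, dx

    med_htn, dx_htn = flags((sbp >= 130) | (dbp >= 80))
    med_dm, dx_dm = flags(glucose > 125, med_rate=0.8)
    med_chol, dx_chol = flags(total_chol >= 200)

    # amyloid mixture with exact positive count; labels from the component
    pib_pos = _exact_count_flags(n, config.fraction_pib_pos, rng)
    dvr = np.where(
        pib_pos,
        rng.normal(config.dvr_pos_mean, config.dvr_pos_sd, n),
        rng.normal(config.dvr_neg_mean, config.dvr_neg_sd, n),
    )
    dvr = np.clip(dvr, 0.8, None)

    table = pd.DataFrame({
        "id": [f"S{i:04d}" for i in range(n)],
        "age": age, "sex": sex, "apoe_e4": e4.astype(int),
        "bmi": bmi, "sbp": sbp, "dbp": dbp, "total_chol": total_chol,
        "hdl": hdl, "ldl": ldl, "triglycerides": trig,
        "fasting_glucose": glucose, "smoking": smoking,
        "med_htn": med_htn, "med_dm": med_dm, "med_chol": med_chol,
        "dx_htn": dx_htn, "dx_dm": dx_dm, "dx_chol": dx_chol,
        "pib_dvr": dvr, "pib_group": pib_pos.astype(int),
    })

    # Framingham risk computed downstream from the vascular variables,
    # then standardised to structure the imaging outcomes
    risk = compute_risk_columns(table)["cvd_risk"].to_numpy()
    z_risk = (risk - risk.mean()) / risk.std(ddof=1)

    def risk_linked_noise(total_corr: float, slope_part: np.ndarray,
                          noise_sd: float) -> np.ndarray:
        sigma_tot = math.sqrt(np.var(slope_part, ddof=1) + noise_sd ** 2)
        a_coef = total_corr * sigma_tot / noise_sd
        if abs(a_coef) >= 1:
            raise ValueError(
                "requested risk-outcome correlation is infeasible for the "
                "configured noise level")
        eps = rng.standard_normal(n)
        return noise_sd * (a_coef * z_risk
                           + math.sqrt(1 - a_coef ** 2) * eps)

    # tau SUVR: linear in DVR (group difference ~ suvr_group_effect for the
    # default mixture separation of 0.30) plus risk-linked noise
    dvr_sep = config.dvr_pos_mean - config.dvr_neg_mean
    slope = config.suvr_group_effect / dvr_sep if dvr_sep > 0 else 0.0
    dvr_part = slope * (dvr - dvr.mean())
    suvr_ec = 1.15 + dvr_part + risk_linked_noise(
        config.suvr_cvd_correlation, dvr_part, 0.14)
    suvr_itg = 1.20 + dvr_part + risk_linked_noise(
        config.suvr_cvd_correlation, dvr_part, 0.10)

    wmv = np.clip(rng.normal(480_000, 60_000, n), 300_000, None)
    log_ratio = -5.3 + (config.wml_cvd_correlation * z_risk
                        + math.sqrt(1 - config.wml_cvd_correlation ** 2)
                        * rng.standard_normal(n))
    log_ratio = np.minimum(log_ratio, -0.5)  # keep WML < WMV
    wml = wmv * np.exp(log_ratio)

    table["suvr_ec"] = np.clip(suvr_ec, 0.5, None)
    table["suvr_itg"] = np.clip(suvr_itg, 0.5, None)
    table["wmv"] = wmv
    table["wml"] = wml
    return table


def compute_risk_columns(table: pd.DataFrame) -> pd.DataFrame:
    """MAP, resolved conditions and Framingham 10-year risk for every row.

    Vectorised implementation of the per-subject rules in
    :mod:`vascbayes.framingham`; the test suite asserts row-for-row agreement
    with the scalar functions.
    """
    from .framingham import smoking_category

    coeffs = load_framingham_coefficients()
    n = len(table)
    sbp = table["sbp"].to_numpy(float)
    dbp = table["dbp"].to_numpy(float)
    if np.any(~(sbp > dbp) | ~(dbp > 0)):
        raise ValueError("require SBP > DBP > 0 for every subject")
    glucose = table["fasting_glucose"].to_numpy(float)
    chol = table["total_chol"].to_numpy(float)
    hdl = table["hdl"].to_numpy(float)
    age = table["age"].to_numpy(float)
    if np.any(age <= 0) or np.any(chol <= 0) or np.any(hdl <= 0):
        raise ValueError("nonpositive value cannot enter a log term")
    smoking = np.array([smoking_category(s) for s in table["smoking"]])

    def tri_col(name):
        if name not in table.columns:
            return np.full(n, None, object)
        return np.array([_tri(v) for v in table[name]], object)

    def resolve(med, dx, fallback):
        med_yes = np.array([v is True for v in med])
        dx_known = np.array([v is not None for v in dx])
        dx_yes = np.array([v is True for v in dx])
        return np.where(med_yes, True,
                        np.where(dx_known, dx_yes, fallback))

    med_htn = tri_col("med_htn")
    htn = resolve(med_htn, tri_col("dx_htn"), (sbp >= 130) | (dbp >= 80))
    dm = resolve(tri_col("med_dm"), tri_col("dx_dm"), glucose > 125)
    hichol = resolve(tri_col("med_chol"), tri_col("dx_chol"), chol >= 200)

    sexes = table["sex"].to_numpy()
    treated = np.array([v is True for v in med_htn])  # missing -> untreated
    smoker = smoking == "current"
    risk = np.empty(n)
    for sex in ("female", "male"):
        mask = sexes == sex
        if not mask.any():
            continue
        b = coeffs.betas[sex]
        lp = (b["ln_age"] * np.log(age[mask])
              + b["ln_total_chol"] * np.log(chol[mask])
              + b["ln_hdl"] * np.log(hdl[mask])
              + np.where(treated[mask], b["ln_sbp_treated"],
                         b["ln_sbp_untreated"]) * np.log(sbp[mask])
              + b["smoker"] * smoker[mask]
              + b["diabetes"] * dm[mask].astype(float))
        risk[mask] = 1 - coeffs.s0_10yr[sex] ** np.exp(lp - coeffs.mean_lp[sex])
    unknown = ~np.isin(sexes, ("female", "male"))
    if unknown.any():
        raise ValueError(f"unknown sex values: {set(sexes[unknown])}")
    return pd.DataFrame({
        "map": dbp + (sbp - dbp) / 3.0,
        "hypertension": htn.astype(int),
        "diabetes": dm.astype(int),
        "high_cholesterol": hichol.astype(int),
        "cvd_risk": np.clip(risk, 1e-12, 1 - 1e-12),
    }, index=table.index)


def _tri(value):
    """Coerce a CSV / object cell to the True / False / None tri-state."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in ("", "nan", "missing", "na", "none"):
        return None
    if token in ("1", "1.0", "true", "yes", "y"):
        return True
    if token in ("0", "0.0", "false", "no", "n"):
        return False
    raise ValueError(f"cannot interpret tri-state flag {value!r}")


def gmm_threshold(values, random_state: int = 0) -> float:
    """Positivity cutoff from a two-component Gaussian mixture.

    The cutoff is the point between the two component means where the
    posterior membership probabilities are equal (for equal weights this
    coincides with the density crossing).
    """
    x = np.asarray(values, float)
    if x.ndim != 1 or len(x) < 20:
        raise ValueError("need at least 20 values")
    if np.any(x <= 0):
        raise ValueError("values must be positive")
    if np.ptp(x) == 0:
        raise ValueError("values are all identical; mixture is degenerate")
    gm = GaussianMixture(n_components=2, n_init=10,
                         random_state=random_state).fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    mu1, mu2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    if min(s1, s2) < 1e-8 * np.std(x):
        raise ValueError("mixture fit degenerate (vanishing variance)")

    def posterior_diff(v):
        l1 = math.log(w1) + stats.norm.logpdf(v, mu1, s1)
        l2 = math.log(w2) + stats.norm.logpdf(v, mu2, s2)
        return l1 - l2

    lo, hi = mu1 + 1e-9, mu2 - 1e-9
    if posterior_diff(lo) <= 0 or posterior_diff(hi) >= 0:
        raise ValueError("no equal-posterior crossing between component means")
    return float(optimize.brentq(posterior_diff, lo, hi))


def scanner_harmonize(value_a, value_b):
    """OLS mapping from scanner B values to scanner A scale.

    Returns ``(slope, intercept, apply)`` where ``apply`` transforms any
    vector of B-scale values to the A scale.
    """
    a = np.asarray(value_a, float)
    b = np.asarray(value_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired value vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if b.var(ddof=1) == 0:
        raise ValueError("predictor values are constant")
    design = np.column_stack([np.ones(len(b)), b])
    (intercept, slope), *_ = np.linalg.lstsq(design, a, rcond=None)

    def apply(values):
        return intercept + slope * np.asarray(values, float)

    return float(slope), float(intercept), apply
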