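"""End-to-end cohort analysis as a model / results pair.

``CohortAnalysis`` holds a validated subject table plus prior settings;
``fit()`` builds the vascular-risk variables, runs the frequentist sanity
checks, the main Bayes-factor analyses (correlation, t-test and nested
regressions relating cardiovascular risk to amyloid and tau measures), and
optionally the principal-component-score model search, returning a
``CohortAnalysisResults`` with a printable summary.

A summary-statistic mode is available through the underlying Bayes-factor
functions: any correlation row can be reproduced from a printed (n, r) pair
without subject-level data.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .bayesfactor import (
    CorrSummary,
    PriorScale,
    RegressionSummary,
    TTestSummary,
    interpret_bf,
    jzs_ttest_bf,
    model_search,
    nested_model_bf,
    stretched_beta_corr_bf,
)
from .classical import pearson_test, variance_ratio_test, welch_ttest
from .cohort import compute_risk_columns
from .pca import VASCULAR_PCA_VARIABLES, PCAModel, fit_pca

__all__ = ["CohortAnalysis", "CohortAnalysisResults", "load_and_filter"]

REQUIRED_COLUMNS = (
    "age", "sex", "apoe_e4", "bmi", "sbp", "dbp", "total_chol", "hdl",
    "ldl", "triglycerides", "fasting_glucose", "smoking",
    "pib_dvr", "pib_group", "suvr_ec", "suvr_itg", "wml", "wmv",
)
FLAG_COLUMNS = ("med_htn", "med_dm", "med_chol", "dx_htn", "dx_dm", "dx_chol")
_NUMERIC = ("age", "bmi", "sbp", "dbp", "total_chol", "hdl", "ldl",
            "triglycerides", "fasting_glucose", "pib_dvr", "suvr_ec",
            "suvr_itg", "wml", "wmv")


def load_and_filter(source,
                    suvr_outlier_z: float | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a cohort CSV (or DataFrame) and apply the exclusion rules.

    Rows with any missing required variable are excluded and logged; a
    missing antihypertensive-medication answer is imputed as "no treatment"
    rather than excluding the row.  ``suvr_outlier_z`` optionally switches
    on a robust-z screen (median/MAD) that additionally excludes rows whose
    regional SUVR lies beyond the given |z| (off by default).
    Returns ``(table, exclusion_log)``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    known = set(REQUIRED_COLUMNS) | set(FLAG_COLUMNS) | {"id"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file lacks required columns: {missing_cols}")
    for col in _NUMERIC:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            line = int(bad[0]) + 2  # header + 1-based
            raise ValueError(
                f"malformed numeric value in column {col!r} near line {line}")

    # antihypertensive use: missing means untreated
    if "med_htn" in df.columns:
        df["med_htn"] = df["med_htn"].where(df["med_htn"].notna(), False)
    else:
        df["med_htn"] = False

    reasons = []
    for idx, row in df.iterrows():
        missing = [c for c in REQUIRED_COLUMNS if pd.isna(row[c])]
        if missing:
            reasons.append({"index": idx,
                            "id": row.get("id", idx),
                            "reason": "missing: " + ", ".join(missing)})
    if suvr_outlier_z is not None:
        for col in ("suvr_ec", "suvr_itg"):
            v = pd.to_numeric(df[col], errors="coerce")
            mad = (v - v.median()).abs().median()
            if mad > 0:
                z = 0.6744897501960817 * (v - v.median()) / mad
                for idx in df.index[z.abs() > suvr_outlier_z]:
                    reasons.append({"index": idx, "id": df.loc[idx].get("id", idx),
                                    "reason": f"outlier: {col}"})
    excluded = pd.DataFrame(reasons, columns=["index", "id", "reason"])
    excluded = excluded.drop_duplicates(subset="index")
    kept = df.drop(index=excluded["index"]) if len(excluded) else df
    if (kept["wml"] <= 0).any() or (kept["wmv"] <= 0).any():
        raise ValueError("nonpositive WML or WMV volume: log ratio undefined")
    return kept.reset_index(drop=True), excluded


@dataclass
class CohortAnalysis:
    """Model object: a validated cohort plus analysis settings.

    Parameters
    ----------
    data : pandas.DataFrame
        Validated subject table (see ``load_and_filter``).
    cauchy_scale, kappa, g_scale : float
        Prior scales for the t-test, correlation and regression Bayes
        factors; medium-width defaults.
    pca_model : PCAModel, optional
        Training-set PCA for the component scores.  When omitted and the
        PCS analysis is requested, the PCA is fitted on the cohort itself.
    """

    data: pd.DataFrame
    cauchy_scale: float = np.sqrt(2) / 2
    kappa: float = 1 / 3
    g_scale: float = np.sqrt(2) / 2
    pca_model: Optional[PCAModel] = None
    exclusions: Optional[pd.DataFrame] = None

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CohortAnalysis":
        table, excluded = load_and_filter(path)
        return cls(data=table, exclusions=excluded, **kwargs)

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "CohortAnalysis":
        table, excluded = load_and_filter(df)
        return cls(data=table, exclusions=excluded, **kwargs)

    # -- pieces ----------------------------------------------------------
    def _with_risk(self) -> pd.DataFrame:
        df = self.data.copy()
        risk = compute_risk_columns(df)
        return pd.concat([df, risk], axis=1)

    def demographics(self, df: pd.DataFrame) -> pd.DataFrame:
        """Median (IQR) for continuous, N (%) for categorical, by sex."""
        rows = []
        for sex, sub in df.groupby("sex"):
            n = len(sub)
            entry = {"sex": sex, "n": n}
            for col in ("age", "cvd_risk"):
                q1, q2, q3 = sub[col].quantile([0.25, 0.5, 0.75])
                entry[col] = f"{q2:.2f} ({q1:.2f}, {q3:.2f})"
            for col, label in (("apoe_e4", "e4_carriers"),
                               ("pib_group", "pib_positive"),
                               ("hypertension", "hypertension"),
                               ("diabetes", "diabetes"),
                               ("high_cholesterol", "high_cholesterol")):
                k = int(sub[col].sum())
                entry[label] = f"{k} ({100 * k / n:.0f}%)"
            rows.append(entry)
        return pd.DataFrame(rows)

    def sanity_checks(self, df: pd.DataFrame) -> dict:
        """Frequentist validation analyses, unadjusted for age or sex."""
        log_wml = np.log(df["wml"] / df["wmv"])
        risk = df["cvd_risk"]
        pos = df["pib_group"] == 1
        return {
            "risk_vs_log_wml": pearson_test(risk, log_wml),
            "suvr_ec_by_group": welch_ttest(df.loc[pos, "suvr_ec"],
                                            df.loc[~pos, "suvr_ec"]),
            "suvr_itg_by_group": welch_ttest(df.loc[pos, "suvr_itg"],
                                             df.loc[~pos, "suvr_itg"]),
            "dvr_vs_suvr_ec": pearson_test(df["pib_dvr"], df["suvr_ec"]),
            "dvr_vs_suvr_itg": pearson_test(df["pib_dvr"], df["suvr_itg"]),
            "risk_variance_by_group": variance_ratio_test(
                df.loc[~pos, "cvd_risk"], df.loc[pos, "cvd_risk"]),
        }

    def main_analysis(self, df: pd.DataFrame) -> pd.DataFrame:
        """Bayes-factor table relating CVD risk to amyloid and tau."""
        corr_prior = PriorScale("stretched_beta", self.kappa)
        t_prior = PriorScale("cauchy_effect", self.cauchy_scale)
        g_prior = PriorScale("g_invgamma", self.g_scale)
        risk = df["cvd_risk"].to_numpy()
        pos = (df["pib_group"] == 1).to_numpy()
        n = len(df)
        rows = []

        def corr_row(hypothesis, region, x, y):
            res = stretched_beta_corr_bf(CorrSummary.from_samples(x, y),
                                         corr_prior)
            rows.append({"hypothesis": hypothesis, "model": "Pearson correlation",
                         "region": region, "bf01": res.bf01,
                         "prior_scale": self.kappa, "n": n,
                         "interpretation": res.interpret()})

        res_t = jzs_ttest_bf(
            TTestSummary.from_samples(risk[~pos], risk[pos]), t_prior)
        rows.append({"hypothesis": "difference in mean CVD risk by PiB group",
                     "model": "t-test", "region": "-", "bf01": res_t.bf01,
                     "prior_scale": self.cauchy_scale, "n": n,
                     "interpretation": res_t.interpret()})
        corr_row("correlation of CVD risk and PiB DVR", "-",
                 risk, df["pib_dvr"])
        corr_row("correlation of CVD risk and FTP SUVR", "EC",
                 risk, df["suvr_ec"])
        corr_row("correlation of CVD risk and FTP SUVR", "ITG",
                 risk, df["suvr_itg"])

        e4 = (df["apoe_e4"] == 1).to_numpy(float)
        pib = pos.astype(float)
        inter = risk * pib
        for region, col in (("EC", "suvr_ec"), ("ITG", "suvr_itg")):
            y = df[col].to_numpy()
            null = RegressionSummary.from_fit(y, np.column_stack([e4, pib]))
            full = RegressionSummary.from_fit(
                y, np.column_stack([e4, pib, risk]))
            res = nested_model_bf(full, null, g_prior)
            rows.append({"hypothesis": "regression coefficient for CVD risk != 0",
                         "model": "SUVR ~ 1 + e4 + PiB + CVD",
                         "region": region, "bf01": res.bf01,
                         "prior_scale": self.g_scale, "n": n,
                         "interpretation": res.interpret()})
            full_i = RegressionSummary.from_fit(
                y, np.column_stack([e4, pib, risk, inter]))
            res_i = nested_model_bf(full_i, null, g_prior)
            rows.append({"hypothesis": ("coefficients for CVD risk and "
                                        "CVD x PiB interaction != 0"),
                         "model": "SUVR ~ 1 + e4 + PiB + CVD + CVD:PiB",
                         "region": region, "bf01": res_i.bf01,
                         "prior_scale": self.g_scale, "n": n,
                         "interpretation": res_i.interpret()})
        return pd.DataFrame(rows)

    def pcs_analysis(self, df: pd.DataFrame) -> dict:
        """Model search over age, sex, e4 and the first three PC scores."""
        work = df.copy()
        work["current_smoker"] = (work["smoking"] == "current").astype(float)
        model = self.pca_model
        if model is None:
            model = fit_pca(work, VASCULAR_PCA_VARIABLES)
        scores = model.project(work)
        work = pd.concat([work, scores], axis=1)
        g_prior = PriorScale("g_invgamma", self.g_scale)
        candidates = pd.DataFrame({
            "age": work["age"],
            "sex": (work["sex"] == "male").astype(float),
            "e4": work["apoe_e4"].astype(float),
            "pcs1": work["pcs1"], "pcs2": work["pcs2"], "pcs3": work["pcs3"],
        })
        log_wml = np.log(work["wml"] / work["wmv"])
        out = {"pca_model": model, "scores": scores,
               "correlations": {}, "search": {}}
        for j in (1, 2, 3):
            out["correlations"][f"pcs{j}_vs_log_wml"] = pearson_test(
                work[f"pcs{j}"], log_wml)
            out["correlations"][f"pcs{j}_vs_cvd_risk"] = pearson_test(
                work[f"pcs{j}"], work["cvd_risk"])
        for region, col in (("EC", "suvr_ec"), ("ITG", "suvr_itg")):
            table = model_search(work[col].to_numpy(), candidates, g_prior)
            top, runner = table.iloc[0], table.iloc[1]
            out["search"][region] = {
                "table": table,
                "top_model": top["covariates"],
                "runner_up": runner["covariates"],
                "bf_top_vs_runner_up": float(top["bf10"] / runner["bf10"]),
            }
        return out

    def fit(self, include_pcs: bool = True) -> "CohortAnalysisResults":
        df = self._with_risk()
        return CohortAnalysisResults(
            model=self,
            data=df,
            demographics=self.demographics(df),
            sanity=self.sanity_checks(df),
            main_table=self.main_analysis(df),
            pcs=self.pcs_analysis(df) if include_pcs else None,
            provenance={
                "n_subjects": len(df),
                "n_excluded": 0 if self.exclusions is None else len(self.exclusions),
                "cauchy_scale": self.cauchy_scale,
                "kappa": self.kappa,
                "g_scale": self.g_scale,
                "software": f"vascbayes {_version}",
            },
        )


@dataclass
class CohortAnalysisResults:
    """Results container produced by ``CohortAnalysis.fit``."""

    model: CohortAnalysis
    data: pd.DataFrame
    demographics: pd.DataFrame
    sanity: dict
    main_table: pd.DataFrame
    pcs: Optional[dict]
    provenance: dict

    def summary(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w("Vascular risk vs amyloid / tau: Bayesian evidence summary\n")
        w("=" * 60 + "\n\n")
        w(f"subjects: {self.provenance['n_subjects']}"
          f" (excluded: {self.provenance['n_excluded']})\n")
        w(f"prior scales: Cauchy {self.provenance['cauchy_scale']:.4g}, "
          f"kappa {self.provenance['kappa']:.4g}, "
          f"g {self.provenance['g_scale']:.4g}\n\n")
        w("Demographics (by sex)\n")
        w(self.demographics.to_string(index=False) + "\n\n")
        w("Sanity checks\n")
        s = self.sanity
        r = s["risk_vs_log_wml"]
        w(f"  CVD risk vs log(WML/WMV): r = {r.r:.3f} "
          f"(95% CI {r.ci_low:.3f} to {r.ci_high:.3f}), p = {r.p:.3g}\n")
        for key, label in (("suvr_ec_by_group", "EC SUVR by PiB group"),
                           ("suvr_itg_by_group", "ITG SUVR by PiB group")):
            t = s[key]
            w(f"  {label}: diff = {t.mean_diff:.4f} "
              f"(95% CI {t.ci_low:.4f} to {t.ci_high:.4f}), p = {t.p:.3g}\n")
        f = s["risk_variance_by_group"]
        w(f"  variance ratio of CVD risk (PiB-/PiB+): "
          f"F({f.df1},{f.df2}) = {f.f:.2f}, p = {f.p:.2g}\n\n")
        w("Main Bayes-factor table (bf01 = evidence null : alternative)\n")
        cols = ["hypothesis", "model", "region", "bf01", "interpretation"]
        tab = self.main_table[cols].copy()
        tab["bf01"] = tab["bf01"].map(lambda v: f"{v:.2f}")
        w(tab.to_string(index=False) + "\n")
        if self.pcs is not None:
            w("\nPC-score model search (top model vs runner-up)\n")
            for region, res in self.pcs["search"].items():
                top = res["top_model"] or ("intercept only",)
                run = res["runner_up"] or ("intercept only",)
                w(f"  {region}: top {' + '.join(top)} | runner-up "
                  f"{' + '.join(run)} | BF(top:runner-up) = "
                  f"{res['bf_top_vs_runner_up']:.2f}\n")
        return buf.getvalue()

    def interpret(self, bf01: float) -> str:
        return interpret_bf(bf01)
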