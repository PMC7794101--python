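"""Registry co-occurrence and SNP-metabolite models.

Three analyses that triangulate whether a case-control metabolite
difference reflects feeding patterns rather than genetics:

* Fisher's exact test on the 2x2 co-occurrence of a diagnosis code (here
  ICD-10 P92.5, neonatal difficulty in feeding at breast) with case status.
  The reported odds ratio is the conditional maximum-likelihood estimate
  under the noncentral hypergeometric model and the confidence interval is
  the exact central interval from inverting one-sided conditional tests.
* A linear model for the transformed metabolite level against the timing of
  the code (assigned on the day of birth vs later), among code carriers
  only, adjusted for sex, year of birth (continuous), parity, gestational
  age and case status.
* Additive-dosage linear models of SNP genotype against transformed
  metabolite levels or metabolite ratios (e.g. the product/precursor ratio
  PC(38:4)/PC(38:3) indexing FADS1 desaturase activity), adjusted for case
  status, sex, year of birth (factor), parity and gestational age, with
  optional birth-era stratification and a Bonferroni-corrected
  all-metabolite sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .assoc import AssocError, inverse_normal_transform

__all__ = [
    "TwoByTwo",
    "ExactTestResult",
    "SnpAssoc",
    "fisher_exact",
    "code_table",
    "code_timing_model",
    "metabolite_ratio",
    "snp_trait_assoc",
    "snp_metabolome_sweep",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a/c cases with/without the code, b/d controls with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class ExactTestResult:
    or_cmle: float
    ci_low: float
    ci_high: float
    p: float
    unbounded_ci: bool = False   # a zero cell pushed one CI bound to 0/inf


@dataclass(frozen=True)
class SnpAssoc:
    snp: str
    trait: str
    beta: float
    se: float
    p: float
    stratum: str = "all"
    n: int = 0
    effect_allele_dosage: str = "0/1/2"


def fisher_exact(table: TwoByTwo, conf: float = 0.95) -> ExactTestResult:
    """Fisher's exact test for a 2x2 table.

    Two-sided p-value sums noncentral-hypergeometric point probabilities at
    odds ratio 1 that do not exceed that of the observed table; the point
    estimate is the conditional MLE and the CI the exact central interval
    (one-sided conditional tests inverted at (1-conf)/2 per side).
    """
    t = table.as_array()
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        raise ValueError("Fisher exact test undefined for a zero margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    res = _odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(conf)
    unbounded = not (np.isfinite(ci.low) and np.isfinite(ci.high)
                     and ci.low > 0)
    return ExactTestResult(float(res.statistic), float(ci.low),
                           float(ci.high), float(p), unbounded)


def code_table(samples: pd.DataFrame, code_col: str = "p92_5") -> TwoByTwo:
    """Tally carriage of a diagnosis-code indicator column by case status."""
    if code_col not in samples.columns:
        raise ValueError(f"sample sheet lacks column {code_col!r}")
    has = samples[code_col].fillna(0).astype(int) > 0
    case = samples["case"].astype(int) == 1
    return TwoByTwo(
        a=int((case & has).sum()), b=int((~case & has).sum()),
        c=int((case & ~has).sum()), d=int((~case & ~has).sum()),
    )


def _ols(y: np.ndarray, X: np.ndarray, names: list[str], term: str
         ) -> tuple[float, float, float, int]:
    """OLS for one term of interest.

    Zero-variance covariate columns (constant in the analysis subset) are
    dropped silently; genuine collinearity involving the term, with the
    term ordered last, raises an error naming the collision.
    """
    keep = [j for j, nm in enumerate(names)
            if nm in ("intercept", term) or np.std(X[:, j]) > 0]
    X, names = X[:, keep], [names[j] for j in keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= j:
                raise AssocError(
                    f"design column {names[j]!r} is collinear with the "
                    f"preceding columns")
        raise AssocError("rank-deficient design")
    fit = sm.OLS(y, X).fit()
    j = names.index(term)
    return (float(fit.params[j]), float(fit.bse[j]),
            float(fit.pvalues[j]), int(len(y)))


def _covariate_design(df: pd.DataFrame, yob_factor: bool) -> tuple[list, list]:
    """Shared adjustment set: case status, sex, year of birth, parity, GA."""
    cols, names = [], []
    cols.append(df["case"].to_numpy(float)); names.append("case")
    sex = df["sex"].astype(str)
    for lev in sorted(sex.unique())[1:]:
        cols.append((sex == lev).to_numpy(float)); names.append(f"sex[{lev}]")
    yob = df["year_of_birth"].astype(int)
    if yob_factor:
        levels = sorted(yob.unique())
        # merge singleton years into the nearest level for estimability
        counts = yob.value_counts()
        keep = [lv for lv in levels if counts[lv] >= 2]
        if not keep:
            keep = levels[:1]
        yob = yob.map(lambda v: v if v in keep
                      else min(keep, key=lambda k: abs(k - v)))
        for lev in sorted(yob.unique())[1:]:
            cols.append((yob == lev).to_numpy(float))
            names.append(f"yob[{lev}]")
    else:
        cols.append(yob.to_numpy(float)); names.append("year_of_birth")
    cols.append(df["parity"].to_numpy(float)); names.append("parity")
    cols.append(df["gestational_age_wk"].to_numpy(float))
    names.append("gestational_age_wk")
    return cols, names


def code_timing_model(y_transformed, samples: pd.DataFrame,
                      day_col: str = "p92_5_day",
                      code_col: str = "p92_5") -> tuple[float, float, float]:
    """Among code carriers, regress the transformed metabolite on an
    indicator of the code being assigned on the day of birth.

    Ordinary least squares adjusted for sex (factor), year of birth
    (continuous), parity, gestational age and case status.  Returns
    (beta, se, p) for the day-of-birth indicator.
    """
    y = pd.Series(np.asarray(y_transformed, float), index=samples.index)
    carriers = samples[samples[code_col].fillna(0).astype(int) > 0].copy()
    if carriers.empty:
        raise AssocError("no code carriers in sample sheet")
    if carriers[day_col].isna().any():
        raise AssocError("code carriers with unknown code day")
    day0 = (carriers[day_col].astype(int) == 0).to_numpy(float)
    if min(day0.sum(), (1 - day0).sum()) < 2:
        raise AssocError("need >= 2 carriers per timing group")
    cols, names = _covariate_design(carriers, yob_factor=False)
    X = np.column_stack([np.ones(len(carriers))] + cols + [day0])
    names = ["intercept"] + names + ["day0"]
    return _ols(y.loc[carriers.index].to_numpy(), X, names, "day0")[:3]


def metabolite_ratio(numerator, denominator) -> np.ndarray:
    """Element-wise metabolite ratio on the concentration scale.

    Non-positive denominators yield NaN (flagged missing); transform the
    result before modelling.
    """
    num = np.asarray(numerator, float)
    den = np.asarray(denominator, float)
    out = np.full(num.shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def snp_trait_assoc(dosage, trait_transformed, samples: pd.DataFrame,
                    snp: str = "snp", trait: str = "trait",
                    stratum: str = "all") -> SnpAssoc:
    """Additive-dosage linear model of a transformed trait on genotype.

    Adjusted for case status, sex (factor), year of birth (factor), parity
    and gestational age.  ``dosage`` holds effect-allele counts 0/1/2;
    monomorphic genotypes are an error.
    """
    g = np.asarray(dosage, float)
    y = np.asarray(trait_transformed, float)
    ok = np.isfinite(g) & np.isfinite(y)
    if ok.sum() < 10:
        raise AssocError("too few samples with genotype and trait")
    if np.nanstd(g[ok]) == 0:
        raise AssocError(f"{snp}: monomorphic dosage")
    df = samples.iloc[np.where(ok)[0]]
    cols, names = _covariate_design(df, yob_factor=True)
    X = np.column_stack([np.ones(int(ok.sum()))] + cols + [g[ok]])
    names = ["intercept"] + names + ["dosage"]
    beta, se, p, n = _ols(y[ok], X, names, "dosage")
    return SnpAssoc(snp, trait, beta, se, p, stratum, n)


def snp_metabolome_sweep(dosage, matrix: pd.DataFrame, samples: pd.DataFrame,
                         snp: str = "snp", alpha: float = 0.05,
                         transform_offset: str = "half"
                         ) -> pd.DataFrame:
    """SNP association against every metabolite with Bonferroni correction
    over the number of metabolites tested."""
    rows = []
    for met in matrix.columns:
        yt = inverse_normal_transform(matrix[met].to_numpy(),
                                      offset=transform_offset)
        r = snp_trait_assoc(dosage, yt, samples, snp=snp, trait=met)
        rows.append((met, r.beta, r.se, r.p, r.n))
    out = pd.DataFrame(rows, columns=["metabolite", "beta", "se", "p", "n"])
    out["significant_bonferroni"] = out["p"] < alpha / len(out)
    return out.sort_values("p").reset_index(drop=True)
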