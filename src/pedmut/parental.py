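"""Parental origin, paternal bias, and parental-age regression models.

Phasing works on read-pair co-occurrence abstractions: a mutation is
assigned to a parent when a nearby heterozygous informant variant, carried
by exactly one parent, co-occurs with the mutant allele on the same
haplotype within the insert-size window.  Upscaling applies the phased
paternal:maternal ratio of a trio to its full mutation count, so per-parent
totals conserve the trio total by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import Pedigree

ORIGIN_PATERNAL = "paternal"
ORIGIN_MATERNAL = "maternal"
ORIGIN_UNPHASED = "unphased"


@dataclass
class ParentAgeModel:
    """Per-parent mutation-count model: count = intercept + slope * age.

    With ``link='log'`` the linear predictor is exponentiated (Poisson
    regression).  Confidence intervals, when fitted, are (low, high) pairs
    for each coefficient.
    """

    maternal_intercept: float
    maternal_slope: float
    paternal_intercept: float
    paternal_slope: float
    link: str = "identity"
    maternal_ci: Optional[tuple[tuple[float, float], tuple[float, float]]] = None
    paternal_ci: Optional[tuple[tuple[float, float], tuple[float, float]]] = None
    maternal_result: Optional[object] = None
    paternal_result: Optional[object] = None

    def predict_maternal(self, age_maternal: float) -> float:
        eta = self.maternal_intercept + self.maternal_slope * age_maternal
        return math.exp(eta) if self.link == "log" else eta

    def predict_paternal(self, age_paternal: float) -> float:
        eta = self.paternal_intercept + self.paternal_slope * age_paternal
        return math.exp(eta) if self.link == "log" else eta

    def predict_total(self, age_maternal: float, age_paternal: float) -> float:
        return self.predict_maternal(age_maternal) + self.predict_paternal(age_paternal)


@dataclass
class RateAgeModel:
    """Regressions of the per-trio rate on parental ages (identity link)."""

    paternal_intercept: float
    paternal_slope: float
    maternal_intercept: float
    maternal_slope: float
    joint_intercept: float
    joint_maternal_slope: float
    joint_paternal_slope: float
    diagnostics: dict = field(default_factory=dict)


def phase_mutations(
    mutations: pd.DataFrame, informants: pd.DataFrame, window: int = 230
) -> pd.DataFrame:
    """Assign parent of origin from phase-informative het variants.

    ``mutations`` needs columns (trio, pos); ``informants`` columns
    (trio, pos, informant_pos, carrier, same_haplotype) where ``carrier``
    is 'father' or 'mother'.  The implied origin is the carrier when the
    informant allele rides the same haplotype as the mutation, otherwise
    the other parent.  Mutations with conflicting informants, or none
    within the window, stay unphased.
    """
    out = mutations.copy()
    out["origin"] = ORIGIN_UNPHASED
    if informants.empty or mutations.empty:
        return out
    inf = informants.copy()
    inf = inf[(inf["informant_pos"] - inf["pos"]).abs() <= window]
    other = {"father": ORIGIN_MATERNAL, "mother": ORIGIN_PATERNAL}
    same = {"father": ORIGIN_PATERNAL, "mother": ORIGIN_MATERNAL}
    inf["implied"] = np.where(
        inf["same_haplotype"], inf["carrier"].map(same), inf["carrier"].map(other)
    )
    implied = inf.groupby(["trio", "pos"])["implied"].agg(
        lambda x: x.iloc[0] if x.nunique() == 1 else ORIGIN_UNPHASED
    )
    key = pd.MultiIndex.from_frame(out[["trio", "pos"]])
    mapped = implied.reindex(key)
    out["origin"] = mapped.fillna(ORIGIN_UNPHASED).to_numpy()
    return out


@dataclass
class PaternalFractionResult:
    fraction: float
    ci_low: float
    ci_high: float
    t_statistic: float
    df: int
    p_value: float
    per_trio: pd.Series


def paternal_fraction(mutations: pd.DataFrame) -> PaternalFractionResult:
    """Mean per-trio paternal fraction among phased mutations, tested vs 0.5.

    One-sample t-test of the per-trio fractions against equal parental
    contribution; the CI is the t-based 95% interval of the mean.
    """
    phased = mutations[mutations["origin"].isin([ORIGIN_PATERNAL, ORIGIN_MATERNAL])]
    if phased.empty:
        raise ValueError("no phased mutations")
    per_trio = phased.groupby("trio")["origin"].agg(
        lambda x: (x == ORIGIN_PATERNAL).mean()
    )
    mean = float(per_trio.mean())
    n = len(per_trio)
    if n > 1 and per_trio.std(ddof=1) > 0:
        test = stats.ttest_1samp(per_trio, 0.5)
        t_stat, p = float(test.statistic), float(test.pvalue)
        se = float(per_trio.std(ddof=1) / math.sqrt(n))
        tq = float(stats.t.ppf(0.975, n - 1))
        lo, hi = mean - tq * se, mean + tq * se
    else:
        t_stat, p, lo, hi = float("nan"), float("nan"), mean, mean
    return PaternalFractionResult(
        fraction=mean, ci_low=lo, ci_high=hi, t_statistic=t_stat, df=n - 1,
        p_value=p, per_trio=per_trio,
    )


def upscale_phased(
    m: float,
    phased_paternal: float,
    phased_maternal: float,
    phased_denominator_paternal: Optional[float] = None,
    phased_denominator_maternal: Optional[float] = None,
) -> tuple[float, float]:
    """Apply the phased paternal:maternal ratio to a trio's full count.

    When per-parent phasing denominators (total SNPs phased to each parent)
    are given, the phased counts are first normalized by them to remove the
    asymmetry of phasing opportunity.  Returns (paternal_total,
    maternal_total) with paternal + maternal = m exactly.
    """
    if phased_paternal + phased_maternal <= 0:
        raise ValueError("no phased mutations for this trio")
    if phased_paternal + phased_maternal > m:
        raise ValueError("phased counts exceed the total mutation count")
    wp, wm = float(phased_paternal), float(phased_maternal)
    if phased_denominator_paternal and phased_denominator_maternal:
        wp /= phased_denominator_paternal
        wm /= phased_denominator_maternal
    paternal = m * wp / (wp + wm)
    return paternal, m - paternal


def _simple_ols(y: np.ndarray, x: np.ndarray):
    X = sm.add_constant(np.asarray(x, dtype=float))
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def fit_rate_age_regressions(per_trio: pd.DataFrame) -> RateAgeModel:
    """Fit mu-on-age regressions (paternal-only, maternal-only, joint).

    ``per_trio`` needs columns (mu, age_maternal, age_paternal) with at
    least three rows and non-constant ages.
    """
    if len(per_trio) < 3:
        raise ValueError("need >= 3 trios for age regressions")
    for col in ("age_maternal", "age_paternal"):
        if per_trio[col].nunique() < 2:
            raise ValueError(f"{col} is constant; regression is undefined")
    pat = _simple_ols(per_trio["mu"], per_trio["age_paternal"])
    mat = _simple_ols(per_trio["mu"], per_trio["age_maternal"])
    X = sm.add_constant(per_trio[["age_maternal", "age_paternal"]].astype(float))
    joint = sm.OLS(per_trio["mu"].astype(float), X).fit()
    return RateAgeModel(
        paternal_intercept=float(pat.params[0]),
        paternal_slope=float(pat.params[1]),
        maternal_intercept=float(mat.params[0]),
        maternal_slope=float(mat.params[1]),
        joint_intercept=float(joint.params.iloc[0]),
        joint_maternal_slope=float(joint.params.iloc[1]),
        joint_paternal_slope=float(joint.params.iloc[2]),
        diagnostics={
            "paternal_r2_adj": float(pat.rsquared_adj),
            "paternal_p": float(pat.pvalues[1]),
            "maternal_r2_adj": float(mat.rsquared_adj),
            "maternal_p": float(mat.pvalues[1]),
            "joint_p": float(joint.f_pvalue),
        },
    )


def fit_parent_count_regressions(
    upscaled: pd.DataFrame, link: str = "identity"
) -> ParentAgeModel:
    """Fit the two per-parent count-on-age regressions independently.

    ``upscaled`` needs columns (maternal_count, paternal_count,
    age_maternal, age_paternal).  ``link='identity'`` fits least squares;
    ``link='log'`` fits a Poisson GLM with log link.
    """
    if len(upscaled) < 3:
        raise ValueError("need >= 3 trios for count regressions")

    def fit(y, x):
        X = sm.add_constant(np.asarray(x, dtype=float))
        if link == "log":
            return sm.GLM(np.asarray(y, dtype=float), X,
                          family=sm.families.Poisson()).fit()
        return sm.OLS(np.asarray(y, dtype=float), X).fit()

    mat = fit(upscaled["maternal_count"], upscaled["age_maternal"])
    pat = fit(upscaled["paternal_count"], upscaled["age_paternal"])
    mat_ci = np.asarray(mat.conf_int())
    pat_ci = np.asarray(pat.conf_int())
    return ParentAgeModel(
        maternal_intercept=float(mat.params[0]),
        maternal_slope=float(mat.params[1]),
        paternal_intercept=float(pat.params[0]),
        paternal_slope=float(pat.params[1]),
        link=link,
        maternal_ci=(tuple(mat_ci[0]), tuple(mat_ci[1])),
        paternal_ci=(tuple(pat_ci[0]), tuple(pat_ci[1])),
        maternal_result=mat,
        paternal_result=pat,
    )


def predict_counts(
    model: ParentAgeModel, age_maternal: float, age_paternal: float
) -> tuple[float, float, float]:
    """Predicted (maternal, paternal, paternal:maternal ratio) at given ages."""
    maternal = model.predict_maternal(age_maternal)
    paternal = model.predict_paternal(age_paternal)
    if maternal < 0 or paternal < 0:
        raise ValueError(
            f"negative predicted count at ages ({age_maternal}, {age_paternal})"
        )
    ratio = paternal / maternal if maternal > 0 else float("inf")
    return maternal, paternal, ratio


@dataclass
class TransmissionResult:
    n_transmitted: int
    n_sites: int
    fraction: float
    p_value: float


def transmission_test(n_transmitted: int, n_sites: int) -> TransmissionResult:
    """Exact two-sided binomial test of gen-2 inheritance against 50%."""
    if n_sites <= 0:
        raise ValueError("no de novo sites genotyped in the second generation")
    result = stats.binomtest(n_transmitted, n_sites, 0.5, alternative="two-sided")
    return TransmissionResult(
        n_transmitted=n_transmitted,
        n_sites=n_sites,
        fraction=n_transmitted / n_sites,
        p_value=float(result.pvalue),
    )


def upscaled_table(
    mutations: pd.DataFrame,
    pedigree: Pedigree,
    phase_denominators: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-trio upscaled per-parent counts with ages, for the regressions.

    Trios with zero phased mutations are excluded (flagged via absence).
    """
    rows = []
    for trio in pedigree.trios:
        sub = mutations[mutations["trio"] == trio.id]
        m = len(sub)
        phased_p = int((sub["origin"] == ORIGIN_PATERNAL).sum())
        phased_m = int((sub["origin"] == ORIGIN_MATERNAL).sum())
        if phased_p + phased_m == 0:
            continue
        denom_p = denom_m = None
        if phase_denominators is not None:
            row = phase_denominators[phase_denominators["trio"] == trio.id]
            if not row.empty:
                denom_p = float(row["paternal"].iloc[0])
                denom_m = float(row["maternal"].iloc[0])
        pat, mat = upscale_phased(m, phased_p, phased_m, denom_p, denom_m)
        rows.append(
            {
                "trio": trio.id,
                "m": m,
                "phased_paternal": phased_p,
                "phased_maternal": phased_m,
                "paternal_count": pat,
                "maternal_count": mat,
                "age_maternal": trio.age_maternal,
                "age_paternal": trio.age_paternal,
            }
        )
    return pd.DataFrame(rows)
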