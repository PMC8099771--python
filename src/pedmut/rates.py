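"""Callability, false-negative rate, and the corrected per-generation rate.

The per-trio rate is

    mu = m * (1 - beta) / ((1 - alpha) * 2 * C)

with m the surviving candidate count, beta the false-positive rate from
manual curation, alpha the false-negative rate of the allelic-balance and
variant-site filters, and C the number of callable sites (both parents
HomRef, all three individuals passing the depth and genotype-quality
filters).  The allelic-balance and variant-site filters do not enter C;
their loss is carried by alpha instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import (
    FilterConfig,
    allelic_balance_pass,
    depth_pass,
    gq_pass,
    run_funnel,
)
from .records import Genotype, Pedigree
from .sites import CHILD, FATHER, MOTHER, TrioSites


@dataclass
class CallabilityResult:
    """Callable-site count for one trio."""

    trio_id: str
    callable_sites: int
    genome_length: int

    @property
    def genome_fraction(self) -> float:
        return self.callable_sites / self.genome_length if self.genome_length else 0.0


@dataclass
class FNEstimate:
    """False-negative rate split into allelic-balance and site-filter parts.

    The two filters act on disjoint evidence (read support of the offspring
    vs site-level mapping statistics), so the total is composed as
    independent losses: alpha = 1 - (1 - alpha_ab) * (1 - alpha_site).
    """

    alpha_ab: float
    alpha_site: float
    n_transmission_sites: int

    @property
    def alpha_total(self) -> float:
        return 1.0 - (1.0 - self.alpha_ab) * (1.0 - self.alpha_site)


@dataclass
class TrioRateEstimate:
    trio_id: str
    m: float
    beta: float
    alpha: float
    callable_sites: float
    mu: float


@dataclass
class AggregateRate:
    """Across-trio mean rate with a t-based 95% confidence interval."""

    mean: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    per_trio: pd.DataFrame

    @property
    def ci_available(self) -> bool:
        return self.ci_low is not None


def compute_callability(
    ts: TrioSites, f: Optional[FilterConfig] = None, mean_depth: Optional[float] = None
) -> CallabilityResult:
    """Count sites where a de novo mutation could have been called.

    Both parents HomRef and all three individuals within the depth bounds
    and at or above the GQ threshold.  Multi-allelic sites are excluded;
    the allelic-balance and variant-site annotation filters are not applied
    here (their loss enters via alpha).
    """
    f = f or FilterConfig()
    if mean_depth is None:
        mean_depth = float(ts.mean_depths().mean())
    parents_homref = (ts.gt[:, FATHER] == Genotype.HOM_REF) & (
        ts.gt[:, MOTHER] == Genotype.HOM_REF
    )
    ok = (
        parents_homref
        & ~ts.multiallelic_mask()
        & depth_pass(ts.dp, mean_depth, f)
        & gq_pass(ts.gq, f)
    )
    return CallabilityResult(
        trio_id=ts.trio_id, callable_sites=int(ok.sum()), genome_length=ts.n_sites
    )


class InsufficientSitesError(ValueError):
    """Too few heterozygous transmission sites to estimate alpha."""


def estimate_alpha(
    trio_sites: Iterable[TrioSites],
    f: Optional[FilterConfig] = None,
    min_sites: int = 50,
) -> FNEstimate:
    """Estimate the false-negative rate, pooled across trios.

    ``alpha_ab``: fraction of true heterozygote transmission sites (one
    parent HomRef, the other HomAlt, offspring Het) whose offspring allelic
    balance falls outside the filter bounds.  ``alpha_site``: tail mass of
    normal distributions fitted to FS, MQRankSum, and ReadPosRankSum at
    those same well-supported sites, beyond the hard-filter thresholds
    (upper tail for FS, both tails for the rank sums), composed as
    independent losses.
    """
    f = f or FilterConfig()
    ab_fail = 0
    ab_total = 0
    fs_vals: list[np.ndarray] = []
    mqrs_vals: list[np.ndarray] = []
    rprs_vals: list[np.ndarray] = []
    for ts in trio_sites:
        gf, gm, gc = ts.gt[:, FATHER], ts.gt[:, MOTHER], ts.gt[:, CHILD]
        trans = (
            ((gf == Genotype.HOM_REF) & (gm == Genotype.HOM_ALT))
            | ((gf == Genotype.HOM_ALT) & (gm == Genotype.HOM_REF))
        ) & (gc == Genotype.HET)
        trans &= ~ts.multiallelic_mask()
        idx = np.flatnonzero(trans)
        if idx.size == 0:
            continue
        ab_ok = allelic_balance_pass(ts.ad_alt[idx, CHILD], ts.dp[idx, CHILD], f)
        ab_total += idx.size
        ab_fail += int(idx.size - ab_ok.sum())
        fs_vals.append(ts.ann[idx, 1])
        mqrs_vals.append(ts.ann[idx, 3])
        rprs_vals.append(ts.ann[idx, 4])

    if ab_total < min_sites:
        raise InsufficientSitesError(
            f"insufficient transmission sites ({ab_total} < {min_sites})"
        )
    alpha_ab = ab_fail / ab_total

    def tail(values: list[np.ndarray], lo: Optional[float], hi: Optional[float]) -> float:
        x = np.concatenate(values) if values else np.array([])
        x = x[~np.isnan(x)]
        if x.size < 2 or np.std(x) == 0:
            return 0.0
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        mass = 0.0
        if lo is not None:
            mass += stats.norm.cdf(lo, mean, sd)
        if hi is not None:
            mass += stats.norm.sf(hi, mean, sd)
        return float(mass)

    tails = [
        tail(fs_vals, None, f.fs_max),
        tail(mqrs_vals, f.mqrs_min, f.mqrs_max),
        tail(rprs_vals, f.rprs_min, f.rprs_max),
    ]
    alpha_site = 1.0 - math.prod(1.0 - t for t in tails)
    return FNEstimate(alpha_ab=alpha_ab, alpha_site=alpha_site, n_transmission_sites=ab_total)


def estimate_rate(m: float, beta: float, alpha: float, callable_sites: float) -> float:
    """Per-site per-generation mutation rate: m(1-beta) / ((1-alpha) * 2 * C)."""
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if not 0.0 <= beta < 1.0:
        raise ValueError(f"beta must be in [0, 1), got {beta}")
    if m < 0:
        raise ValueError("mutation count m must be non-negative")
    return m * (1.0 - beta) / ((1.0 - alpha) * 2.0 * callable_sites)


def aggregate_rates(estimates: Sequence[TrioRateEstimate]) -> AggregateRate:
    """Across-trio mean with a symmetric t-based 95% CI.

    With a single trio the mean is returned and the CI flagged unavailable.
    """
    if not estimates:
        raise ValueError("no trio estimates")
    mus = np.array([e.mu for e in estimates], dtype=float)
    per_trio = pd.DataFrame(
        {
            "trio": [e.trio_id for e in estimates],
            "m": [e.m for e in estimates],
            "beta": [e.beta for e in estimates],
            "alpha": [e.alpha for e in estimates],
            "callable_sites": [e.callable_sites for e in estimates],
            "mu": mus,
        }
    )
    mean = float(mus.mean())
    if len(mus) < 2 or np.all(mus == mus[0]):
        if len(mus) >= 2:
            return AggregateRate(mean=mean, ci_low=mean, ci_high=mean, per_trio=per_trio)
        return AggregateRate(mean=mean, ci_low=None, ci_high=None, per_trio=per_trio)
    se = float(mus.std(ddof=1) / math.sqrt(len(mus)))
    tq = float(stats.t.ppf(0.975, len(mus) - 1))
    return AggregateRate(
        mean=mean, ci_low=mean - tq * se, ci_high=mean + tq * se, per_trio=per_trio
    )


def estimate_cohort(
    trio_sites: Mapping[str, TrioSites],
    pedigree: Pedigree,
    beta: float = 0.1089,
    f: Optional[FilterConfig] = None,
    min_transmission_sites: int = 50,
) -> tuple[AggregateRate, pd.DataFrame, FNEstimate]:
    """Full pipeline on a cohort: funnel, callability, alpha, per-trio rates.

    Returns the aggregate rate, the surviving candidate table, and the
    pooled false-negative estimate.
    """
    f = f or FilterConfig()
    candidates, _report = run_funnel(trio_sites, pedigree, f)
    fn = estimate_alpha(trio_sites.values(), f, min_sites=min_transmission_sites)
    counts = candidates.groupby("trio").size() if not candidates.empty else {}
    estimates = []
    for trio_id, ts in trio_sites.items():
        m = int(counts.get(trio_id, 0)) if len(counts) else 0
        call = compute_callability(ts, f)
        mu = estimate_rate(m, beta, fn.alpha_total, call.callable_sites)
        estimates.append(
            TrioRateEstimate(
                trio_id=trio_id,
                m=m,
                beta=beta,
                alpha=fn.alpha_total,
                callable_sites=call.callable_sites,
                mu=mu,
            )
        )
    return aggregate_rates(estimates), candidates, fn
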