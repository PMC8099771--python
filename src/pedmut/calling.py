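"""De novo mutation candidate funnel.

Candidates are Mendelian violations where both parents are homozygous
reference and the offspring heterozygous, passed through four filters in
order: (a) hard site-annotation thresholds, (b) offspring allelic balance
within 30-70%, (c) depth of all three individuals within [0.5, 2] x the
trio's mean depth, (d) genotype quality >= 60 in all three individuals.
Sites carried by unrelated offspring are removed at the end.

Threshold comparisons are strict as printed (QD < 2.0 fails, QD = 2.0
passes); the allelic-balance bounds are inclusive.  A missing annotation
passes its filter: rank-sum annotations are undefined at sites where one
allele is absent, so absence carries no evidence against the site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import Genotype, Pedigree, SiteRecord, Trio
from .sites import CHILD, FATHER, MOTHER, TrioSites

#: Funnel stage names, in order.
FUNNEL_STAGES = (
    "snvs",
    "potential_mv",
    "mv_homref_het",
    "site_pass",
    "ab_pass",
    "depth_pass",
    "gq_pass",
    "cross_family_pass",
)


@dataclass(frozen=True)
class FilterConfig:
    """Hard filter thresholds (defaults as used for the rhesus trios)."""

    qd_min: float = 2.0
    fs_max: float = 20.0
    mq_min: float = 40.0
    mqrs_min: float = -2.0
    mqrs_max: float = 4.0
    rprs_min: float = -3.0
    rprs_max: float = 3.0
    sor_max: float = 3.0
    ab_min: float = 0.30
    ab_max: float = 0.70
    depth_low_mult: float = 0.5
    depth_high_mult: float = 2.0
    gq_min: int = 60

    def __post_init__(self) -> None:
        if not self.ab_min < self.ab_max:
            raise ValueError("ab_min must be < ab_max")
        if not self.depth_low_mult < self.depth_high_mult:
            raise ValueError("depth_low_mult must be < depth_high_mult")


@dataclass
class CandidateMutation:
    """A per-trio candidate with the funnel stage it reached."""

    record: SiteRecord
    trio_id: str
    stage_reached: str
    reject_reason: Optional[str] = None

    @property
    def passed(self) -> bool:
        return self.reject_reason is None


@dataclass
class FunnelReport:
    """Per-trio candidate counts at each funnel stage (non-increasing)."""

    counts: pd.DataFrame  # index: trio id, columns: FUNNEL_STAGES

    def total(self, stage: str) -> int:
        return int(self.counts[stage].sum())


# ---------------------------------------------------------------------------
# Predicates (numpy ufunc style: work on scalars and arrays alike)
# ---------------------------------------------------------------------------


def site_annotations_pass(
    qd, fs, mq, mqrs, rprs, sor, f: FilterConfig
) -> np.ndarray:
    """Vector verdict of the hard site filters; NaN values pass."""

    def bad(x, lo=None, hi=None):
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape, dtype=bool)
        valid = ~np.isnan(x)
        if lo is not None:
            out |= valid & (x < lo)
        if hi is not None:
            out |= valid & (x > hi)
        return out

    violated = (
        bad(qd, lo=f.qd_min)
        | bad(fs, hi=f.fs_max)
        | bad(mq, lo=f.mq_min)
        | bad(mqrs, lo=f.mqrs_min, hi=f.mqrs_max)
        | bad(rprs, lo=f.rprs_min, hi=f.rprs_max)
        | bad(sor, hi=f.sor_max)
    )
    return ~violated


def apply_site_filters(c: CandidateMutation, f: FilterConfig) -> tuple[bool, list[str]]:
    """Scalar site-filter verdict with the list of violated annotations."""
    r = c.record
    nan = float("nan")
    checks = [
        ("QD", r.qd, f.qd_min, None),
        ("FS", r.fs, None, f.fs_max),
        ("MQ", r.mq, f.mq_min, None),
        ("MQRankSum", r.mq_rank_sum, f.mqrs_min, f.mqrs_max),
        ("ReadPosRankSum", r.read_pos_rank_sum, f.rprs_min, f.rprs_max),
        ("SOR", r.sor, None, f.sor_max),
    ]
    reasons = []
    for name, value, lo, hi in checks:
        if value is None:
            continue
        if (lo is not None and value < lo) or (hi is not None and value > hi):
            reasons.append(name)
    return (len(reasons) == 0, reasons)


def allelic_balance_pass(ad_alt, dp, f: FilterConfig):
    """Inclusive allelic-balance bounds on the offspring; DP=0 fails."""
    ad_alt = np.asarray(ad_alt, dtype=float)
    dp = np.asarray(dp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(dp > 0, ad_alt / np.where(dp > 0, dp, 1), np.nan)
    return (dp > 0) & (ab >= f.ab_min) & (ab <= f.ab_max)


def depth_pass(dp_trio, m_depth: float, f: FilterConfig):
    """All three individuals within [low, high] x mean trio depth (inclusive)."""
    dp_trio = np.asarray(dp_trio, dtype=float)
    lo, hi = f.depth_low_mult * m_depth, f.depth_high_mult * m_depth
    ok = (dp_trio >= lo) & (dp_trio <= hi)
    return ok.all(axis=-1)


def gq_pass(gq_trio, f: FilterConfig):
    gq_trio = np.asarray(gq_trio, dtype=float)
    return (gq_trio >= f.gq_min).all(axis=-1)


# child genotype feasible under Mendelian inheritance, indexed [gt_f, gt_m, gt_c]
_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}
_MENDEL_OK = np.zeros((3, 3, 3), dtype=bool)
for _gf in range(3):
    for _gm in range(3):
        for _a in _ALLELES[_gf]:
            for _b in _ALLELES[_gm]:
                _MENDEL_OK[_gf, _gm, _a + _b] = True


def is_mendelian_violation(gt_father, gt_mother, gt_child):
    """Child genotype impossible given the parents (missing never violates)."""
    gf = np.asarray(gt_father, dtype=np.int64)
    gm = np.asarray(gt_mother, dtype=np.int64)
    gc = np.asarray(gt_child, dtype=np.int64)
    callable_ = (gf >= 0) & (gm >= 0) & (gc >= 0)
    ok = _MENDEL_OK[np.clip(gf, 0, 2), np.clip(gm, 0, 2), np.clip(gc, 0, 2)]
    return callable_ & ~ok


# ---------------------------------------------------------------------------
# Funnel over a TrioSites block
# ---------------------------------------------------------------------------


@dataclass
class TrioFunnelResult:
    trio_id: str
    counts: dict[str, int]
    candidates: pd.DataFrame  # survivors before cross-family removal
    mean_depth: float


def funnel_trio(
    ts: TrioSites, f: FilterConfig, mean_depth: Optional[float] = None
) -> TrioFunnelResult:
    """Run stages (a)-(d) over one trio's sites, vectorized.

    ``mean_depth`` is the trio's genome-wide mean depth (mean of the three
    individuals' means); computed from the data when not supplied.
    """
    if mean_depth is None:
        mean_depth = float(ts.mean_depths().mean())

    snv = ts.is_variant & ~ts.multiallelic_mask()
    gf, gm, gc = ts.gt[:, FATHER], ts.gt[:, MOTHER], ts.gt[:, CHILD]
    potential_mv = snv & is_mendelian_violation(gf, gm, gc)
    mv = snv & (gf == Genotype.HOM_REF) & (gm == Genotype.HOM_REF) & (gc == Genotype.HET)
    site_ok = mv & site_annotations_pass(
        ts.ann[:, 0], ts.ann[:, 1], ts.ann[:, 2], ts.ann[:, 3], ts.ann[:, 4], ts.ann[:, 5], f
    )
    ab_ok = site_ok & allelic_balance_pass(ts.ad_alt[:, CHILD], ts.dp[:, CHILD], f)
    depth_ok = ab_ok & depth_pass(ts.dp, mean_depth, f)
    gq_ok = depth_ok & gq_pass(ts.gq, f)

    idx = np.flatnonzero(gq_ok)
    codes = "ACGT"
    candidates = pd.DataFrame(
        {
            "chrom": ts.chrom,
            "pos": idx + 1,
            "ref": [codes[b] for b in ts.ref[idx]],
            "alt": [codes[b] for b in ts.alt[idx]],
            "trio": ts.trio_id,
            "child": ts.samples[CHILD],
            "ad_alt": ts.ad_alt[idx, CHILD],
            "dp": ts.dp[idx, CHILD],
        }
    )
    counts = {
        "snvs": int(snv.sum()),
        "potential_mv": int(potential_mv.sum()),
        "mv_homref_het": int(mv.sum()),
        "site_pass": int(site_ok.sum()),
        "ab_pass": int(ab_ok.sum()),
        "depth_pass": int(depth_ok.sum()),
        "gq_pass": int(gq_ok.sum()),
    }
    return TrioFunnelResult(ts.trio_id, counts, candidates, mean_depth)


def select_mendelian_violations(
    records: Iterable[SiteRecord], trio: Trio
) -> Iterable[CandidateMutation]:
    """Stream candidates where parents are HomRef and the offspring Het.

    Records with a missing genotype in any member are skipped (tallied by
    :func:`run_funnel`, not raised).
    """
    for rec in records:
        if not rec.is_snv:
            continue
        try:
            gf = rec.calls[trio.father].gt
            gm = rec.calls[trio.mother].gt
            gc = rec.calls[trio.child].gt
        except KeyError:
            continue
        if gf == Genotype.HOM_REF and gm == Genotype.HOM_REF and gc == Genotype.HET:
            yield CandidateMutation(record=rec, trio_id=trio.id, stage_reached="mv_homref_het")


def remove_cross_family_shared(
    candidates: pd.DataFrame, pedigree: Pedigree
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop sites shared by offspring with no common parent.

    A site carried by two or more offspring among whom any pair shares no
    parent is removed for all carriers; sibling-/half-sibling-shared sites
    are retained.  Returns (kept, removed).
    """
    if candidates.empty:
        return candidates, candidates.iloc[0:0]
    removed_idx: list[int] = []
    for _, group in candidates.groupby(["chrom", "pos", "alt"], sort=False):
        children = group["child"].unique().tolist()
        if len(children) < 2:
            continue
        unrelated = any(
            not pedigree.share_parent(a, b)
            for i, a in enumerate(children)
            for b in children[i + 1 :]
        )
        if unrelated:
            removed_idx.extend(group.index.tolist())
    removed = candidates.loc[removed_idx]
    kept = candidates.drop(index=removed_idx).reset_index(drop=True)
    return kept, removed


def run_funnel(
    trio_sites: Mapping[str, TrioSites] | Sequence[TrioSites],
    pedigree: Pedigree,
    f: Optional[FilterConfig] = None,
    mean_depths: Optional[Mapping[str, float]] = None,
) -> tuple[pd.DataFrame, FunnelReport]:
    """Run the full funnel for a cohort of trios.

    Returns the surviving candidate table (one row per mutation per trio)
    and the per-trio :class:`FunnelReport` whose stage counts are
    non-increasing left to right.
    """
    f = f or FilterConfig()
    if isinstance(trio_sites, Mapping):
        blocks = list(trio_sites.values())
    else:
        blocks = list(trio_sites)

    rows = {}
    all_candidates = []
    for ts in blocks:
        md = mean_depths.get(ts.trio_id) if mean_depths else None
        res = funnel_trio(ts, f, md)
        rows[ts.trio_id] = res.counts
        all_candidates.append(res.candidates)
    candidates = (
        pd.concat(all_candidates, ignore_index=True)
        if all_candidates
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "trio", "child"])
    )
    kept, _removed = remove_cross_family_shared(candidates, pedigree)
    survivors_per_trio = kept.groupby("trio").size() if not kept.empty else pd.Series(dtype=int)
    report = pd.DataFrame.from_dict(rows, orient="index")
    report["cross_family_pass"] = [
        int(survivors_per_trio.get(tid, 0)) for tid in report.index
    ]
    report = report[list(FUNNEL_STAGES)]
    report.index.name = "trio"
    return kept, FunnelReport(counts=report)
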