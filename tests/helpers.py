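"""Independent oracles shared by the unit and acceptance tests."""

from __future__ import annotations

import numpy as np

from pedmut.calling import FilterConfig
from pedmut.sites import CHILD, FATHER, MOTHER, TrioSites


def brute_force_funnel(ts: TrioSites, f: FilterConfig) -> list[int]:
    """Per-site reimplementation of the candidate funnel, straight from the
    printed filter definitions; returns surviving 1-based positions."""
    m_depth = float(ts.dp.mean(axis=0).mean())
    survivors = []
    for i in range(ts.n_sites):
        if ts.alt[i] == 255:
            continue
        if ts.gt[i, FATHER] != 0 or ts.gt[i, MOTHER] != 0 or ts.gt[i, CHILD] != 1:
            continue
        qd, fs, mq, mqrs, rprs, sor = ts.ann[i]
        if not np.isnan(qd) and qd < f.qd_min:
            continue
        if not np.isnan(fs) and fs > f.fs_max:
            continue
        if not np.isnan(mq) and mq < f.mq_min:
            continue
        if not np.isnan(mqrs) and (mqrs < f.mqrs_min or mqrs > f.mqrs_max):
            continue
        if not np.isnan(rprs) and (rprs < f.rprs_min or rprs > f.rprs_max):
            continue
        if not np.isnan(sor) and sor > f.sor_max:
            continue
        dp_c = ts.dp[i, CHILD]
        if dp_c == 0:
            continue
        ab = ts.ad_alt[i, CHILD] / dp_c
        if ab < f.ab_min or ab > f.ab_max:
            continue
        if any(
            ts.dp[i, j] < f.depth_low_mult * m_depth
            or ts.dp[i, j] > f.depth_high_mult * m_depth
            for j in range(3)
        ):
            continue
        if any(ts.gq[i, j] < f.gq_min for j in range(3)):
            continue
        survivors.append(i + 1)
    return survivors
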