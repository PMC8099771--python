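"""Synthetic pedigree sequencing data with known ground truth.

The generator emulates a high-coverage (76x) trio-sequencing experiment at
the genotype-record level: per-site depth drawn negative-binomially around
each individual's mean, genotype qualities from a phred-scaled binomial read
model with additive noise, background heterozygous variants for
false-negative estimation and phasing, true germline de novo mutations with
Poisson counts whose means increase linearly with parental age, spurious
Mendelian violations with skewed allele fractions (mode near 0.2, the
signature of somatic/sequencing artefacts), CpG-enriched transition spectra,
clustered mutations within 20 kb, and postzygotic mutations shared between
siblings with low-fraction mosaic reads in the common parent.

Every planted event is recorded in a truth table, so the downstream calling,
rate, phasing, and characterization stages can be tested against a known
answer without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import Genotype, Pedigree, Trio
from .sites import CHILD, FATHER, MOTHER, NO_ALT, TrioSites

_CODES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

#: Annotation sampling means/sds for well-behaved variant sites, in
#: (qd, fs, mq, mq_rank_sum, read_pos_rank_sum, sor) order.
GOOD_ANN_MEAN = (25.0, 2.0, 60.0, 0.0, 0.0, 1.0)
GOOD_ANN_SD = (5.0, 2.0, 1.5, 1.0, 1.0, 0.4)
#: Error sites draw from shifted distributions (worse FS/SOR, noisier ranks).
ERROR_ANN_MEAN = (12.0, 10.0, 55.0, 0.0, 0.0, 2.0)
ERROR_ANN_SD = (6.0, 8.0, 5.0, 2.5, 2.5, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults reproduce the design of the rhesus macaque trio study this
    package models: 76x mean coverage, nucleotide diversity 0.00247 as the
    background heterozygosity, linear parental-age mutation-count model with
    intercepts/slopes (maternal 4.6497 + 0.3042/yr, paternal 4.8399 +
    1.8364/yr), transition fraction matching ti/tv = 2.08, 32.1% of
    transitions at CpG sites, ~3.5% of mutations in 20 kb clusters and ~3.5%
    shared between siblings, error allele fractions peaked near 0.2, and
    half of mutations carrying a phase-informative read pair.
    """

    genome_length: int = 1_000_000
    chrom: str = "chr1"
    gc_content: float = 0.41
    mean_depth: float = 76.0
    depth_sd_between: float = 5.0  # spread of per-individual mean depths
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    heterozygosity: float = 0.00247
    # linear age model for per-parent germline mutation counts
    maternal_intercept: float = 4.6497
    maternal_slope: float = 0.3042
    paternal_intercept: float = 4.8399
    paternal_slope: float = 1.8364
    count_link: str = "identity"  # or "log": mean = exp(a + b * age)
    count_scale: float = 1.0  # scales expected counts (genome scaling)
    error_mv_rate: float = 4e-6  # spurious Mendelian violations per site
    error_ab_alpha: float = 2.0  # Beta shape: error allele fraction, mean 0.2
    error_ab_beta: float = 8.0
    mosaic_sharing_rate: float = 0.035  # fraction of germline DNMs planted shared
    mosaic_max_fraction: float = 0.05
    transition_fraction: float = 0.675  # ti/tv ~ 2.08
    cpg_fraction_of_transitions: float = 0.321
    cluster_fraction: float = 0.035
    cluster_window: int = 20_000
    phase_informative_rate: float = 0.5
    phase_window: int = 230  # mean sequencing insert size
    gq_per_read: float = 3.0  # ~10*log10(2*(1-e)) per concordant read
    gq_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "heterozygosity",
            "error_mv_rate",
            "mosaic_sharing_rate",
            "transition_fraction",
            "cpg_fraction_of_transitions",
            "cluster_fraction",
            "phase_informative_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def expected_counts(self, trio: Trio) -> tuple[float, float]:
        """Expected (maternal, paternal) germline mutation counts for a trio."""
        lam_m = self.maternal_intercept + self.maternal_slope * trio.age_maternal
        lam_p = self.paternal_intercept + self.paternal_slope * trio.age_paternal
        if self.count_link == "log":
            lam_m, lam_p = np.exp(lam_m), np.exp(lam_p)
        return self.count_scale * lam_m, self.count_scale * lam_p


@dataclass
class SimulatedCohort:
    """Simulator output: reference, per-trio site blocks, and ground truth."""

    config: SimulationConfig
    pedigree: Pedigree
    reference: np.ndarray  # uint8 base codes
    trios: dict[str, TrioSites]
    truth: pd.DataFrame
    informants: pd.DataFrame

    def reference_str(self) -> str:
        return "".join(_CODES[b] for b in self.reference)

    def parent_allele_fraction(self, trio_id: str, pos: int) -> Optional[float]:
        """Common-parent alternative-read fraction at a site (for mosaic checks)."""
        ts = self.trios[trio_id]
        i = pos - 1
        fractions = {}
        for col, sample in ((FATHER, ts.samples[FATHER]), (MOTHER, ts.samples[MOTHER])):
            dp = int(ts.dp[i, col])
            fractions[sample] = ts.ad_alt[i, col] / dp if dp > 0 else 0.0
        return fractions


def simulate_reference(length: int, gc_content: float, seed: int) -> np.ndarray:
    """IID base sequence with the requested GC content (uint8 codes into ACGT)."""
    if length < 2:
        raise ValueError("reference length must be >= 2")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be within [0, 1]")
    rng = np.random.default_rng(seed)
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    return rng.choice(
        np.arange(4, dtype=np.uint8), size=length, p=[p_at, p_gc, p_gc, p_at]
    )


def _sample_distinct(
    rng: np.random.Generator, n: int, k: int, exclude: set[int]
) -> np.ndarray:
    """k distinct 0-based positions in [0, n) avoiding ``exclude``."""
    if k == 0:
        return np.array([], dtype=np.int64)
    if k > n - len(exclude):
        raise ValueError(f"cannot place {k} events on {n - len(exclude)} free sites")
    chosen: list[int] = []
    taken = set(exclude)
    while len(chosen) < k:
        draw = rng.integers(0, n, size=2 * (k - len(chosen)) + 8)
        for p in draw:
            p = int(p)
            if p not in taken:
                taken.add(p)
                chosen.append(p)
                if len(chosen) == k:
                    break
    return np.array(chosen, dtype=np.int64)


def _transition_of(code: int) -> int:
    # A<->G, C<->T
    return {0: 2, 2: 0, 1: 3, 3: 1}[code]


def _transversions_of(code: int) -> tuple[int, int]:
    return {0: (1, 3), 2: (1, 3), 1: (0, 2), 3: (0, 2)}[code]


def _draw_annotations(rng: np.random.Generator, k: int, error: bool) -> np.ndarray:
    mean = ERROR_ANN_MEAN if error else GOOD_ANN_MEAN
    sd = ERROR_ANN_SD if error else GOOD_ANN_SD
    ann = rng.normal(mean, sd, size=(k, 6)).astype(np.float32)
    ann[:, 0] = np.clip(ann[:, 0], 0.1, None)  # QD
    ann[:, 1] = np.clip(ann[:, 1], 0.0, None)  # FS
    ann[:, 5] = np.clip(ann[:, 5], 0.0, None)  # SOR
    return np.round(ann, 4)


class _TruthBuilder:
    def __init__(self) -> None:
        self.rows: list[dict] = []

    def add(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def frame(self) -> pd.DataFrame:
        columns = [
            "trio",
            "chrom",
            "pos",
            "ref",
            "alt",
            "kind",
            "origin",
            "cpg",
            "cluster_id",
        ]
        if not self.rows:
            return pd.DataFrame(columns=columns)
        return pd.DataFrame(self.rows)[columns]


def simulate_dataset(
    config: SimulationConfig, pedigree: Pedigree
) -> SimulatedCohort:
    """Generate per-trio site blocks plus a complete truth table.

    True de novo sites have both parents HomRef and the offspring Het with
    alternative reads ~ Binomial(DP, 0.5); error sites carry skewed allele
    fractions; shared postzygotic sites appear in >= 2 offspring of one
    parent with the parent's alternative reads capped at the mosaic
    fraction of its depth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    reference = simulate_reference(n, config.gc_content, int(rng.integers(2**31)))

    # CpG positions: C followed by G (forward) or G preceded by C (reverse).
    is_c_next_g = (reference[:-1] == 1) & (reference[1:] == 2)
    cpg_c = np.flatnonzero(is_c_next_g)  # position of the C
    cpg_g = cpg_c + 1  # position of the G
    cpg_pool = np.concatenate([cpg_c, cpg_g])

    # Plan shared postzygotic events at cohort level.
    total_lambda = sum(sum(config.expected_counts(t)) for t in pedigree.trios)
    shared_events = _plan_shared_events(rng, config, pedigree, total_lambda, n)
    shared_positions = {ev["pos0"] for ev in shared_events}

    truth = _TruthBuilder()
    informant_rows: list[dict] = []
    trio_blocks: dict[str, TrioSites] = {}
    cluster_counter = 0

    for trio in pedigree.trios:
        ts = TrioSites.empty(trio.id, trio.members, config.chrom, n)
        ts.ref = reference.copy()

        # per-individual depth and GQ
        mean_depths = np.clip(
            rng.normal(config.mean_depth, config.depth_sd_between, size=3), 10.0, None
        )
        r = config.depth_dispersion
        for j in range(3):
            p = r / (r + mean_depths[j])
            ts.dp[:, j] = rng.negative_binomial(r, p, size=n)
        gq = config.gq_per_read * ts.dp + rng.normal(0.0, config.gq_noise_sd, size=(n, 3))
        ts.gq[:] = np.clip(np.round(gq), 0, 99).astype(np.int16)

        used: set[int] = set(p for p in shared_positions)

        # ---- background heterozygous transmission variants -----------------
        n_bg = int(rng.binomial(n, config.heterozygosity))
        bg_pos = _sample_distinct(rng, n, n_bg, used)
        used.update(int(p) for p in bg_pos)
        if n_bg:
            homalt_parent = rng.integers(0, 2, size=n_bg)  # 0 father, 1 mother
            alt = (reference[bg_pos] + rng.integers(1, 4, size=n_bg)) % 4
            ts.alt[bg_pos] = alt.astype(np.uint8)
            father_alt = homalt_parent == 0
            ts.gt[bg_pos, FATHER] = np.where(father_alt, Genotype.HOM_ALT, Genotype.HOM_REF)
            ts.gt[bg_pos, MOTHER] = np.where(father_alt, Genotype.HOM_REF, Genotype.HOM_ALT)
            ts.gt[bg_pos, CHILD] = int(Genotype.HET)
            dpf, dpm, dpc = (ts.dp[bg_pos, j] for j in (FATHER, MOTHER, CHILD))
            ts.ad_alt[bg_pos, FATHER] = np.where(father_alt, dpf, 0)
            ts.ad_alt[bg_pos, MOTHER] = np.where(father_alt, 0, dpm)
            ts.ad_alt[bg_pos, CHILD] = rng.binomial(dpc, 0.5)
            ts.ann[bg_pos] = _draw_annotations(rng, n_bg, error=False)

        # ---- germline de novo mutations ------------------------------------
        lam_m, lam_p = config.expected_counts(trio)
        n_m = int(rng.poisson(lam_m))
        n_p = int(rng.poisson(lam_p))
        origins = ["maternal"] * n_m + ["paternal"] * n_p
        dnm_rows = _plant_germline(
            ts, rng, config, reference, cpg_pool, used, origins, truth, trio
        )
        cluster_counter = _form_clusters(
            ts, rng, config, reference, used, dnm_rows, truth, trio, cluster_counter
        )
        for row in dnm_rows:
            ts.ann[row["pos0"]] = _draw_annotations(rng, 1, error=False)[0]
            _maybe_informant(rng, config, informant_rows, trio, row)

        # ---- spurious Mendelian violations ----------------------------------
        n_err = int(rng.poisson(config.error_mv_rate * n))
        err_pos = _sample_distinct(rng, n, n_err, used)
        used.update(int(p) for p in err_pos)
        for p in err_pos:
            p = int(p)
            dp_c = int(ts.dp[p, CHILD])
            frac = rng.beta(config.error_ab_alpha, config.error_ab_beta)
            ad = 0 if dp_c == 0 else int(np.clip(rng.binomial(dp_c, frac), 1, dp_c))
            alt = _pick_alt(rng, int(reference[p]))
            ts.alt[p] = alt
            ts.gt[p, CHILD] = Genotype.HET
            ts.ad_alt[p, CHILD] = ad
            truth.add(
                trio=trio.id, chrom=config.chrom, pos=p + 1,
                ref=_CODES[reference[p]], alt=_CODES[alt], kind="error",
                origin="none", cpg=_is_cpg(reference, p, alt), cluster_id=-1,
            )
        if n_err:
            ts.ann[err_pos] = _draw_annotations(rng, n_err, error=True)

        trio_blocks[trio.id] = ts

    # ---- shared postzygotic events (planted after per-trio blocks exist) ----
    for ev in shared_events:
        _plant_shared(trio_blocks, rng, config, pedigree, reference, ev, truth,
                      informant_rows)

    truth_df = truth.frame().sort_values(["trio", "pos"]).reset_index(drop=True)
    inf_df = pd.DataFrame(
        informant_rows,
        columns=["trio", "pos", "informant_pos", "carrier", "same_haplotype"],
    )
    return SimulatedCohort(
        config=config,
        pedigree=pedigree,
        reference=reference,
        trios=trio_blocks,
        truth=truth_df,
        informants=inf_df,
    )


def _pick_alt(rng: np.random.Generator, ref_code: int) -> int:
    choices = [c for c in range(4) if c != ref_code]
    return int(rng.choice(choices))


def _is_cpg(reference: np.ndarray, pos0: int, alt: int) -> bool:
    ref = int(reference[pos0])
    if ref == 1:  # C followed by G
        return pos0 + 1 < len(reference) and reference[pos0 + 1] == 2
    if ref == 2:  # G preceded by C
        return pos0 >= 1 and reference[pos0 - 1] == 1
    return False


def _plant_variant(
    ts: TrioSites,
    rng: np.random.Generator,
    pos0: int,
    reference: np.ndarray,
    gt: tuple[Genotype, Genotype, Genotype],
    alt: Optional[int] = None,
) -> int:
    """Set genotypes and binomial allele depths at one site; returns alt code."""
    if alt is None:
        alt = _pick_alt(rng, int(reference[pos0]))
    ts.alt[pos0] = alt
    for j, g in enumerate(gt):
        ts.gt[pos0, j] = int(g)
        dp = int(ts.dp[pos0, j])
        if g == Genotype.HET:
            ts.ad_alt[pos0, j] = rng.binomial(dp, 0.5) if dp > 0 else 0
        elif g == Genotype.HOM_ALT:
            ts.ad_alt[pos0, j] = dp
        else:
            ts.ad_alt[pos0, j] = 0
    return alt


def _plant_germline(
    ts: TrioSites,
    rng: np.random.Generator,
    config: SimulationConfig,
    reference: np.ndarray,
    cpg_pool: np.ndarray,
    used: set[int],
    origins: Sequence[str],
    truth: _TruthBuilder,
    trio: Trio,
) -> list[dict]:
    """Plant germline DNMs with the configured transition/CpG composition."""
    rows: list[dict] = []
    for origin in origins:
        is_ti = rng.random() < config.transition_fraction
        at_cpg = is_ti and rng.random() < config.cpg_fraction_of_transitions
        pos0 = None
        if at_cpg and len(cpg_pool):
            for _ in range(20):  # CpG pool is dense; a few tries suffice
                cand = int(cpg_pool[rng.integers(0, len(cpg_pool))])
                if cand not in used:
                    pos0 = cand
                    break
        if pos0 is None:
            pos0 = int(_sample_distinct(rng, len(reference), 1, used)[0])
            at_cpg = False
        used.add(pos0)
        ref_code = int(reference[pos0])
        if is_ti:
            alt = _transition_of(ref_code)
        else:
            alt = int(rng.choice(_transversions_of(ref_code)))
        _plant_variant(
            ts, rng, pos0, reference,
            gt=(Genotype.HOM_REF, Genotype.HOM_REF, Genotype.HET), alt=alt,
        )
        row = {
            "trio": trio.id,
            "chrom": ts.chrom,
            "pos": pos0 + 1,
            "pos0": pos0,
            "ref": _CODES[ref_code],
            "alt": _CODES[alt],
            "kind": f"germline_{origin}",
            "origin": origin,
            "cpg": _is_cpg(reference, pos0, alt),
            "cluster_id": -1,
        }
        rows.append(row)
        truth.add(**{k: v for k, v in row.items() if k != "pos0"})
    return rows


def _form_clusters(
    ts: TrioSites,
    rng: np.random.Generator,
    config: SimulationConfig,
    reference: np.ndarray,
    used: set[int],
    dnm_rows: list[dict],
    truth: _TruthBuilder,
    trio: Trio,
    cluster_counter: int,
) -> int:
    """Relocate a fraction of planted DNMs into tight 2-3 mutation clusters."""
    n_clustered = int(round(config.cluster_fraction * len(dnm_rows)))
    if n_clustered < 2:
        return cluster_counter
    indices = list(rng.choice(len(dnm_rows), size=n_clustered, replace=False))
    while len(indices) >= 2:
        size = 3 if (len(indices) >= 3 and rng.random() < 0.2) else 2
        members, indices = indices[:size], indices[size:]
        anchor = int(dnm_rows[members[0]]["pos0"])
        for idx in members[1:]:
            row = dnm_rows[idx]
            old = row["pos0"]
            offset = int(rng.integers(1, config.cluster_window))
            new = min(max(anchor + offset, 0), len(reference) - 1)
            if new in used:
                continue
            # move the planted site
            _clear_site(ts, old)
            used.discard(old)
            used.add(new)
            ref_code = int(reference[new])
            alt = _pick_alt(rng, ref_code)
            _plant_variant(
                ts, rng, new, reference,
                gt=(Genotype.HOM_REF, Genotype.HOM_REF, Genotype.HET), alt=alt,
            )
            row.update(
                pos0=new, pos=new + 1, ref=_CODES[ref_code], alt=_CODES[alt],
                cpg=_is_cpg(reference, new, alt),
            )
        for idx in members:
            dnm_rows[idx]["cluster_id"] = cluster_counter
        cluster_counter += 1
    # rebuild truth rows for this trio's germline mutations
    _refresh_truth(truth, trio, dnm_rows)
    return cluster_counter


def _refresh_truth(truth: _TruthBuilder, trio: Trio, dnm_rows: list[dict]) -> None:
    truth.rows = [
        r for r in truth.rows
        if not (r["trio"] == trio.id and r["kind"].startswith("germline"))
    ]
    for row in dnm_rows:
        truth.add(**{k: v for k, v in row.items() if k != "pos0"})


def _clear_site(ts: TrioSites, pos0: int) -> None:
    ts.alt[pos0] = NO_ALT
    ts.gt[pos0] = int(Genotype.HOM_REF)
    ts.ad_alt[pos0] = 0
    ts.ann[pos0] = np.nan


def _maybe_informant(
    rng: np.random.Generator,
    config: SimulationConfig,
    rows: list[dict],
    trio: Trio,
    dnm_row: dict,
    origin: Optional[str] = None,
) -> None:
    """With the configured probability, emit a phase-informative het record."""
    if rng.random() >= config.phase_informative_rate:
        return
    origin = origin or dnm_row["origin"]
    offset = int(rng.integers(10, max(config.phase_window, 11)))
    sign = -1 if rng.random() < 0.5 else 1
    carrier = "father" if rng.random() < 0.5 else "mother"
    origin_parent = "father" if origin == "paternal" else "mother"
    rows.append(
        {
            "trio": trio.id,
            "pos": dnm_row["pos"],
            "informant_pos": max(1, dnm_row["pos"] + sign * offset),
            "carrier": carrier,
            "same_haplotype": carrier == origin_parent,
        }
    )


def _plan_shared_events(
    rng: np.random.Generator,
    config: SimulationConfig,
    pedigree: Pedigree,
    total_lambda: float,
    n: int,
) -> list[dict]:
    parents_multi = sorted(
        {
            parent
            for trio in pedigree.trios
            for parent in (trio.father, trio.mother)
            if len(pedigree.offspring_of(parent)) >= 2
        }
    )
    if not parents_multi or config.mosaic_sharing_rate == 0:
        return []
    n_events = int(rng.poisson(config.mosaic_sharing_rate * total_lambda / 2.0))
    events = []
    taken: set[int] = set()
    for _ in range(n_events):
        parent = parents_multi[int(rng.integers(0, len(parents_multi)))]
        offspring = pedigree.offspring_of(parent)
        k = 3 if (len(offspring) >= 3 and rng.random() < 0.2) else 2
        carriers = list(rng.choice(offspring, size=k, replace=False))
        pos0 = int(_sample_distinct(rng, n, 1, taken)[0])
        taken.add(pos0)
        events.append(
            {
                "parent": parent,
                "carriers": carriers,
                "pos0": pos0,
                "fraction": float(rng.uniform(0.005, config.mosaic_max_fraction)),
            }
        )
    return events


def _plant_shared(
    trio_blocks: dict[str, TrioSites],
    rng: np.random.Generator,
    config: SimulationConfig,
    pedigree: Pedigree,
    reference: np.ndarray,
    event: dict,
    truth: _TruthBuilder,
    informant_rows: list[dict],
) -> None:
    pos0 = event["pos0"]
    alt = _pick_alt(rng, int(reference[pos0]))
    parent = event["parent"]
    for child in event["carriers"]:
        trio = pedigree.trio_for_child(child)
        ts = trio_blocks[trio.id]
        _plant_variant(
            ts, rng, pos0, reference,
            gt=(Genotype.HOM_REF, Genotype.HOM_REF, Genotype.HET), alt=alt,
        )
        ts.ann[pos0] = _draw_annotations(rng, 1, error=False)[0]
        # mosaic reads in the common parent, capped at the mosaic fraction
        col = FATHER if trio.father == parent else MOTHER
        dp = int(ts.dp[pos0, col])
        cap = max(int(np.floor(config.mosaic_max_fraction * dp)), 1)
        ad = 0 if dp == 0 else int(np.clip(rng.binomial(dp, event["fraction"]), 1, min(cap, dp)))
        ts.ad_alt[pos0, col] = ad
        origin = "paternal" if col == FATHER else "maternal"
        row = {
            "trio": trio.id,
            "chrom": ts.chrom,
            "pos": pos0 + 1,
            "ref": _CODES[reference[pos0]],
            "alt": _CODES[alt],
            "kind": "postzygotic_shared",
            "origin": origin,
            "cpg": _is_cpg(reference, pos0, alt),
            "cluster_id": -1,
        }
        truth.add(**row)
        _maybe_informant(rng, config, informant_rows, trio, row, origin=origin)

    # parent's mosaic reads are visible in every trio it belongs to
    for trio in pedigree.trios:
        if parent not in (trio.father, trio.mother):
            continue
        if trio.child in event["carriers"]:
            continue
        ts = trio_blocks[trio.id]
        col = FATHER if trio.father == parent else MOTHER
        dp = int(ts.dp[pos0, col])
        cap = max(int(np.floor(config.mosaic_max_fraction * dp)), 1)
        ts.ad_alt[pos0, col] = 0 if dp == 0 else int(
            np.clip(rng.binomial(dp, event["fraction"]), 0, min(cap, dp))
        )


def emit_truth(truth: pd.DataFrame, path: str, seed: Optional[int] = None) -> None:
    """Write the truth table as TSV (one row per planted event per trio)."""
    from .io import write_table

    provenance = {"seed": seed} if seed is not None else None
    write_table(truth, path, provenance=provenance)
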