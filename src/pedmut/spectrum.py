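"""Mutation characterization: spectrum, CpG status, clusters, sharing, CDS.

Substitutions are collapsed onto the pyrimidine/adenine strand into the six
standard classes (e.g. "C>T/G>A"); a CpG site is a mutated C immediately
followed by G, or a mutated G immediately preceded by C.  Clusters are
chains of mutations on one chromosome whose successive gaps stay within a
20 kb window; a tiled fixed-window mode is available as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import Pedigree

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: The six strand-collapsed substitution classes.
CLASSES = ("A>C/T>G", "A>G/T>C", "A>T/T>A", "C>A/G>T", "C>G/G>C", "C>T/G>A")


@dataclass(frozen=True)
class MutationClass:
    label: str  # one of CLASSES
    cpg: bool
    transition: bool


def classify_mutation(ref: str, alt: str, context: str) -> MutationClass:
    """Collapse a substitution with its 3-mer reference context.

    ``context`` is the reference trinucleotide centered on the site.  The
    class is strand-symmetric; CpG status is read from the uncollapsed
    context (C followed by G, or G preceded by C).
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if ref == alt:
        raise ValueError("ref equals alt")
    for base in (ref, alt, *context):
        if base not in _COMPLEMENT:
            raise ValueError(f"non-ACGT base {base!r}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} is not centered on ref {ref!r}")
    cpg = (ref == "C" and context[2] == "G") or (ref == "G" and context[0] == "C")
    if ref in ("G", "T"):
        cref, calt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    else:
        cref, calt = ref, alt
    label = f"{cref}>{calt}/{_COMPLEMENT[cref]}>{_COMPLEMENT[calt]}"
    return MutationClass(label=label, cpg=cpg, transition=(ref, alt) in _TRANSITIONS)


def annotate_classes(mutations: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Add class/cpg/transition columns using a reference sequence for context."""
    out = mutations.copy()
    labels, cpgs, transitions = [], [], []
    for _, row in out.iterrows():
        pos0 = int(row["pos"]) - 1
        left = reference[pos0 - 1] if pos0 >= 1 else "A"
        right = reference[pos0 + 1] if pos0 + 1 < len(reference) else "A"
        mc = classify_mutation(row["ref"], row["alt"], left + row["ref"] + right)
        labels.append(mc.label)
        cpgs.append(mc.cpg)
        transitions.append(mc.transition)
    out["class"] = labels
    out["cpg"] = cpgs
    out["transition"] = transitions
    return out


def spectrum_table(mutations: pd.DataFrame) -> pd.DataFrame:
    """Counts per collapsed class, split by CpG status."""
    table = (
        mutations.groupby(["class", "cpg"]).size().rename("count").reset_index()
    )
    return table


def titv_ratio(mutations: pd.DataFrame) -> float:
    """Transitions / transversions; infinity (with a warning) if no transversions."""
    ti = int(mutations["transition"].sum())
    tv = int((~mutations["transition"]).sum())
    if tv == 0:
        warnings.warn("no transversions observed; ti/tv is infinite")
        return float("inf")
    return ti / tv


@dataclass
class Cluster:
    members: list[int]  # indices into the mutation table
    chrom: str
    span: int
    scope: str  # within-individual | related | unrelated


def _cluster_scope(children: Sequence[str], pedigree: Optional[Pedigree]) -> str:
    unique = list(dict.fromkeys(children))
    if len(unique) == 1:
        return "within-individual"
    if pedigree is None:
        return "unrelated"
    related = all(
        pedigree.share_parent(a, b)
        for i, a in enumerate(unique)
        for b in unique[i + 1 :]
    )
    return "related" if related else "unrelated"


def find_clusters(
    mutations: pd.DataFrame,
    window: int = 20_000,
    pedigree: Optional[Pedigree] = None,
    mode: str = "chain",
) -> tuple[list[Cluster], dict]:
    """Group mutations within 20 kb windows, across all individuals.

    ``mode='chain'`` (default) chains mutations whose successive gaps are
    <= window (order-invariant single linkage); ``mode='tiled'`` counts
    fixed windows [k*window+1, (k+1)*window] holding more than one
    mutation.  Returns clusters of >= 2 mutations and a summary with the
    clustered fraction and the within-individual clustered fraction.
    """
    clusters: list[Cluster] = []
    total = len(mutations)
    for chrom, group in mutations.groupby("chrom"):
        order = group.sort_values("pos")
        idx = order.index.to_numpy()
        pos = order["pos"].to_numpy()
        if mode == "chain":
            breaks = np.flatnonzero(np.diff(pos) > window)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [len(pos)]])
            groups = [(int(s), int(e)) for s, e in zip(starts, ends)]
        elif mode == "tiled":
            bins = (pos - 1) // window
            groups = [
                (int(np.searchsorted(bins, b, "left")), int(np.searchsorted(bins, b, "right")))
                for b in np.unique(bins)
            ]
        else:
            raise ValueError(f"unknown cluster mode {mode!r}")
        for s, e in groups:
            if e - s < 2:
                continue
            members = idx[s:e].tolist()
            children = mutations.loc[members, "child" if "child" in mutations else "trio"]
            clusters.append(
                Cluster(
                    members=members,
                    chrom=chrom,
                    span=int(pos[e - 1] - pos[s]),
                    scope=_cluster_scope(list(children), pedigree),
                )
            )
    clustered = sum(len(c.members) for c in clusters)
    within = sum(len(c.members) for c in clusters if c.scope == "within-individual")
    summary = {
        "n_clusters": len(clusters),
        "n_clustered_mutations": clustered,
        "pct_clustered": 100.0 * clustered / total if total else 0.0,
        "pct_within_individual_clustered": 100.0 * within / total if total else 0.0,
    }
    return clusters, summary


def distance_null_comparison(
    mutations: pd.DataFrame,
    n_sim: int,
    genome_length: int,
    seed: int,
    pedigree: Optional[Pedigree] = None,
    quantiles: Sequence[float] = (0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Observed vs uniform-null distances between successive mutations.

    Successive (position-sorted) mutation pairs are stratified by the
    relationship of the two carriers (within / related / unrelated); the
    null redraws the same number of positions uniformly with the carrier
    labels permuted, ``n_sim`` times, and reports mean quantiles.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    child_col = "child" if "child" in mutations else "trio"

    def strat_distances(pos: np.ndarray, carriers: np.ndarray) -> dict[str, np.ndarray]:
        order = np.argsort(pos)
        pos, carriers = pos[order], carriers[order]
        dists = np.diff(pos)
        strata = {"within": [], "related": [], "unrelated": []}
        for d, a, b in zip(dists, carriers[:-1], carriers[1:]):
            if a == b:
                strata["within"].append(d)
            elif pedigree is not None and pedigree.share_parent(a, b):
                strata["related"].append(d)
            else:
                strata["unrelated"].append(d)
        return {k: np.array(v) for k, v in strata.items()}

    pos_obs = mutations["pos"].to_numpy()
    carriers_obs = mutations[child_col].to_numpy()
    observed = strat_distances(pos_obs, carriers_obs)

    simulated: dict[str, list[np.ndarray]] = {k: [] for k in observed}
    for _ in range(n_sim):
        pos_sim = rng.integers(1, genome_length + 1, size=len(pos_obs))
        carriers_sim = rng.permutation(carriers_obs)
        for k, v in strat_distances(pos_sim, carriers_sim).items():
            simulated[k].append(v)

    rows = []
    for stratum, obs in observed.items():
        if len(obs) < 2:
            continue
        sim_all = [s for s in simulated[stratum] if len(s) >= 1]
        for q in quantiles:
            sim_q = np.mean([np.quantile(s, q) for s in sim_all]) if sim_all else np.nan
            rows.append(
                {
                    "stratum": stratum,
                    "quantile": q,
                    "observed": float(np.quantile(obs, q)),
                    "simulated": float(sim_q),
                }
            )
    if not rows:
        raise ValueError("fewer than 2 mutations in every stratum")
    return pd.DataFrame(rows)


@dataclass
class SharedMutation:
    chrom: str
    pos: int
    ref: str
    alt: str
    carriers: list[str]
    common_parent: Optional[str]
    phasing_consistent: bool
    mosaic_fractions: dict[str, float]
    mosaic_support: bool


def find_shared(
    mutations: pd.DataFrame,
    pedigree: Pedigree,
    parent_allele_fraction: Optional[Callable[[str, int], Mapping[str, float]]] = None,
    mosaic_max: float = 0.05,
) -> tuple[list[SharedMutation], dict]:
    """Mutations recurring in related offspring, with mosaic evidence.

    Groups identical sites across offspring sharing a parent, checks that
    any phased origin points at the common parent, and flags parental
    mosaic support when the common parent's alternative-read fraction lies
    in (0, mosaic_max].  Also runs a Fisher exact test comparing the
    proportion of mutations shared within maternally vs paternally related
    offspring pairs.
    """
    child_col = "child" if "child" in mutations else "trio"
    shared: list[SharedMutation] = []
    shared_keys: set[tuple] = set()
    for key, group in mutations.groupby(["chrom", "pos", "ref", "alt"], sort=False):
        carriers = group[child_col].unique().tolist()
        if len(carriers) < 2:
            continue
        common = pedigree.common_parents(carriers)
        if not common:
            continue
        common_parent = sorted(common)[0]
        side = (
            "paternal"
            if pedigree.sex.get(common_parent) == "M"
            else "maternal"
        )
        consistent = True
        if "origin" in group:
            phased = group[group["origin"].isin(["paternal", "maternal"])]
            consistent = bool((phased["origin"] == side).all())
        fractions: dict[str, float] = {}
        mosaic = False
        if parent_allele_fraction is not None:
            for child in carriers:
                trio = pedigree.trio_for_child(child)
                frac = parent_allele_fraction(trio.id, int(key[1]))
                f = float(frac.get(common_parent, 0.0))
                fractions[trio.id] = f
                if 0.0 < f <= mosaic_max:
                    mosaic = True
        shared.append(
            SharedMutation(
                chrom=key[0], pos=int(key[1]), ref=key[2], alt=key[3],
                carriers=carriers, common_parent=common_parent,
                phasing_consistent=consistent, mosaic_fractions=fractions,
                mosaic_support=mosaic,
            )
        )
        shared_keys.add(key)

    # Fisher test: shared vs unshared mutation counts within maternal-pair
    # and paternal-pair strata.  A pair's denominator is the total number of
    # mutations carried by its two offspring.
    counts = {"maternal": [0, 0], "paternal": [0, 0]}  # [shared, unshared]
    by_child = {c: g for c, g in mutations.groupby(child_col)}
    for a, b, side in pedigree.related_pairs():
        ga = by_child.get(a, mutations.iloc[0:0])
        gb = by_child.get(b, mutations.iloc[0:0])
        keys_a = set(map(tuple, ga[["chrom", "pos", "ref", "alt"]].to_numpy()))
        keys_b = set(map(tuple, gb[["chrom", "pos", "ref", "alt"]].to_numpy()))
        n_shared = 2 * len(keys_a & keys_b)  # both offspring's copies count
        total = len(ga) + len(gb)
        counts[side][0] += n_shared
        counts[side][1] += max(total - n_shared, 0)
    table = np.array([counts["maternal"], counts["paternal"]])
    if table.sum() and table.sum(axis=1).min() > 0:
        _, fisher_p = stats.fisher_exact(table)
    else:
        fisher_p = float("nan")
    n_total = len(mutations)
    n_shared_mut = sum(
        len(g)
        for key, g in mutations.groupby(["chrom", "pos", "ref", "alt"], sort=False)
        if key in shared_keys
    )
    summary = {
        "n_shared_sites": len(shared),
        "n_shared_mutations": n_shared_mut,
        "pct_shared": 100.0 * n_shared_mut / n_total if n_total else 0.0,
        "pair_table": table,
        "fisher_p": float(fisher_p),
    }
    return shared, summary


def cds_overlap(
    mutations: pd.DataFrame, intervals: Iterable[tuple[str, int, int]]
) -> tuple[int, float, np.ndarray]:
    """Count mutations inside CDS intervals (1-based, inclusive ends).

    Returns (count, fraction of all mutations, per-mutation mask).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end < start or start < 1:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    mask = np.zeros(len(mutations), dtype=bool)
    for i, (_, row) in enumerate(mutations.iterrows()):
        for start, end in by_chrom.get(row["chrom"], ()):
            if start <= row["pos"] <= end:
                mask[i] = True
                break
    count = int(mask.sum())
    fraction = count / len(mutations) if len(mutations) else 0.0
    return count, fraction, mask


def read_cds_intervals(gff_path: str) -> list[tuple[str, int, int]]:
    """Extract CDS intervals (1-based inclusive) from a GFF3/GTF file."""
    intervals = []
    table = pd.read_csv(
        gff_path, sep="\t", comment="#", header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
    )
    for _, row in table[table["type"] == "CDS"].iterrows():
        intervals.append((str(row["seqid"]), int(row["start"]), int(row["end"])))
    return intervals
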