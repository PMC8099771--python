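"""Core domain containers: per-site trio genotype records and pedigrees.

A :class:`SiteRecord` is the atom of the pipeline: one genomic position with
per-individual genotype calls (GT/AD/DP/GQ) and the variant-site annotations
used by the hard filters (QD, FS, MQ, MQRankSum, ReadPosRankSum, SOR).
Base-pair-resolution datasets contain a record for every site, variant or not;
non-variant records carry no alternative allele and no variant annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Optional


class Genotype(IntEnum):
    """Diploid biallelic genotype relative to the reference allele."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


#: Variant-site annotation fields, in canonical column order.
ANNOTATION_FIELDS = ("qd", "fs", "mq", "mq_rank_sum", "read_pos_rank_sum", "sor")


@dataclass
class Call:
    """One individual's call at one site."""

    gt: Genotype
    ad_ref: int = 0
    ad_alt: int = 0
    dp: int = 0
    gq: int = 0

    def __post_init__(self) -> None:
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError(
                f"allele depths {self.ad_ref}+{self.ad_alt} exceed DP={self.dp}"
            )
        if self.gq < 0:
            raise ValueError(f"negative GQ {self.gq}")

    @property
    def allele_balance(self) -> Optional[float]:
        """Fraction of reads supporting the alternative allele (None if DP=0)."""
        if self.dp <= 0:
            return None
        return self.ad_alt / self.dp


@dataclass
class SiteRecord:
    """One genomic position with calls for a set of individuals.

    ``alt`` is ``None`` for non-variant (homozygous-reference block) records.
    ``multiallelic`` flags records that carried more than one alternative
    allele in the source file; such sites are excluded from candidacy and
    callability downstream.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: Optional[str]
    calls: dict[str, Call]
    qd: Optional[float] = None
    fs: Optional[float] = None
    mq: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    sor: Optional[float] = None
    multiallelic: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.alt is not None and self.alt == self.ref:
            raise ValueError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_variant(self) -> bool:
        return self.alt is not None

    @property
    def is_snv(self) -> bool:
        return (
            self.alt is not None
            and len(self.ref) == 1
            and len(self.alt) == 1
            and not self.multiallelic
        )

    def annotation(self, name: str) -> Optional[float]:
        return getattr(self, name)


@dataclass(frozen=True)
class Trio:
    """A father/mother/offspring unit with parental ages at conception."""

    father: str
    mother: str
    child: str
    age_paternal: float
    age_maternal: float
    family: str = "FAM"

    def __post_init__(self) -> None:
        if self.age_paternal <= 0 or self.age_maternal <= 0:
            raise ValueError(f"non-positive parental age in trio {self.child}")
        if self.child in (self.father, self.mother):
            raise ValueError(f"offspring {self.child} listed as its own parent")

    @property
    def id(self) -> str:
        # a child appears in exactly one trio, so the child id names the trio
        return self.child

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.father, self.mother, self.child)


@dataclass
class Pedigree:
    """Family structure: individuals with sex, trios with parental ages.

    Invariants: every trio member exists in ``sex``; an individual appears as
    offspring in at most one trio; parental ages are positive.
    """

    sex: dict[str, str]  # 'M' / 'F' / 'U'
    trios: list[Trio] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_children: set[str] = set()
        for trio in self.trios:
            for member in trio.members:
                if member not in self.sex:
                    raise ValueError(f"trio member {member} missing from pedigree")
            if trio.child in seen_children:
                raise ValueError(f"offspring {trio.child} appears in more than one trio")
            seen_children.add(trio.child)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.sex)

    def trio_for_child(self, child: str) -> Optional[Trio]:
        for trio in self.trios:
            if trio.child == child:
                return trio
        return None

    def parents_of(self, child: str) -> Optional[tuple[str, str]]:
        trio = self.trio_for_child(child)
        return (trio.father, trio.mother) if trio else None

    def offspring_of(self, parent: str) -> list[str]:
        return [t.child for t in self.trios if parent in (t.father, t.mother)]

    def share_parent(self, child_a: str, child_b: str) -> bool:
        """True if two offspring have at least one parent in common."""
        pa, pb = self.parents_of(child_a), self.parents_of(child_b)
        if pa is None or pb is None:
            return False
        return bool(set(pa) & set(pb))

    def common_parents(self, children: list[str]) -> set[str]:
        """Parents shared by *all* of the given offspring."""
        shared: Optional[set[str]] = None
        for child in children:
            parents = self.parents_of(child)
            if parents is None:
                return set()
            shared = set(parents) if shared is None else shared & set(parents)
        return shared or set()

    def related_pairs(self) -> Iterator[tuple[str, str, str]]:
        """Yield (child_a, child_b, side) for offspring pairs sharing a parent.

        ``side`` is 'paternal' or 'maternal'; full siblings yield both rows,
        matching the convention of counting maternally and paternally related
        pairs separately.
        """
        children = [t.child for t in self.trios]
        for i, a in enumerate(children):
            ta = self.trio_for_child(a)
            for b in children[i + 1 :]:
                tb = self.trio_for_child(b)
                if ta.father == tb.father:
                    yield (a, b, "paternal")
                if ta.mother == tb.mother:
                    yield (a, b, "maternal")

    def second_generation_links(self) -> list[tuple[Trio, Trio]]:
        """Pairs (gen-1 trio, gen-2 trio) where the gen-1 child is a gen-2 parent."""
        links = []
        for t1 in self.trios:
            for t2 in self.trios:
                if t1.child in (t2.father, t2.mother):
                    links.append((t1, t2))
        return links
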