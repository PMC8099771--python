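"""Columnar per-trio site data.

A :class:`TrioSites` holds one trio's base-pair-resolution calls as numpy
arrays (one row per genomic position, columns father/mother/offspring).  It
is the container the calling and rate-estimation stages operate on; the
record-stream interface in :mod:`pedmut.io` converts to and from it, so the
filter logic exists once, vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .records import ANNOTATION_FIELDS, Call, Genotype, SiteRecord

#: Base encoding used throughout the package (index into "ACGT"; 255 = none).
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_TO_CODE = {b: i for i, b in enumerate("ACGT")}
NO_ALT = 255

#: Column order within per-individual arrays.
FATHER, MOTHER, CHILD = 0, 1, 2


@dataclass
class TrioSites:
    """Dense per-site arrays for one trio over positions 1..n of one contig.

    ``gt`` uses the :class:`~pedmut.records.Genotype` codes (missing = -1);
    ``ref`` and ``alt`` are base codes (``alt`` = 255 at non-variant sites);
    ``ann`` holds the six variant-site annotations (NaN = missing) in
    :data:`~pedmut.records.ANNOTATION_FIELDS` order.
    """

    trio_id: str
    samples: tuple[str, str, str]  # (father, mother, child)
    chrom: str
    ref: np.ndarray  # (n,) uint8 base codes
    gt: np.ndarray  # (n, 3) int8
    ad_alt: np.ndarray  # (n, 3) int32
    dp: np.ndarray  # (n, 3) int32
    gq: np.ndarray  # (n, 3) int16
    alt: np.ndarray  # (n,) uint8 base codes, 255 = no alt
    ann: np.ndarray  # (n, 6) float32, NaN = missing
    multiallelic: Optional[np.ndarray] = None  # (n,) bool

    @property
    def n_sites(self) -> int:
        return len(self.ref)

    @property
    def positions(self) -> np.ndarray:
        """1-based positions."""
        return np.arange(1, self.n_sites + 1, dtype=np.int64)

    @property
    def is_variant(self) -> np.ndarray:
        return self.alt != NO_ALT

    def multiallelic_mask(self) -> np.ndarray:
        if self.multiallelic is None:
            return np.zeros(self.n_sites, dtype=bool)
        return self.multiallelic

    def mean_depths(self) -> np.ndarray:
        """Genome-wide mean depth per individual (father, mother, child)."""
        return self.dp.mean(axis=0)

    @classmethod
    def empty(cls, trio_id: str, samples: Sequence[str], chrom: str, n: int) -> "TrioSites":
        return cls(
            trio_id=trio_id,
            samples=tuple(samples),
            chrom=chrom,
            ref=np.zeros(n, dtype=np.uint8),
            gt=np.zeros((n, 3), dtype=np.int8),
            ad_alt=np.zeros((n, 3), dtype=np.int32),
            dp=np.zeros((n, 3), dtype=np.int32),
            gq=np.zeros((n, 3), dtype=np.int16),
            alt=np.full(n, NO_ALT, dtype=np.uint8),
            ann=np.full((n, 6), np.nan, dtype=np.float32),
        )

    # -- record-stream interface -------------------------------------------

    def to_records(self) -> Iterator[SiteRecord]:
        """Yield one :class:`SiteRecord` per position, in coordinate order."""
        codes = "ACGT"
        for i in range(self.n_sites):
            alt_code = self.alt[i]
            calls = {}
            for j, sid in enumerate(self.samples):
                dp = int(self.dp[i, j])
                ad_alt = int(self.ad_alt[i, j])
                calls[sid] = Call(
                    gt=Genotype(int(self.gt[i, j])),
                    ad_ref=max(dp - ad_alt, 0),
                    ad_alt=ad_alt,
                    dp=dp,
                    gq=int(self.gq[i, j]),
                )
            ann = {
                name: (None if np.isnan(self.ann[i, k]) else round(float(self.ann[i, k]), 4))
                for k, name in enumerate(ANNOTATION_FIELDS)
            }
            yield SiteRecord(
                chrom=self.chrom,
                pos=i + 1,
                ref=codes[self.ref[i]],
                alt=None if alt_code == NO_ALT else codes[alt_code],
                calls=calls,
                multiallelic=bool(self.multiallelic_mask()[i]),
                **ann,
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[SiteRecord],
        trio_id: str,
        samples: Sequence[str],
    ) -> "TrioSites":
        """Build dense arrays from a record stream covering positions 1..n.

        Positions absent from the stream are treated as uncalled (missing
        genotype, zero depth), so they never contribute to candidacy or
        callability.
        """
        records = list(records)
        n = max((r.pos for r in records), default=0)
        ts = cls.empty(trio_id, samples, records[0].chrom if records else "chr1", n)
        ts.gt[:] = int(Genotype.MISSING)
        multi = np.zeros(n, dtype=bool)
        for rec in records:
            i = rec.pos - 1
            ts.ref[i] = BASE_TO_CODE.get(rec.ref[0].upper(), 0)
            if rec.alt is not None and len(rec.alt) == 1 and rec.alt.upper() in BASE_TO_CODE:
                ts.alt[i] = BASE_TO_CODE[rec.alt.upper()]
            multi[i] = rec.multiallelic
            for j, sid in enumerate(samples):
                call = rec.calls[sid]
                ts.gt[i, j] = int(call.gt)
                ts.ad_alt[i, j] = call.ad_alt
                ts.dp[i, j] = call.dp
                ts.gq[i, j] = call.gq
            for k, name in enumerate(ANNOTATION_FIELDS):
                value = rec.annotation(name)
                if value is not None:
                    ts.ann[i, k] = value
        ts.multiallelic = multi
        return ts
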