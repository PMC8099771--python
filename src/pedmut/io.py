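"""Reading and writing the standard formats the pipeline touches.

VCF 4.2 in a base-pair-resolution dialect (non-variant sites appear as
records with ``ALT=.``), PED pedigree files extended with two parental-age
columns, and tab-separated output tables with a provenance comment block.
VCF parsing goes through :mod:`pysam`.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .records import ANNOTATION_FIELDS, Call, Genotype, Pedigree, SiteRecord, Trio

#: VCF INFO keys in the order of :data:`ANNOTATION_FIELDS`.
_INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")


class SiteFileError(ValueError):
    """A VCF file could not be parsed or is inconsistent with the request."""


class PedigreeError(ValueError):
    """A pedigree file violates the pedigree invariants."""


def _genotype_from_tuple(gt: tuple) -> Genotype:
    if gt is None or any(a is None for a in gt) or len(gt) == 0:
        return Genotype.MISSING
    alleles = set(gt)
    if alleles == {0}:
        return Genotype.HOM_REF
    if alleles == {0, 1}:
        return Genotype.HET
    if alleles == {1}:
        return Genotype.HOM_ALT
    # genotype involving a second alternative allele: treat as missing for
    # biallelic analysis (the record is flagged multiallelic anyway)
    return Genotype.MISSING


def read_sites(path: str, sample_ids: Sequence[str]) -> Iterator[SiteRecord]:
    """Stream :class:`SiteRecord` objects from a VCF file.

    Non-variant records (``ALT=.`` or ``<NON_REF>``) yield records with
    ``alt=None``; records with more than one alternative allele are flagged
    ``multiallelic``. Raises :class:`SiteFileError` for a malformed file and
    when a requested sample is absent from the header.
    """
    if not os.path.exists(path):
        raise SiteFileError(f"no such file: {path}")
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:  # malformed header
        raise SiteFileError(f"cannot parse VCF header of {path}: {exc}") from exc
    missing = [s for s in sample_ids if s not in vcf.header.samples]
    if missing:
        raise SiteFileError(f"samples absent from {path}: {', '.join(missing)}")

    for rec in vcf:
        alts = tuple(a for a in (rec.alts or ()) if a != "<NON_REF>")
        multiallelic = len(alts) > 1
        alt = alts[0] if alts else None
        calls: dict[str, Call] = {}
        for sid in sample_ids:
            sample = rec.samples[sid]
            gt = _genotype_from_tuple(sample.get("GT"))
            ad = sample.get("AD")
            dp = sample.get("DP") or 0
            gq = sample.get("GQ")
            ad_ref, ad_alt = 0, 0
            if ad is not None and len(ad) >= 1 and ad[0] is not None:
                ad_ref = ad[0]
                if len(ad) >= 2 and ad[1] is not None:
                    ad_alt = ad[1]
            calls[sid] = Call(
                gt=gt,
                ad_ref=int(ad_ref),
                ad_alt=int(ad_alt),
                dp=int(dp),
                gq=int(gq) if gq is not None else 0,
            )
        # htslib stores INFO floats in single precision; round to the 4-decimal
        # precision the writer emits so round-trips are exact
        info = {
            field: (round(float(rec.info[key]), 4) if key in rec.info else None)
            for field, key in zip(ANNOTATION_FIELDS, _INFO_KEYS)
        }
        yield SiteRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=alt,
            calls=calls,
            multiallelic=multiallelic,
            **info,
        )


def _format_float(x: float) -> str:
    s = f"{x:.4f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-") else "0"


_GT_STRINGS = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_sites(
    records: Iterable[SiteRecord],
    path: str,
    sample_ids: Sequence[str],
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> int:
    """Write site records as a VCF 4.2 file; returns the record count.

    Lossless for every :class:`SiteRecord` field the pipeline consumes
    (annotations are written with four decimals, matching the precision the
    simulator and typical callers emit).
    """
    records = list(records)
    if contig_lengths is None:
        contig_lengths = {}
        for r in records:
            contig_lengths[r.chrom] = max(contig_lengths.get(r.chrom, 0), r.pos)
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    for key in _INFO_KEYS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="{key} site annotation">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header_cols + list(sample_ids)))

    n = 0
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for rec in records:
            info_items = []
            for field, key in zip(ANNOTATION_FIELDS, _INFO_KEYS):
                value = getattr(rec, field)
                if value is not None:
                    info_items.append(f"{key}={_format_float(value)}")
            info = ";".join(info_items) if info_items else "."
            row = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt if rec.alt is not None else ".",
                ".",
                ".",
                info,
                "GT:AD:DP:GQ",
            ]
            for sid in sample_ids:
                call = rec.calls[sid]
                row.append(
                    f"{_GT_STRINGS[call.gt]}:{call.ad_ref},{call.ad_alt}:{call.dp}:{call.gq}"
                )
            fh.write("\t".join(row) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# PED pedigree with parental-age columns
# ---------------------------------------------------------------------------

_PED_COLUMNS = [
    "family",
    "id",
    "father",
    "mother",
    "sex",
    "phenotype",
    "age_paternal",
    "age_maternal",
]

_SEX_CODES = {"1": "M", "2": "F", "0": "U", "M": "M", "F": "F", "U": "U"}


def read_pedigree(path: str) -> Pedigree:
    """Read a PED file (6 standard columns + paternal/maternal age columns).

    Offspring rows (both parents non-zero) must carry positive ages; founder
    rows may use ``.`` or ``0`` in the age columns.
    """
    try:
        table = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=str)
    except Exception as exc:
        raise PedigreeError(f"cannot parse pedigree file {path}: {exc}") from exc
    if table.shape[1] < len(_PED_COLUMNS):
        raise PedigreeError(
            f"{path}: expected {len(_PED_COLUMNS)} columns "
            f"(family id father mother sex phenotype age_paternal age_maternal), "
            f"got {table.shape[1]}"
        )
    table = table.iloc[:, : len(_PED_COLUMNS)]
    table.columns = _PED_COLUMNS

    sex: dict[str, str] = {}
    for _, row in table.iterrows():
        if row["id"] in sex:
            raise PedigreeError(f"duplicate individual id {row['id']}")
        sex[row["id"]] = _SEX_CODES.get(str(row["sex"]), "U")

    trios: list[Trio] = []
    for _, row in table.iterrows():
        father, mother = row["father"], row["mother"]
        if father in ("0", ".") and mother in ("0", "."):
            continue
        if father in ("0", ".") or mother in ("0", "."):
            raise PedigreeError(f"offspring {row['id']} has only one parent listed")
        for parent in (father, mother):
            if parent not in sex:
                raise PedigreeError(f"dangling parent id {parent} for {row['id']}")
        if row["id"] in (father, mother):
            raise PedigreeError(f"offspring {row['id']} listed as its own parent")
        try:
            age_p = float(row["age_paternal"])
            age_m = float(row["age_maternal"])
        except (TypeError, ValueError) as exc:
            raise PedigreeError(f"missing parental age for offspring {row['id']}") from exc
        if age_p <= 0 or age_m <= 0:
            raise PedigreeError(f"non-positive parental age for offspring {row['id']}")
        trios.append(
            Trio(
                father=father,
                mother=mother,
                child=row["id"],
                age_paternal=age_p,
                age_maternal=age_m,
                family=row["family"],
            )
        )
    try:
        return Pedigree(sex=sex, trios=trios)
    except ValueError as exc:
        raise PedigreeError(str(exc)) from exc


def write_pedigree(pedigree: Pedigree, path: str) -> None:
    """Write a pedigree in the extended PED dialect read by :func:`read_pedigree`."""
    sex_codes = {"M": "1", "F": "2", "U": "0"}
    children = {t.child: t for t in pedigree.trios}
    with open(path, "w") as fh:
        fh.write("# " + " ".join(_PED_COLUMNS) + "\n")
        for ind in pedigree.individuals:
            trio = children.get(ind)
            if trio is None:
                fh.write(f"FAM\t{ind}\t0\t0\t{sex_codes[pedigree.sex[ind]]}\t0\t.\t.\n")
            else:
                fh.write(
                    f"{trio.family}\t{ind}\t{trio.father}\t{trio.mother}\t"
                    f"{sex_codes[pedigree.sex[ind]]}\t0\t"
                    f"{trio.age_paternal:g}\t{trio.age_maternal:g}\n"
                )


def write_table(
    table: pd.DataFrame, path: str, provenance: Optional[Mapping[str, object]] = None
) -> None:
    """Write a DataFrame as TSV with ``# key=value`` provenance comment lines."""
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
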