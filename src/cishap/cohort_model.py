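"""Cohort data model and I/O.

Variants, per-proband biallelic genotype records, and structural-variant
junction annotation for a rare-disease cohort at the OCA2 locus. A proband
record carries two allele calls; each call is an ordered *cis* list of
variant ids, so multi-variant haplotype alleles such as ``c.79G>A; c.1320G>C``
are first-class. A packaged transcription of the study cohort table ships
with the module (:func:`load_packaged_cohort`).

Coordinates are 1-based inclusive internally; BED repeat intervals are
converted from their half-open 0-based convention on read.
"""
from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "VariantClass", "Variant", "AlleleCall", "ProbandRecord", "RepeatTrack",
    "VariantTable", "JunctionAnnotation", "normalize_label",
    "read_variant_table", "read_cohort", "write_cohort", "classify_rarity",
    "allele_count", "distinct_variants", "sv_carrier_count",
    "annotate_junctions", "cohort_stats", "load_packaged_cohort",
    "export_vcf", "SV_CLASSES", "RARITY_THRESHOLD",
]

#: default population-MAF threshold separating rare from common alleles
RARITY_THRESHOLD = 0.01


class VariantClass(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift_indel = "frameshift_indel"
    inframe_indel = "inframe_indel"
    splice_region = "splice_region"
    deep_intronic = "deep_intronic"
    sv_deletion = "sv_deletion"
    sv_duplication = "sv_duplication"
    cxsv = "cxsv"
    regulatory_snp = "regulatory_snp"
    synonymous = "synonymous"


#: classes counted as large structural variants
SV_CLASSES = frozenset(
    {VariantClass.sv_deletion, VariantClass.sv_duplication, VariantClass.cxsv}
)


@dataclass(frozen=True)
class Variant:
    """One rare or common allele (SNV, indel, delins, SV or complex SV).

    Attributes
    ----------
    id:
        Normalized label, e.g. ``"c.1327G>A"`` or ``"exon7_del"``. Unique
        within a variant table.
    vclass:
        Functional class of the allele.
    start, end:
        1-based inclusive reference coordinates, ``end >= start``.
    population_maf:
        Minor allele frequency in a reference population, or ``None``.
    anchor:
        True for the common pigmentation-trait GWAS alleles on which rare
        haplotypes are catalogued (rs1800401, rs1800404, rs1800407,
        rs1800414, rs12913832).
    retention_factor:
        Fraction of correctly spliced / expressed transcript retained per
        copy of this allele, in (0, 1]; used by the dosage-expression model.
    """

    id: str
    vclass: VariantClass
    contig: str = "chr15"
    start: int = 0
    end: int = 0
    hgvs_c: Optional[str] = None
    hgvs_g: Optional[str] = None
    hgvs_p: Optional[str] = None
    ref_allele: str = ""
    alt_allele: str = ""
    population_maf: Optional[float] = None
    anchor: bool = False
    retention_factor: Optional[float] = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.id}: end < start")
        if self.anchor:
            if self.population_maf is None or self.population_maf < RARITY_THRESHOLD:
                raise ValueError(
                    f"anchor variant {self.id} requires population_maf >= "
                    f"{RARITY_THRESHOLD}"
                )


@dataclass(frozen=True)
class AlleleCall:
    """Variants asserted in cis on one chromosome.

    Cohort-table calls always carry >= 1 variant; an empty tuple denotes a
    reference chromosome (used by simulated cohorts).
    """

    variants: tuple[str, ...]
    parental_origin: str = "unknown"  # paternal | maternal | unknown

    def __post_init__(self):
        if len(set(self.variants)) != len(self.variants):
            raise ValueError(f"duplicate variant in allele call: {self.variants}")


@dataclass(frozen=True)
class ProbandRecord:
    proband_id: str
    sex: str  # M | F | unknown
    allele1: AlleleCall
    allele2: AlleleCall
    phase_method: str = "not_determined"
    group: str = "two_PLP"

    @property
    def carried(self) -> frozenset[str]:
        """All variant ids this proband carries on either chromosome."""
        return frozenset(self.allele1.variants) | frozenset(self.allele2.variants)


@dataclass
class JunctionAnnotation:
    variant_id: str
    start_in_repeat: bool
    end_in_repeat: bool
    repeat_classes: frozenset[str]


_DASHES = {"‐": "-", "‑": "-", "‒": "-", "–": "-", "−": "-"}


def normalize_label(label: str) -> str:
    """Normalize a variant label as printed in a cohort table.

    Collapses whitespace, maps unicode dashes to ASCII, removes thousands
    separators inside numbers (``c.2433-22,889T>A``) and drops the redundant
    deleted-base suffix (``c.1555delG`` -> ``c.1555del``).
    """
    s = label.strip()
    for u, a in _DASHES.items():
        s = s.replace(u, a)
    s = s.replace(" ", "")
    s = re.sub(r"(?<=\d),(?=\d)", "", s)
    s = re.sub(r"del[ACGT]+$", "del", s)
    return s


class VariantTable:
    """Lookup of :class:`Variant` records by id, HGVS name or alias."""

    def __init__(self, variants: Sequence[Variant], aliases: Mapping[str, str] = ()):
        self.variants: dict[str, Variant] = {}
        self._resolver: dict[str, str] = {}
        for v in variants:
            if v.id in self.variants:
                raise ValueError(f"duplicate variant id {v.id}")
            self.variants[v.id] = v
            for label in (v.id, v.hgvs_c, v.hgvs_g):
                if label:
                    self._resolver.setdefault(normalize_label(label), v.id)
        for alias, vid in dict(aliases).items():
            self._resolver.setdefault(normalize_label(alias), vid)

    def __len__(self):
        return len(self.variants)

    def __contains__(self, vid):
        return vid in self.variants

    def __getitem__(self, vid) -> Variant:
        return self.variants[vid]

    def resolve(self, label: str) -> str:
        """Return the canonical id for a (possibly unnormalized) label."""
        key = normalize_label(label)
        if key not in self._resolver:
            raise KeyError(f"unresolvable variant label: {label!r}")
        return self._resolver[key]

    def anchors(self) -> list[Variant]:
        return [v for v in self.variants.values() if v.anchor]


def read_variant_table(path) -> VariantTable:
    """Read a variant annotation TSV.

    Expected columns: ``id, vclass, contig, start, end`` and optionally
    ``hgvs_c, hgvs_g, hgvs_p, ref_allele, alt_allele, population_maf,
    anchor, retention_factor, aliases`` (aliases comma-separated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    variants, aliases = [], {}
    for _, row in df.iterrows():
        v = Variant(
            id=row["id"],
            vclass=VariantClass(row["vclass"]),
            contig=row.get("contig", "chr15") or "chr15",
            start=int(row["start"]),
            end=int(row["end"]),
            hgvs_c=row.get("hgvs_c") or None,
            hgvs_g=row.get("hgvs_g") or None,
            hgvs_p=row.get("hgvs_p") or None,
            ref_allele=row.get("ref_allele", ""),
            alt_allele=row.get("alt_allele", ""),
            population_maf=float(row["population_maf"]) if row.get("population_maf") else None,
            anchor=row.get("anchor", "0") in ("1", "True", "true"),
            retention_factor=float(row["retention_factor"]) if row.get("retention_factor") else None,
        )
        variants.append(v)
        for alias in (row.get("aliases") or "").split(","):
            if alias.strip():
                aliases[alias.strip()] = v.id
    return VariantTable(variants, aliases)


_PHASE_METHODS = {
    "CCS": "ccs_reads", "TRIOS": "trios", "ND": "not_determined",
    "": "not_determined", "MAT": "maternal_only", "PAT": "paternal_only",
    # already-normalized tokens round-trip unchanged
    "CCS_READS": "ccs_reads", "NOT_DETERMINED": "not_determined",
    "MATERNAL_ONLY": "maternal_only", "PATERNAL_ONLY": "paternal_only",
}
_ORIGINS = {"": "unknown", "PAT": "paternal", "MAT": "maternal",
            "UNKNOWN": "unknown", "PATERNAL": "paternal", "MATERNAL": "maternal"}


def _parse_call(cell: str, origin: str, table: VariantTable, row_id: str) -> AlleleCall:
    raw = cell.strip()
    if not raw:  # reference chromosome (simulated cohorts)
        return AlleleCall((), _ORIGINS[origin.strip().upper()])
    # bracketed complex-SV labels contain semicolons that are not cis separators
    parts = [raw] if raw.startswith("g.[") else raw.split(";")
    ids = []
    for part in parts:
        try:
            ids.append(table.resolve(part))
        except KeyError:
            raise ValueError(
                f"proband {row_id}: unresolvable variant label {part.strip()!r}"
            ) from None
    return AlleleCall(tuple(ids), _ORIGINS[origin.strip().upper()])


def read_cohort(cohort_path, variant_table) -> list[ProbandRecord]:
    """Read a cohort genotype TSV against a variant annotation table.

    Parameters
    ----------
    cohort_path:
        TSV with columns ``proband_id, sex, allele1, origin1, allele2,
        origin2, phase_method, group``. Semicolon-separated variant strings
        are split into cis lists; homozygous rows carry identical calls.
    variant_table:
        A :class:`VariantTable` or a path to one.

    Raises
    ------
    ValueError
        On an unresolvable variant label (naming the label and proband) or
        a duplicate proband id.
    """
    table = variant_table if isinstance(variant_table, VariantTable) else read_variant_table(variant_table)
    df = pd.read_csv(cohort_path, sep="\t", dtype=str, keep_default_na=False)
    records, seen = [], set()
    for _, row in df.iterrows():
        pid = row["proband_id"].strip()
        if pid in seen:
            raise ValueError(f"duplicate proband id {pid}")
        seen.add(pid)
        records.append(
            ProbandRecord(
                proband_id=pid,
                sex=row.get("sex", "unknown") or "unknown",
                allele1=_parse_call(row["allele1"], row.get("origin1", ""), table, pid),
                allele2=_parse_call(row["allele2"], row.get("origin2", ""), table, pid),
                phase_method=_PHASE_METHODS[row.get("phase_method", "").strip().upper()],
                group=row.get("group", "two_PLP") or "two_PLP",
            )
        )
    return records


_ORIGIN_OUT = {"unknown": "", "paternal": "Pat", "maternal": "Mat"}


def write_cohort(records: Iterable[ProbandRecord], path) -> None:
    """Write the normalized cohort table; inverse of :func:`read_cohort`."""
    with open(path, "w") as fh:
        fh.write("proband_id\tsex\tallele1\torigin1\tallele2\torigin2\tphase_method\tgroup\n")
        for r in records:
            fh.write("\t".join([
                r.proband_id, r.sex,
                "; ".join(r.allele1.variants), _ORIGIN_OUT[r.allele1.parental_origin],
                "; ".join(r.allele2.variants), _ORIGIN_OUT[r.allele2.parental_origin],
                r.phase_method, r.group,
            ]) + "\n")


def classify_rarity(v: Variant, threshold: float = RARITY_THRESHOLD) -> str:
    """Classify an allele as ``"rare"`` / ``"common"`` by population MAF.

    The comparison is strict (``maf < threshold`` is rare). A variant with
    no recorded MAF is ``"unknown"`` — never silently rare.
    """
    if v.population_maf is None:
        return "unknown"
    return "rare" if v.population_maf < threshold else "common"


def allele_count(cohort: Iterable[ProbandRecord], variant_id: str) -> int:
    """Total occurrences of a variant across both allele calls of all
    probands; homozygotes count twice. An absent id counts 0."""
    n = 0
    for r in cohort:
        for call in (r.allele1, r.allele2):
            n += call.variants.count(variant_id)
    return n


def distinct_variants(
    cohort: Iterable[ProbandRecord], table: Optional[VariantTable] = None
) -> tuple[set[str], Counter]:
    """Union of all variant ids in all allele calls, with per-class tallies.

    Members of multi-variant cis calls are counted individually. The tally
    is empty when no table is supplied.
    """
    ids: set[str] = set()
    for r in cohort:
        ids |= r.carried
    tally: Counter = Counter()
    if table is not None:
        for vid in ids:
            tally[table[vid].vclass] += 1
    return ids, tally


def sv_carrier_count(cohort: Iterable[ProbandRecord], table: VariantTable) -> int:
    """Number of probands carrying >= 1 large-SV allele; each counted once."""
    return sum(
        1
        for r in cohort
        if any(table[vid].vclass in SV_CLASSES for vid in r.carried)
    )


class RepeatTrack:
    """Repeat-element intervals (LINE / SINE / LTR / other) from a BED file.

    Intervals are stored half-open 0-based as read from BED.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        self.intervals = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for contig, start, end, rclass in self.intervals:
            if start >= end:
                raise ValueError(f"empty repeat interval {contig}:{start}-{end}")
            self._trees.setdefault(contig, IntervalTree()).addi(start, end, rclass)

    @classmethod
    def from_bed(cls, path) -> "RepeatTrack":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "other"))
        return cls(ivs)

    def classes_at(self, contig: str, pos0: int) -> frozenset[str]:
        """Repeat classes covering a 0-based point (BED half-open test)."""
        tree = self._trees.get(contig)
        if tree is None:
            return frozenset()
        return frozenset(iv.data for iv in tree.at(pos0))


def annotate_junctions(
    svs: Iterable[Variant], repeats: RepeatTrack
) -> list[JunctionAnnotation]:
    """Flag SV junction endpoints that fall inside repeat elements.

    Each SV's 1-based endpoints are converted to 0-based points and tested
    against the half-open repeat intervals; an endpoint equal to a BED end
    coordinate is therefore *not* flagged. A contig absent from the track
    yields a not-overlapping flag with a warning.
    """
    out = []
    known = {c for c, *_ in repeats.intervals}
    for v in svs:
        if v.contig not in known:
            warnings.warn(
                f"{v.id}: contig {v.contig} absent from repeat track; "
                "endpoints reported as not overlapping"
            )
        s_cls = repeats.classes_at(v.contig, v.start - 1)
        e_cls = repeats.classes_at(v.contig, v.end - 1)
        out.append(
            JunctionAnnotation(
                variant_id=v.id,
                start_in_repeat=bool(s_cls),
                end_in_repeat=bool(e_cls),
                repeat_classes=s_cls | e_cls,
            )
        )
    return out


def cohort_stats(cohort: Sequence[ProbandRecord], table: VariantTable) -> dict:
    """Headline cohort summary: proband count, distinct alleles, SV tallies
    and the most frequent individual variants."""
    ids, tally = distinct_variants(cohort, table)
    counts = Counter()
    for vid in ids:
        counts[vid] = allele_count(cohort, vid)
    n_sv = sum(n for cls, n in tally.items() if cls in SV_CLASSES)
    return {
        "n_probands": len(cohort),
        "n_distinct_variants": len(ids),
        "n_distinct_svs": n_sv,
        "class_tally": {cls.value: n for cls, n in sorted(tally.items())},
        "allele_counts": dict(counts.most_common()),
        "sv_carriers": sv_carrier_count(cohort, table),
    }


def load_packaged_cohort() -> tuple[list[ProbandRecord], VariantTable]:
    """Load the packaged transcription of the study's cohort table."""
    data = resources.files("cishap") / "data"
    table = read_variant_table(str(data / "table1_variants.tsv"))
    cohort = read_cohort(str(data / "table1_cohort.tsv"), table)
    return cohort, table


def export_vcf(table: VariantTable, path, assembly: str = "GRCh38") -> None:
    """Export the variant table as a minimal VCF (one record per variant,
    symbolic ALT for structural variants). Sorted by position."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##reference={assembly}")
    contigs = {v.contig for v in table.variants.values()}
    for c in sorted(contigs):
        header.contigs.add(c, length=300_000_000)
    header.info.add("END", 1, "Integer", "End position")
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("VCLASS", 1, "String", "Functional class")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(table.variants.values(), key=lambda x: (x.contig, x.start)):
            rec = vcf.new_record()
            rec.contig = v.contig
            rec.start = v.start - 1  # pysam is 0-based
            rec.id = v.id.replace(" ", "_")
            if v.vclass in SV_CLASSES:
                svtype = {"sv_deletion": "DEL", "sv_duplication": "DUP", "cxsv": "CPX"}[v.vclass.value]
                rec.ref = "N"
                rec.alts = (f"<{svtype}>",)
                rec.stop = v.end
                rec.info["SVTYPE"] = svtype
            else:
                rec.ref = v.ref_allele or "N"
                rec.alts = (v.alt_allele or "<ALT>",)
            rec.info["VCLASS"] = v.vclass.value
            vcf.write(rec)
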