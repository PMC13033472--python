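"""Multi-variant cis-haplotype cataloging and population frequencies.

Builds the catalog of recurring multi-variant haplotypes observed in a
cohort: maximal sets of variants pairwise phased cis on one chromosome of
at least one proband, merged across probands by member set. Each proband's
relationship to a haplotype is classified as *phase-validated* (carries all
member alleles, all pairs resolved cis), *genotype-consistent* (carries all
member alleles, >= 1 pair unresolved) or *inconsistent* (>= 1 pair resolved
trans). Population haplotype frequencies are estimated by pattern matching
against a phased panel.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .cohort_model import ProbandRecord, VariantTable
from .phasing import PhaseCall

__all__ = [
    "Haplotype", "HaplotypeObservation", "CatalogEntry", "PhasedPanel",
    "build_catalog", "match_proband", "cohort_enrichment", "panel_hf",
    "display_name", "write_catalog",
]


@dataclass(frozen=True)
class Haplotype:
    """An ordered set of variant ids asserted to be on one chromosome."""

    id: str
    members: tuple[str, ...]
    anchors: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.members:
            raise ValueError("haplotype with no members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass(frozen=True)
class HaplotypeObservation:
    proband_id: str
    haplotype_id: str
    status: str  # phase_validated | genotype_consistent | inconsistent
    n_chromosomes: int = 1


@dataclass
class CatalogEntry:
    haplotype: Haplotype
    observations: list[HaplotypeObservation] = field(default_factory=list)

    def count(self, status: str) -> int:
        return sum(o.n_chromosomes for o in self.observations if o.status == status)

    @property
    def n_probands(self) -> int:
        return len({o.proband_id for o in self.observations})


def _order_members(members: Iterable[str], table: Optional[VariantTable]) -> tuple[str, ...]:
    # transcript order: the modelled locus is minus-strand, so ascending
    # coding position corresponds to descending genomic coordinate
    ms = list(members)
    if table is not None and all(m in table for m in ms):
        return tuple(sorted(ms, key=lambda m: (-table[m].start, m)))
    return tuple(sorted(ms))


def _member_anchors(members, table: Optional[VariantTable]) -> frozenset[str]:
    if table is None:
        return frozenset()
    return frozenset(m for m in members if m in table and table[m].anchor)


def match_proband(
    record: ProbandRecord,
    phase_calls: Mapping[tuple[str, str], PhaseCall],
    h: Haplotype,
) -> Optional[str]:
    """Classify one proband's observation of a haplotype.

    Returns ``"phase_validated"``, ``"genotype_consistent"``,
    ``"inconsistent"`` or ``None`` when the proband does not carry every
    member allele. A conflict-flagged pair counts as inconsistent.
    """
    if not h.member_set <= record.carried:
        return None
    any_unresolved = False
    for a, b in itertools.combinations(sorted(h.member_set), 2):
        call = phase_calls.get(tuple(sorted((a, b))))
        rel = call.relation if call is not None else "ambiguous"
        if rel == "trans" or (call is not None and call.conflict):
            return "inconsistent"
        if rel != "cis":
            any_unresolved = True
    # single-member haplotypes carried are trivially phase-validated
    return "genotype_consistent" if any_unresolved else "phase_validated"


def _chromosome_multiplicity(record: ProbandRecord, h: Haplotype) -> int:
    """Number of the proband's allele calls individually containing all
    members (a homozygote contributes two observations of one haplotype)."""
    n = sum(
        1
        for call in (record.allele1, record.allele2)
        if h.member_set <= set(call.variants)
    )
    return max(n, 1)


def build_catalog(
    phase_calls: Mapping[str, Mapping[tuple[str, str], PhaseCall]],
    cohort: Sequence[ProbandRecord],
    table: Optional[VariantTable] = None,
    min_members: int = 2,
) -> list[CatalogEntry]:
    """Build the catalog of recurring multi-variant cis-haplotypes.

    Parameters
    ----------
    phase_calls:
        Per-proband pairwise phase calls (as from
        :func:`cishap.phasing.resolve_proband`).
    cohort:
        Proband records; allele-call membership supplies the carried
        alleles and chromosome multiplicity.
    table:
        Optional variant table used to order members genomically and flag
        anchors.
    min_members:
        Smallest member set emitted (default 2: multi-allele haplotypes).

    A haplotype is emitted for every maximal clique of pairwise-cis variants
    in at least one proband; identical member sets merge across probands.
    Every proband is then classified against every emitted haplotype, so a
    proband with conflicting phase evidence appears as an inconsistent
    observation while the haplotype itself is still emitted from others.
    """
    by_members: dict[frozenset[str], None] = {}
    rec_by_id = {r.proband_id: r for r in cohort}
    for pid, calls in phase_calls.items():
        record = rec_by_id.get(pid)
        if record is None:
            continue
        g = nx.Graph()
        g.add_nodes_from(record.carried)
        for (a, b), call in calls.items():
            if call.relation == "cis" and not call.conflict:
                g.add_edge(a, b)
        for clique in nx.find_cliques(g):
            if len(clique) >= min_members:
                by_members.setdefault(frozenset(clique))
    # allele calls asserting multi-variant cis lists (e.g. a curated cohort
    # table) contribute haplotypes even without explicit phase calls
    for r in cohort:
        for call in (r.allele1, r.allele2):
            if len(call.variants) >= min_members:
                by_members.setdefault(frozenset(call.variants))

    entries = []
    for i, members in enumerate(sorted(by_members, key=lambda m: sorted(m))):
        ordered = _order_members(members, table)
        h = Haplotype(
            id=f"H{i + 1:03d}",
            members=ordered,
            anchors=_member_anchors(ordered, table),
        )
        entry = CatalogEntry(h)
        for r in cohort:
            status = match_proband(r, phase_calls.get(r.proband_id, {}), h)
            if status is None:
                continue
            mult = _chromosome_multiplicity(r, h) if status != "inconsistent" else 1
            entry.observations.append(
                HaplotypeObservation(r.proband_id, h.id, status, mult)
            )
        entries.append(entry)
    return entries


def display_name(h: Haplotype, table: VariantTable) -> str:
    """Protein-level display name, e.g. ``p.[Gly27Arg;Ala355=;Leu440Phe]``.

    Members without a protein-level name keep their id. Nonsense/frameshift
    members 5' of an anchor are retained in the catalog itself; pass the
    haplotype through :func:`truncation_display_filter` first to apply the
    figure-style exclusion.
    """
    parts, protein = [], []
    for m in h.members:
        p = table[m].hgvs_p if m in table else None
        if p and p.startswith("p."):
            protein.append(p[2:])
        else:
            parts.append(m)
    label = ""
    if protein:
        label = "p.[" + ";".join(protein) + "]"
    if parts:
        label = (label + ";" if label else "") + ";".join(parts)
    return label


_TRUNCATING = {"nonsense", "frameshift_indel"}


def truncation_display_filter(h: Haplotype, table: VariantTable) -> Haplotype:
    """Drop anchors 3' (in transcript order) of a truncating member for
    display purposes only; the catalog stores full member sets."""
    truncs = [m for m in h.members if m in table and table[m].vclass.value in _TRUNCATING]
    if not truncs:
        return h
    # minus-strand locus: transcript order is descending genomic coordinate
    cut = max(table[m].start for m in truncs)
    kept = tuple(
        m for m in h.members
        if m not in h.anchors or table[m].start >= cut
    )
    return Haplotype(h.id, kept or h.members, _member_anchors(kept, table))


def cohort_enrichment(
    cohort: Sequence[ProbandRecord], variant_id: str, reference_maf: float
) -> tuple[float, float]:
    """Cohort allele frequency and fold enrichment over a reference MAF.

    ``cohort_af = allele_count / (2 * n_probands)``. A zero reference MAF
    yields an infinite fold with a warning rather than an error.
    """
    from .cohort_model import allele_count
    import warnings

    af = allele_count(cohort, variant_id) / (2 * len(cohort))
    if reference_maf < 0:
        raise ValueError("reference_maf must be >= 0")
    if reference_maf == 0:
        warnings.warn(f"{variant_id}: reference MAF is 0; fold enrichment undefined")
        return af, float("inf") if af > 0 else 0.0
    return af, af / reference_maf


@dataclass
class PhasedPanel:
    """A phased reference panel: 2N haplotypes over a site list.

    ``haplotypes`` is a (2N, S) 0/1 array; rows ``2i`` and ``2i + 1`` are
    the two chromosomes of individual ``i``.
    """

    sites: tuple[str, ...]
    haplotypes: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("haplotype matrix shape does not match site list")
        if self.haplotypes.shape[0] % 2:
            raise ValueError("panel requires exactly 2 haplotypes per individual")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @classmethod
    def from_tsv(cls, path) -> "PhasedPanel":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        sites = tuple(c for c in df.columns if c not in ("sample_id", "hap_index"))
        return cls(sites, df[list(sites)].to_numpy())

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.haplotypes, columns=list(self.sites))
        df.insert(0, "hap_index", [i % 2 for i in range(len(df))])
        df.insert(0, "sample_id", [f"I{i // 2:05d}" for i in range(len(df))])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_vcf(cls, path) -> "PhasedPanel":
        """Read phased genotypes from a VCF; site ids come from the ID
        column (falling back to ``contig:pos``)."""
        import pysam

        sites, cols = [], []
        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                sites.append(rec.id or f"{rec.contig}:{rec.pos}")
                col = []
                for s in samples:
                    gt = rec.samples[s]
                    if not gt.phased:
                        raise ValueError(f"unphased genotype for {s} at {sites[-1]}")
                    col.extend(int(bool(a)) for a in gt["GT"])
                cols.append(col)
        return cls(tuple(sites), np.array(cols, dtype=np.int8).T)


def panel_hf(panel: PhasedPanel, pattern: Mapping[str, int | str]) -> float:
    """Fraction of panel haplotypes matching every required allele.

    ``pattern`` maps site id to the required allele (``1``/``"alt"`` or
    ``0``/``"ref"``); sites outside the pattern are unconstrained. A pattern
    site absent from the panel is a hard error.
    """
    if panel.haplotypes.shape[0] == 0:
        raise ValueError("empty panel")
    idx = {s: i for i, s in enumerate(panel.sites)}
    mask = np.ones(panel.haplotypes.shape[0], dtype=bool)
    for site, allele in pattern.items():
        if site not in idx:
            raise KeyError(f"pattern site {site!r} absent from panel")
        want = 1 if allele in (1, "alt") else 0
        mask &= panel.haplotypes[:, idx[site]] == want
    return mask.mean()


def write_catalog(entries: Sequence[CatalogEntry], path, table: Optional[VariantTable] = None) -> None:
    """Write the catalog as TSV: id, members, anchors, display name and
    observation counts by status."""
    with open(path, "w") as fh:
        fh.write(
            "haplotype_id\tmembers\tanchors\tdisplay_name\t"
            "phase_validated\tgenotype_consistent\tinconsistent\tn_probands\n"
        )
        for e in entries:
            name = display_name(e.haplotype, table) if table is not None else ""
            fh.write("\t".join([
                e.haplotype.id,
                ";".join(e.haplotype.members),
                ";".join(sorted(e.haplotype.anchors)),
                name,
                str(e.count("phase_validated")),
                str(e.count("genotype_consistent")),
                str(e.count("inconsistent")),
                str(e.n_probands),
            ]) + "\n")
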