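"""Cis/trans phase resolution for variant pairs.

Two evidence sources, mirroring how phase is established in practice for a
single gene locus:

* **Trio segregation** — enumerate every parental-haplotype transmission
  consistent with all six genotypes of a family trio, assuming no
  recombination within the locus, and classify the pair as cis when every
  consistent transmission places both alternate alleles on the same
  transmitted chromosome.
* **Read fragments** — count co-observations of the two sites on single
  sequencing fragments (paired-end or long reads) and call cis/trans when
  one configuration dominates.

Both lines of evidence are combined per proband; discordant non-ambiguous
calls raise a conflict flag rather than being silently averaged.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .cohort_model import ProbandRecord

__all__ = [
    "SiteGenotype", "Trio", "Fragment", "PhaseCall",
    "phase_trio", "phase_fragments", "resolve_proband",
    "MIN_FRAGMENT_SUPPORT", "MAX_FRAGMENT_CONFLICT",
]

#: fragment-phasing defaults: a call requires replicated direct
#: observation, and supporting observations must outnumber conflicting
#: (likely sequencing-error) ones at least two to one
MIN_FRAGMENT_SUPPORT = 2
MAX_FRAGMENT_CONFLICT = 1 / 3

#: within-locus transmissions are modelled without recombination
NO_RECOMBINATION = True


@dataclass(frozen=True)
class SiteGenotype:
    variant_id: str
    dosage: int  # 0 | 1 | 2 alternate-allele copies
    missing: bool = False


@dataclass
class Trio:
    """Genotypes of proband, father and mother over a shared site set."""

    proband: dict[str, SiteGenotype]
    father: dict[str, SiteGenotype]
    mother: dict[str, SiteGenotype]

    def __post_init__(self):
        if not (set(self.proband) == set(self.father) == set(self.mother)):
            raise ValueError("trio members must share one variant_id set")


@dataclass(frozen=True)
class Fragment:
    """Alleles observed on one sequencing fragment."""

    fragment_id: str
    observations: Mapping[str, str]  # variant_id -> "ref" | "alt"

    def __post_init__(self):
        if not self.observations:
            raise ValueError("fragment with no observations")


@dataclass
class PhaseCall:
    pair: tuple[str, str]
    relation: str  # cis | trans | ambiguous | mendelian_error
    origin: dict[str, str] = field(default_factory=dict)  # variant_id -> paternal|maternal
    support: int = 0
    conflict: bool = False
    source: str = ""

    def __post_init__(self):
        self.pair = tuple(sorted(self.pair))


def _transmittable(g: SiteGenotype) -> tuple[int, ...]:
    """Alleles a parent can place on the transmitted haplotype at one site."""
    if g.missing:
        return (0, 1)
    return {0: (0,), 1: (0, 1), 2: (1,)}[g.dosage]


def phase_trio(trio: Trio, a: str, b: str) -> PhaseCall:
    """Phase a pair of sites by Mendelian segregation in a trio.

    Enumerates all (paternal, maternal) transmitted-haplotype assignments
    over the two sites that reproduce the proband's genotypes, with no
    recombination between the sites. Relation is ``cis`` if every consistent
    assignment puts the proband's alternate alleles at both sites on one
    chromosome, ``trans`` if never, ``ambiguous`` if both occur and
    ``mendelian_error`` if no assignment is consistent (including de novo
    alleles absent from both parents). Parental origin is reported per
    variant when it is the same in every consistent assignment.

    Requires proband dosage >= 1 at both sites; missing parental genotypes
    are treated as unconstrained.
    """
    gp = {s: trio.proband[s] for s in (a, b)}
    for s, g in gp.items():
        if g.missing:
            raise ValueError(f"proband genotype missing at {s}")
        if g.dosage < 1:
            raise ValueError(f"proband carries no alternate allele at {s}")

    f_haps = list(itertools.product(_transmittable(trio.father[a]),
                                    _transmittable(trio.father[b])))
    m_haps = list(itertools.product(_transmittable(trio.mother[a]),
                                    _transmittable(trio.mother[b])))
    target = (gp[a].dosage, gp[b].dosage)
    consistent = [
        (f, m)
        for f in f_haps
        for m in m_haps
        if (f[0] + m[0], f[1] + m[1]) == target
    ]
    if not consistent:
        return PhaseCall((a, b), "mendelian_error", support=0, source="trio")

    cis_flags = [
        (f == (1, 1)) or (m == (1, 1))  # some chromosome carries both alts
        for f, m in consistent
    ]
    if all(cis_flags):
        relation = "cis"
    elif not any(cis_flags):
        relation = "trans"
    else:
        relation = "ambiguous"

    origin: dict[str, str] = {}
    for i, site in enumerate((a, b)):
        if gp[site].dosage == 1:
            sources = {("paternal" if f[i] else "maternal") for f, m in consistent}
            if len(sources) == 1:
                origin[site] = sources.pop()
    return PhaseCall((a, b), relation, origin=origin,
                     support=len(consistent), source="trio")


def phase_fragments(
    frags: Iterable[Fragment],
    a: str,
    b: str,
    min_support: int = MIN_FRAGMENT_SUPPORT,
    max_conflict: float = MAX_FRAGMENT_CONFLICT,
) -> PhaseCall:
    """Phase a pair of sites from direct read-fragment co-observation.

    Fragments covering both sites are tabulated as (alt,alt), (alt,ref),
    (ref,alt) or (ref,ref). The pair is ``cis`` when at least
    ``min_support`` double-alt fragments are seen and the conflicting
    fraction among alt-involving double observations is at most
    ``max_conflict``; ``trans`` symmetrically for the two single-alt
    configurations; otherwise ``ambiguous`` (including when no fragment
    covers both sites).
    """
    n_aa = n_ar = n_ra = 0
    for fr in frags:
        obs = fr.observations
        if a not in obs or b not in obs:
            continue
        oa, ob = obs[a], obs[b]
        if oa == "alt" and ob == "alt":
            n_aa += 1
        elif oa == "alt":
            n_ar += 1
        elif ob == "alt":
            n_ra += 1
    informative = n_aa + n_ar + n_ra
    if informative == 0:
        return PhaseCall((a, b), "ambiguous", support=0, source="fragments")

    cis_ok = n_aa >= min_support and (n_ar + n_ra) / informative <= max_conflict
    trans_ok = (
        n_ar + n_ra >= min_support
        and min(n_ar, n_ra) >= 1
        and n_aa / informative <= max_conflict
    )
    if cis_ok and not trans_ok:
        return PhaseCall((a, b), "cis", support=n_aa, source="fragments")
    if trans_ok and not cis_ok:
        return PhaseCall((a, b), "trans", support=n_ar + n_ra, source="fragments")
    return PhaseCall((a, b), "ambiguous", support=informative, source="fragments")


def _combine(tc: Optional[PhaseCall], fc: Optional[PhaseCall], pair) -> PhaseCall:
    calls = [c for c in (tc, fc) if c is not None]
    resolved = [c for c in calls if c.relation in ("cis", "trans")]
    if len(resolved) == 2 and resolved[0].relation != resolved[1].relation:
        return PhaseCall(pair, "mendelian_error", conflict=True,
                         support=0, source="trio+fragments")
    if resolved:
        best = max(resolved, key=lambda c: c.support)
        origin = {}
        for c in calls:
            origin.update(c.origin)
        return PhaseCall(pair, best.relation, origin=origin,
                         support=sum(c.support for c in resolved),
                         source="+".join(c.source for c in calls))
    for c in calls:  # keep mendelian_error over plain ambiguous
        if c.relation == "mendelian_error":
            return c
    origin = {}
    for c in calls:
        origin.update(c.origin)
    return PhaseCall(pair, "ambiguous", origin=origin, support=0,
                     source="+".join(c.source for c in calls))


def resolve_proband(
    record: ProbandRecord,
    trio: Optional[Trio] = None,
    frags: Optional[Iterable[Fragment]] = None,
    min_support: int = MIN_FRAGMENT_SUPPORT,
    max_conflict: float = MAX_FRAGMENT_CONFLICT,
) -> dict[tuple[str, str], PhaseCall]:
    """Phase every pair of variants a proband carries.

    Trio and fragment evidence are evaluated independently and combined:
    concordant resolved calls (or a single resolved call) give the
    relation; discordant resolved calls yield a ``mendelian_error`` with
    ``conflict=True``. Pairs with no informative evidence are ambiguous.
    """
    frag_list = list(frags) if frags is not None else None
    variants = sorted(record.carried)
    dosage = {v: record.allele1.variants.count(v) + record.allele2.variants.count(v)
              for v in variants}
    out: dict[tuple[str, str], PhaseCall] = {}
    for a, b in itertools.combinations(variants, 2):
        tc = fc = None
        if trio is not None and a in trio.proband and b in trio.proband:
            try:
                tc = phase_trio(trio, a, b)
            except ValueError:
                tc = None
        if frag_list is not None:
            fc = phase_fragments(frag_list, a, b, min_support, max_conflict)
        if tc is None and fc is None:
            # genotype-only deduction: homozygosity at one site forces cis
            if dosage[a] == 2 or dosage[b] == 2:
                out[(a, b)] = PhaseCall((a, b), "cis", support=0, source="genotype")
            else:
                out[(a, b)] = PhaseCall((a, b), "ambiguous", source="none")
            continue
        out[(a, b)] = _combine(tc, fc, (a, b))
    return out
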