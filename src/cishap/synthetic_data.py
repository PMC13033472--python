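"""Seeded synthetic-data generators for every pipeline input.

The default ``oca2_like`` scenario emulates the structure of the study
system: a recessive-locus patient cohort whose chromosomes are drawn from a
small pool of multi-variant haplotypes anchored on the five common
pigmentation-trait GWAS alleles; exact-Mendelian trios built backwards from
the proband's chromosomes; read fragments with a per-observation error
rate; a phased population panel; splice windows and motif-model training
sets; multiplicative dosage-model expression; and LRR tables with planted
copy-number states.

Every generator is a pure function of its configuration: the random stream
of each generator is derived from the scenario seed and a per-generator
constant, so adding one generator never perturbs another's output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort_model import AlleleCall, ProbandRecord, VariantTable, load_packaged_cohort
from .dosage_expression import DosageModel, ExpressionSample, simulate_expression
from .haplotype_catalog import Haplotype, PhasedPanel
from .phasing import Fragment, SiteGenotype, Trio
from .splice_scoring import BASES, FLANK, SpliceWindow
from .cnv_lrr import LrrObservation

__all__ = [
    "ScenarioConfig", "SyntheticCohort", "SpliceTrainingSet",
    "default_haplotype_pool", "donor_motif_table", "acceptor_motif_table",
    "gen_cohort", "gen_panel", "gen_splice_training", "gen_expression",
    "gen_lrr", "oca2_like",
]

# per-generator stream constants (seed-derived, independent streams)
_STREAM = {"cohort": 11, "panel": 23, "splice": 37, "expression": 41, "lrr": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream]])


def default_haplotype_pool() -> list[tuple[Haplotype, float]]:
    """Six recurring multi-variant haplotypes echoing the study cohort.

    Frequencies are chromosome frequencies in the simulated patient pool;
    the remainder is the reference haplotype. The two-common-anchor
    haplotype is planted at 0.14, the frequency reported for it in phased
    population panels.
    """
    mk = lambda hid, members, anchors: Haplotype(hid, tuple(members), frozenset(anchors))
    return [
        (mk("hap_A355_V443I", ["rs1800404", "c.1327G>A"], ["rs1800404"]), 0.22),
        (mk("hap_G27R_A355_L440F", ["c.79G>A", "rs1800404", "c.1320G>C"], ["rs1800404"]), 0.10),
        (mk("hap_R305W_ex7del", ["rs1800401", "exon7_del"], ["rs1800401"]), 0.18),
        (mk("hap_G27R_ex14del", ["c.79G>A", "exon14_del"], []), 0.08),
        (mk("hap_blue_A355", ["rs12913832", "rs1800404"], ["rs12913832", "rs1800404"]), 0.14),
        (mk("hap_R419Q_splice", ["rs1800407", "c.1239+5G>C"], ["rs1800407"]), 0.08),
    ]


def donor_motif_table(peak: float = 0.85) -> np.ndarray:
    """9-mer donor (5'SS) per-position frequency table, consensus CAG|GTAAGT."""
    return _peaked("CAGGTAAGT", peak)


def acceptor_motif_table(peak: float = 0.85) -> np.ndarray:
    """23-mer acceptor (3'SS) frequency table: pyrimidine tract + AG + exon."""
    tbl = np.full((23, 4), 0.0)
    for i in range(18):  # intronic pyrimidine-rich tract
        tbl[i] = [0.08, 0.32, 0.08, 0.52]
    for i, b in enumerate("AG", start=18):  # consensus dinucleotide
        row = np.full(4, (1 - 0.97) / 3)
        row[BASES.index(b)] = 0.97
        tbl[i] = row
    for i, b in enumerate("GTT", start=20):  # mild exonic preference
        row = np.full(4, 0.15)
        row[BASES.index(b)] = 0.55
        tbl[i] = row
    return tbl


def _peaked(consensus: str, peak: float) -> np.ndarray:
    tbl = np.full((len(consensus), 4), (1 - peak) / 3)
    for i, b in enumerate(consensus):
        tbl[i, BASES.index(b)] = peak
    return tbl


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Haplotype frequencies must sum to <= 1 (the remainder is the reference
    haplotype). Fragment depth is the number of fragments co-covering each
    variant pair per proband; fragment_error is the per-observation allele
    error probability.
    """

    seed: int = 0
    haplotype_pool: list[tuple[Haplotype, float]] = field(default_factory=default_haplotype_pool)
    n_probands: int = 60
    trio_fraction: float = 0.5
    fragment_depth: int = 30
    fragment_error: float = 0.02
    donor_table: np.ndarray = field(default_factory=donor_motif_table)
    acceptor_table: np.ndarray = field(default_factory=acceptor_motif_table)
    flank: int = FLANK
    exon_length: int = 50
    strand: str = "-"
    n_training_sites: int = 500
    n_decoys: int = 500
    dosage_model: DosageModel = field(default_factory=lambda: DosageModel(100.0, 0.73, 0.15))
    n_per_dosage: int = 20
    lrr_het_shift: float = -0.45
    lrr_hom_shift: float = -2.0
    lrr_probe_sd: float = 0.15
    lrr_probes_per_region: int = 4
    lrr_n_controls: int = 20
    panel_size: int = 2504

    def __post_init__(self):
        total = sum(f for _, f in self.haplotype_pool)
        if total > 1 + 1e-12:
            raise ValueError(f"haplotype frequencies sum to {total} > 1")
        for _, f in self.haplotype_pool:
            if not 0 <= f <= 1:
                raise ValueError("haplotype frequency outside [0, 1]")


def oca2_like(seed: int = 0, **overrides) -> ScenarioConfig:
    """The documented default scenario."""
    return replace(ScenarioConfig(seed=seed), **overrides)


# ---------------------------------------------------------------- cohort

@dataclass
class SyntheticCohort:
    records: list[ProbandRecord]
    trios: dict[str, Trio]
    fragments: dict[str, list[Fragment]]
    truth: dict[str, tuple[frozenset, frozenset]]  # proband -> member sets
    sites: tuple[str, ...]


def _draw_hap(pool, rng) -> frozenset:
    freqs = np.array([f for _, f in pool])
    ref_freq = 1 - freqs.sum()
    probs = np.append(freqs, ref_freq)
    k = rng.choice(len(probs), p=probs)
    if k == len(pool):
        return frozenset()
    return pool[k][0].member_set


def _genotypes(sites, hap1: frozenset, hap2: frozenset) -> dict[str, SiteGenotype]:
    return {
        s: SiteGenotype(s, int(s in hap1) + int(s in hap2)) for s in sites
    }


def gen_cohort(cfg: ScenarioConfig, table: Optional[VariantTable] = None) -> SyntheticCohort:
    """Simulate a patient cohort with trios, fragments and phase truth.

    Each proband draws two chromosomes from the haplotype pool. Parents
    are constructed backwards — the proband's chromosome 1 is the paternal
    transmitted haplotype, chromosome 2 the maternal one, and each parent's
    untransmitted chromosome is an independent pool draw — so Mendelian
    transmission is exact by construction. Fragments co-cover every pair
    of pool sites at the configured depth with per-observation error.
    """
    rng = _rng(cfg.seed, "cohort")
    if table is None:
        _, table = load_packaged_cohort()
    pool = cfg.haplotype_pool
    sites = tuple(sorted({m for h, _ in pool for m in h.members}))

    def order(members: frozenset) -> tuple[str, ...]:
        return tuple(sorted(members, key=lambda m: (table[m].start if m in table else 0, m)))

    records, trios, fragments, truth = [], {}, {}, {}
    for i in range(cfg.n_probands):
        pid = f"S{i:04d}"
        hap1, hap2 = _draw_hap(pool, rng), _draw_hap(pool, rng)
        truth[pid] = (hap1, hap2)
        has_trio = rng.random() < cfg.trio_fraction
        records.append(
            ProbandRecord(
                proband_id=pid,
                sex="F" if rng.random() < 0.5 else "M",
                allele1=AlleleCall(order(hap1), "paternal"),
                allele2=AlleleCall(order(hap2), "maternal"),
                phase_method="trios" if has_trio else "ccs_reads",
            )
        )
        if has_trio:
            f_other, m_other = _draw_hap(pool, rng), _draw_hap(pool, rng)
            trios[pid] = Trio(
                proband=_genotypes(sites, hap1, hap2),
                father=_genotypes(sites, hap1, f_other),
                mother=_genotypes(sites, hap2, m_other),
            )
        frags = []
        carried = sorted(hap1 | hap2)
        for ai in range(len(carried)):
            for bi in range(ai + 1, len(carried)):
                a, b = carried[ai], carried[bi]
                for d in range(cfg.fragment_depth):
                    chrom = hap1 if rng.random() < 0.5 else hap2
                    obs = {}
                    for s in (a, b):
                        allele = "alt" if s in chrom else "ref"
                        if rng.random() < cfg.fragment_error:
                            allele = "ref" if allele == "alt" else "alt"
                        obs[s] = allele
                    frags.append(Fragment(f"{pid}_f{len(frags):05d}", obs))
        fragments[pid] = frags
    return SyntheticCohort(records, trios, fragments, truth, sites)


# ---------------------------------------------------------------- panel

def gen_panel(cfg: ScenarioConfig) -> tuple[PhasedPanel, dict[str, float]]:
    """Draw 2N panel haplotypes i.i.d. from the pool; returns the panel and
    the planted haplotype frequencies (by pool haplotype id)."""
    rng = _rng(cfg.seed, "panel")
    pool = cfg.haplotype_pool
    sites = tuple(sorted({m for h, _ in pool for m in h.members}))
    idx = {s: j for j, s in enumerate(sites)}
    n_hap = 2 * cfg.panel_size
    H = np.zeros((n_hap, len(sites)), dtype=np.int8)
    freqs = np.array([f for _, f in pool])
    probs = np.append(freqs, 1 - freqs.sum())
    draws = rng.choice(len(probs), size=n_hap, p=probs)
    for row, k in enumerate(draws):
        if k < len(pool):
            for m in pool[k][0].members:
                H[row, idx[m]] = 1
    return PhasedPanel(sites, H), {h.id: f for h, f in pool}


# ---------------------------------------------------------------- splice

@dataclass
class SpliceTrainingSet:
    """Motif-span training sets (9/23-mers), full-window training sets for
    windowed scorers, decoys of both lengths, and the overlapping
    reference window pair."""

    donor_sites: list[str]
    acceptor_sites: list[str]
    decoys: list[str]
    donor_window_sites: list[str]
    acceptor_window_sites: list[str]
    window_decoys: list[str]
    donor_window: SpliceWindow
    acceptor_window: SpliceWindow
    anchor_genomic: int


def _sample_seqs(table: np.ndarray, n: int, rng) -> list[str]:
    L = table.shape[0]
    out = []
    draws = np.stack([rng.choice(4, size=n, p=table[i] / table[i].sum()) for i in range(L)], axis=1)
    for row in draws:
        out.append("".join(BASES[j] for j in row))
    return out


def gen_splice_training(cfg: ScenarioConfig) -> SpliceTrainingSet:
    """Sample motif training sets and build the overlapping window pair.

    A plus-strand genomic segment ``intron | exon | intron`` is laid out
    with the exon shorter than the flank length, so the acceptor and donor
    162 bp windows overlap across the exon — the geometry that lets one
    exonic anchor allele fall inside both windows. The configured strand
    ('-' by default, matching the modelled locus) exercises the
    reverse-complement path.
    """
    rng = _rng(cfg.seed, "splice")
    donor_sites = _sample_seqs(cfg.donor_table, cfg.n_training_sites, rng)
    acceptor_sites = _sample_seqs(cfg.acceptor_table, cfg.n_training_sites, rng)
    bg = np.array([0.27, 0.23, 0.23, 0.27])
    decoy_len = max(cfg.donor_table.shape[0], cfg.acceptor_table.shape[0])
    decoys = ["".join(BASES[j] for j in rng.choice(4, size=decoy_len, p=bg))
              for _ in range(cfg.n_decoys)]

    # full-window (L = 2*flank + 2) training sets for windowed scorers:
    # motif tables at the consensus, a mild exonic composition signal
    # elsewhere on the exonic side, background introns
    L = 2 * cfg.flank + 2
    exon_bias = np.array([0.22, 0.28, 0.28, 0.22])

    def window_table(site_type: str, motif: np.ndarray) -> np.ndarray:
        tbl = np.tile(bg, (L, 1))
        d0 = cfg.flank  # 0-based index of the first dinucleotide base
        exonic_idx = range(0, d0) if site_type == "donor_5ss" else range(d0 + 2, L)
        for i in exonic_idx:
            tbl[i] = exon_bias
        if site_type == "donor_5ss":
            span0 = d0 - 3  # 3 exonic + GT + 4 intronic
        else:
            span0 = d0 - 18  # 18 intronic + AG + 3 exonic
        tbl[span0:span0 + motif.shape[0]] = motif
        return tbl

    donor_window_sites = _sample_seqs(window_table("donor_5ss", cfg.donor_table),
                                      cfg.n_training_sites, rng)
    acceptor_window_sites = _sample_seqs(window_table("acceptor_3ss", cfg.acceptor_table),
                                         cfg.n_training_sites, rng)
    window_decoys = ["".join(BASES[j] for j in rng.choice(4, size=L, p=bg))
                     for _ in range(cfg.n_decoys)]

    flank, exon = cfg.flank, cfg.exon_length
    # transcript-orientation layout of the segment
    seg_len = 2 * flank + exon + 2 * 2 + 60  # introns padded beyond the flanks
    t = list("".join(BASES[j] for j in rng.choice(4, size=seg_len, p=bg)))
    # acceptor: [intron flank][AG][exon ...]; donor: [... exon][GT][intron flank]
    acc_dinuc = flank  # 0-based start of AG in transcript orientation
    don_dinuc = flank + 2 + exon
    t[acc_dinuc:acc_dinuc + 2] = "AG"
    t[don_dinuc:don_dinuc + 2] = "GT"
    transcript = "".join(t)

    contig, g0 = "chrS", 1_000_000  # synthetic contig
    if cfg.strand == "-":
        from Bio.Seq import Seq
        plus = str(Seq(transcript).reverse_complement())
        # transcript index i (0-based) sits at plus-strand position g0 + (seg_len-1-i)
        tpos = lambda i: g0 + seg_len - 1 - i
    else:
        plus = transcript
        tpos = lambda i: g0 + i

    # anchor: an exonic position inside both windows, 20 bases into the exon
    anchor_t = acc_dinuc + 2 + 20
    anchor_genomic = tpos(anchor_t)

    def window(site_type: str, dinuc_t: int) -> SpliceWindow:
        start_t = dinuc_t - flank
        end_t = dinuc_t + 2 + flank  # exclusive
        g_positions = [tpos(i) for i in range(start_t, end_t)]
        lo, hi = min(g_positions), max(g_positions)
        sub = plus[lo - g0: hi - g0 + 1]
        return SpliceWindow.from_genomic(
            sub, contig, lo, cfg.strand, site_type, anchor_genomic=anchor_genomic
        )

    return SpliceTrainingSet(
        donor_sites=donor_sites,
        acceptor_sites=acceptor_sites,
        decoys=decoys,
        donor_window_sites=donor_window_sites,
        acceptor_window_sites=acceptor_window_sites,
        window_decoys=window_decoys,
        donor_window=window("donor_5ss", don_dinuc),
        acceptor_window=window("acceptor_3ss", acc_dinuc),
        anchor_genomic=anchor_genomic,
    )


# ---------------------------------------------------------------- tables

def gen_expression(cfg: ScenarioConfig) -> tuple[list[ExpressionSample], DosageModel]:
    """Expression table under the multiplicative dosage model; returns the
    samples and the generative truth."""
    rng = _rng(cfg.seed, "expression")
    dosages = [d for d in (0, 1, 2) for _ in range(cfg.n_per_dosage)]
    return simulate_expression(cfg.dosage_model, dosages, rng), cfg.dosage_model


def gen_lrr(
    cfg: ScenarioConfig, cn_states: Optional[Sequence[int]] = None
) -> tuple[list[LrrObservation], list[LrrObservation], dict[str, int]]:
    """LRR tables with planted copy-number states for one region.

    Returns (sample observations, control observations, truth by sample).
    When ``cn_states`` is omitted one sample per state (2, 1, 0) is
    generated.
    """
    rng = _rng(cfg.seed, "lrr")
    region = "exon14"
    if cn_states is None:
        cn_states = [2, 1, 0]
    shift = {2: 0.0, 1: cfg.lrr_het_shift, 0: cfg.lrr_hom_shift}
    samples, truth = [], {}
    for i, cn in enumerate(cn_states):
        sid = f"L{i:04d}"
        truth[sid] = int(cn)
        for p in range(cfg.lrr_probes_per_region):
            samples.append(LrrObservation(
                sid, f"probe{p}", region,
                float(shift[int(cn)] + rng.normal(0, cfg.lrr_probe_sd)),
            ))
    controls = [
        LrrObservation(
            f"C{c:04d}", f"probe{p}", region, float(rng.normal(0, cfg.lrr_probe_sd))
        )
        for c in range(cfg.lrr_n_controls)
        for p in range(cfg.lrr_probes_per_region)
    ]
    return samples, controls, truth
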