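"""Splice-site strength scoring and haplotype sequence manipulation.

Windows of reference sequence around a splice site (80 bp on each side of
the consensus GT/AG dinucleotide, 162 bp total by default) are stored in
transcript orientation; minus-strand loci are reverse-complemented at
construction time and a genome map carries the coordinate correspondence.

Scoring is pluggable. Two reference scorers are provided:

* ``wmm`` — weight matrix model: per-position log2 odds of pseudocounted
  site frequencies against a decoy-derived background. Score differences
  are additive over edited positions.
* ``wam`` — weight array model: first-order model scoring each base
  conditioned on its predecessor, capturing adjacent-position dependence.

The compound cis-impact of a rare variant with a common anchor allele is
the difference between the score with both alleles present and the
reference score; when a variant falls in more than one window only the
impact on the strongest (highest reference score) site is reported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceWindow", "ScorerModel", "HaplotypeEdit", "train_scorer", "score",
    "compound_impact", "strongest_site", "apply_edits", "FLANK", "BASES",
    "DONOR_SPAN", "ACCEPTOR_SPAN",
]

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

#: flank length on each side of the consensus dinucleotide (window L = 2*FLANK + 2)
FLANK = 80

#: (exonic, intronic) motif spans; the intronic count includes the dinucleotide
DONOR_SPAN = (3, 6)     # 9-mer around the 5'SS
ACCEPTOR_SPAN = (3, 20)  # 23-mer around the 3'SS

_CONSENSUS = {"donor_5ss": "GT", "acceptor_3ss": "AG"}


@dataclass(frozen=True)
class HaplotypeEdit:
    """Single-base substitutions at distinct window positions (1-based)."""

    substitutions: tuple[tuple[int, str], ...]

    def __post_init__(self):
        pos = [p for p, _ in self.substitutions]
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate edit positions")
        for p, alt in self.substitutions:
            if alt not in BASES:
                raise ValueError(f"invalid base {alt!r}")

    @classmethod
    def single(cls, position: int, alt: str) -> "HaplotypeEdit":
        return cls(((position, alt),))

    def __add__(self, other: "HaplotypeEdit") -> "HaplotypeEdit":
        return HaplotypeEdit(self.substitutions + other.substitutions)

    def __len__(self):
        return len(self.substitutions)


@dataclass
class SpliceWindow:
    """A reference window around one splice site, transcript orientation.

    ``dinucleotide_positions`` are the 1-based window indices of the
    consensus GT (donor) or AG (acceptor). ``genome_map`` maps window index
    to (contig, genomic position, strand) when the window was built from
    genomic sequence.
    """

    site_type: str  # donor_5ss | acceptor_3ss
    sequence: str
    dinucleotide_positions: tuple[int, int]
    anchor_position: Optional[int] = None
    genome_map: dict[int, tuple[str, int, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        d1, d2 = self.dinucleotide_positions
        if d2 != d1 + 1:
            raise ValueError("dinucleotide positions must be adjacent")
        dinuc = self.sequence[d1 - 1 : d2]
        want = _CONSENSUS[self.site_type]
        if dinuc != want:
            raise ValueError(
                f"{self.site_type} window has {dinuc!r} at the consensus "
                f"positions, expected {want!r}"
            )

    def __len__(self):
        return len(self.sequence)

    @classmethod
    def from_genomic(
        cls,
        plus_seq: str,
        contig: str,
        genomic_start: int,
        strand: str,
        site_type: str,
        anchor_genomic: Optional[int] = None,
    ) -> "SpliceWindow":
        """Build a window from plus-strand genomic sequence.

        ``genomic_start`` is the 1-based position of ``plus_seq[0]``. For a
        minus-strand gene the sequence is reverse-complemented into
        transcript orientation and the genome map reversed accordingly.
        The dinucleotide is assumed centred: positions FLANK+1, FLANK+2 in
        transcript orientation.
        """
        plus_seq = plus_seq.upper()
        L = len(plus_seq)
        if strand == "+":
            seq = plus_seq
            gmap = {i + 1: (contig, genomic_start + i, "+") for i in range(L)}
        elif strand == "-":
            seq = str(Seq(plus_seq).reverse_complement())
            gmap = {i + 1: (contig, genomic_start + L - 1 - i, "-") for i in range(L)}
        else:
            raise ValueError(f"bad strand {strand!r}")
        half = (L - 2) // 2
        anchor = None
        if anchor_genomic is not None:
            rev = {g: w for w, (_, g, _) in gmap.items()}
            anchor = rev[anchor_genomic]
        return cls(site_type, seq, (half + 1, half + 2), anchor, gmap)

    def window_index(self, contig: str, genomic_pos: int) -> int:
        """Window index of a genomic position; KeyError when outside."""
        for w, (c, g, _) in self.genome_map.items():
            if c == contig and g == genomic_pos:
                return w
        raise KeyError(f"{contig}:{genomic_pos} not in window")


def apply_edits(w: SpliceWindow, edits: Optional[HaplotypeEdit]) -> str:
    """Return the window sequence with substitutions applied.

    Edits at the consensus dinucleotide are permitted — they can destroy
    the site and the score will reflect it — but an edit must change the
    reference base.
    """
    if edits is None:
        return w.sequence
    seq = list(w.sequence)
    for pos, alt in edits.substitutions:
        if not 1 <= pos <= len(seq):
            raise IndexError(f"edit position {pos} outside window of length {len(seq)}")
        if seq[pos - 1] == alt:
            raise ValueError(f"edit at {pos} does not change the reference base {alt}")
        seq[pos - 1] = alt
    return "".join(seq)


@dataclass
class ScorerModel:
    """Trained splice-site scorer (weight matrix or weight array model).

    For ``wmm``, ``log_odds`` is an (L, 4) per-position table. For ``wam``,
    ``log_odds`` holds the first-position marginal (4,) and
    ``cond_log_odds`` an (L-1, 4, 4) table indexed by [position-1, previous
    base, base]. All log odds are base 2 against the decoy background.
    """

    model_type: str  # wmm | wam
    site_type: str
    motif_span: tuple[int, int]
    log_odds: np.ndarray
    cond_log_odds: Optional[np.ndarray] = None
    pseudocount: float = 1.0

    @property
    def span_length(self) -> int:
        return sum(self.motif_span)

    # ---- serialization (plain-text matrix format) ----
    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model_type\t{self.model_type}\n")
            fh.write(f"# site_type\t{self.site_type}\n")
            fh.write(f"# motif_span\t{self.motif_span[0]}\t{self.motif_span[1]}\n")
            fh.write(f"# pseudocount\t{self.pseudocount}\n")
            fh.write("# columns\t" + "\t".join(BASES) + "\n")
            for row in np.atleast_2d(self.log_odds):
                fh.write("\t".join(f"{x:.10g}" for x in row) + "\n")
            if self.cond_log_odds is not None:
                fh.write("# conditional\n")
                for i in range(self.cond_log_odds.shape[0]):
                    for p in range(4):
                        fh.write("\t".join(f"{x:.10g}" for x in self.cond_log_odds[i, p]) + "\n")

    @classmethod
    def from_text(cls, path) -> "ScorerModel":
        meta, rows, cond_rows, in_cond = {}, [], [], False
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    parts = line[1:].strip().split("\t")
                    if parts[0] == "conditional":
                        in_cond = True
                    elif parts[0] != "columns":
                        meta[parts[0]] = parts[1:]
                    continue
                if not line.strip():
                    continue
                (cond_rows if in_cond else rows).append([float(x) for x in line.split("\t")])
        span = (int(meta["motif_span"][0]), int(meta["motif_span"][1]))
        lo = np.array(rows)
        if meta["model_type"][0] == "wam":
            lo = lo[0]
            L = span[0] + span[1]
            cond = np.array(cond_rows).reshape(L - 1, 4, 4)
        else:
            cond = None
        return cls(meta["model_type"][0], meta["site_type"][0], span, lo, cond,
                   float(meta["pseudocount"][0]))


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.array([[_B2I[b] for b in s] for s in seqs], dtype=np.int64)


def _background(decoys: Optional[Sequence[str]], pc: float) -> np.ndarray:
    if not decoys:
        return np.full(4, 0.25)
    counts = np.full(4, pc / 4)
    for s in decoys:
        for b in s:
            counts[_B2I[b]] += 1
    return counts / counts.sum()


def _cond_background(decoys: Optional[Sequence[str]], pc: float) -> np.ndarray:
    """First-order background P(base | previous base) from decoy dinucleotides."""
    counts = np.full((4, 4), pc / 4)
    if decoys:
        for s in decoys:
            for x, y in zip(s, s[1:]):
                counts[_B2I[x], _B2I[y]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def train_scorer(
    true_sites: Sequence[str],
    decoys: Optional[Sequence[str]] = None,
    model_type: str = "wmm",
    pseudocount: float = 1.0,
    site_type: str = "donor_5ss",
    motif_span: Optional[tuple[int, int]] = None,
) -> ScorerModel:
    """Train a WMM or WAM from aligned true-site sequences and decoys.

    Pseudocounted per-position frequencies ``(n_b + pc/4) / (N + pc)`` are
    compared against the decoy base composition (uniform when no decoys are
    given). For ``wam``, positions after the first use frequencies
    conditioned on the preceding base against a first-order decoy
    background. All sequences must share the motif-span length.
    """
    if not true_sites:
        raise ValueError("at least one training sequence required")
    L = len(true_sites[0])
    if any(len(s) != L for s in true_sites):
        raise ValueError("true-site sequences must all have the motif-span length")
    if motif_span is None:
        motif_span = DONOR_SPAN if site_type == "donor_5ss" else ACCEPTOR_SPAN
        if sum(motif_span) != L:
            motif_span = (0, L)  # full-window or custom span
    if sum(motif_span) != L:
        raise ValueError("motif_span does not match training sequence length")

    X = _encode([s.upper() for s in true_sites])
    n, pc = len(true_sites), pseudocount
    q = _background(decoys, pc)
    freqs = np.empty((L, 4))
    for i in range(L):
        counts = np.bincount(X[:, i], minlength=4) + pc / 4
        freqs[i] = counts / (n + pc)
    assert np.allclose(freqs.sum(axis=1), 1, atol=1e-9)

    if model_type == "wmm":
        return ScorerModel("wmm", site_type, motif_span, np.log2(freqs / q),
                           pseudocount=pc)
    if model_type != "wam":
        raise ValueError(f"unknown model_type {model_type!r}")

    qc = _cond_background(decoys, pc)
    cond = np.empty((L - 1, 4, 4))
    for i in range(1, L):
        counts = np.full((4, 4), pc / 16)
        for row in X:
            counts[row[i - 1], row[i]] += 1
        f = counts / counts.sum(axis=1, keepdims=True)
        cond[i - 1] = np.log2(f / qc)
    return ScorerModel("wam", site_type, motif_span, np.log2(freqs[0] / q),
                       cond, pc)


def _span_bounds(model: ScorerModel, w: SpliceWindow) -> tuple[int, int]:
    """1-based inclusive window bounds of the model's motif span."""
    exonic, intronic = model.motif_span
    d1, d2 = w.dinucleotide_positions
    if exonic == 0 and intronic == len(w):  # full-window span
        return 1, len(w)
    if w.site_type == "donor_5ss":
        start = d1 - exonic
        end = d2 + (intronic - 2)
    else:
        start = d1 - (intronic - 2)
        end = d2 + exonic
    if start < 1 or end > len(w):
        raise ValueError("motif span exceeds window bounds")
    return start, end


def score(model: ScorerModel, w: SpliceWindow, edits: Optional[HaplotypeEdit] = None) -> float:
    """Score the window (with optional edits) under the model.

    Applies the edits, extracts the model's motif span around the
    consensus dinucleotide and returns the summed log2 odds; higher means
    a stronger site.
    """
    if model.site_type != w.site_type:
        raise ValueError("model/window site type mismatch")
    seq = apply_edits(w, edits)
    start, end = _span_bounds(model, w)
    motif = seq[start - 1 : end]
    idx = [_B2I[b] for b in motif]
    if model.model_type == "wmm":
        return float(sum(model.log_odds[i, x] for i, x in enumerate(idx)))
    total = float(model.log_odds[idx[0]])
    for i in range(1, len(idx)):
        total += float(model.cond_log_odds[i - 1, idx[i - 1], idx[i]])
    return total


def score_delta_lookup(model: ScorerModel, w: SpliceWindow, edits: HaplotypeEdit) -> float:
    """WMM-only fast path: score difference from the reference by table
    lookup at the edited positions (additivity of the WMM)."""
    if model.model_type != "wmm":
        raise ValueError("delta lookup is defined for WMM only")
    start, end = _span_bounds(model, w)
    delta = 0.0
    for pos, alt in edits.substitutions:
        if not start <= pos <= end:
            continue
        i = pos - start
        ref = w.sequence[pos - 1]
        delta += float(model.log_odds[i, _B2I[alt]] - model.log_odds[i, _B2I[ref]])
    return delta


def compound_impact(
    model: ScorerModel,
    w: SpliceWindow,
    variant: HaplotypeEdit,
    anchor: HaplotypeEdit,
) -> tuple[float, float]:
    """Impact of a variant alone and in cis with an anchor allele.

    Returns ``(delta_variant, delta_haplotype)`` where both deltas are
    against the reference window score. Variant and anchor must occupy
    distinct positions.
    """
    vpos = {p for p, _ in variant.substitutions}
    apos = {p for p, _ in anchor.substitutions}
    if vpos & apos:
        raise ValueError("variant and anchor edits overlap")
    ref = score(model, w)
    return (score(model, w, variant) - ref,
            score(model, w, variant + anchor) - ref)


def strongest_site(
    models: Mapping[str, ScorerModel],
    windows: Mapping[str, SpliceWindow],
    edits_by_site: Mapping[str, HaplotypeEdit],
) -> tuple[str, float]:
    """Report a variant's impact on the strongest affected splice site.

    Among sites whose window the variant maps into, the site with the
    larger reference-sequence score is selected and the impact (edited
    minus reference score) is reported there only. Ties break
    deterministically acceptor before donor, and are logged.
    """
    affected = [s for s, e in edits_by_site.items() if e is not None and len(e)]
    if not affected:
        raise ValueError("variant affects no splice window")
    refs = {s: score(models[s], windows[s]) for s in affected}
    best = max(refs.values())
    winners = sorted((s for s in affected if refs[s] == best),
                     key=lambda s: (s != "acceptor_3ss", s))
    if len(winners) > 1:
        logger.info("reference-score tie among %s; reporting %s", winners, winners[0])
    site = winners[0]
    return site, score(models[site], windows[site], edits_by_site[site]) - refs[site]
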