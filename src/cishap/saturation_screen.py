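"""Exhaustive splice-window saturation screen.

Enumerates every single-nucleotide substitution across a splice window's
flanks (excluding the consensus dinucleotide and the anchor-allele
position), scores each substitution alone and in cis with the anchor
allele, and classifies each point relative to the identity diagonal
(anchor decreases / increases the site score) and the reference score
(retention-increasing: the two-variant haplotype scores above the
reference). For a 162 bp window with one anchor this yields
3 x (162 - 2 - 1) = 477 simulated haplotypes per site.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .splice_scoring import (
    BASES, HaplotypeEdit, ScorerModel, SpliceWindow, score,
)

__all__ = ["ScreenRecord", "ScreenReport", "enumerate_snvs", "run_screen",
           "classify_point", "CLASS_NAMES"]

CLASS_NAMES = ("anchor_decreases", "anchor_increases", "retention_increasing")


@dataclass
class ScreenRecord:
    site_type: str
    window_position: int
    alt: str
    score_alone: float
    score_with_anchor: float
    reference_score: float

    @property
    def classes(self) -> frozenset[str]:
        return classify_point(self)


@dataclass
class ScreenReport:
    records: list[ScreenRecord]
    reference_scores: dict[str, float]
    anchor_deltas: dict[str, float]

    def counts(self, site_type: Optional[str] = None) -> dict[str, int]:
        recs = [r for r in self.records if site_type in (None, r.site_type)]
        return {c: sum(1 for r in recs if c in r.classes) for c in CLASS_NAMES}

    def n_records(self, site_type: str) -> int:
        return sum(1 for r in self.records if r.site_type == site_type)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            dict(
                site=r.site_type, position=r.window_position, alt=r.alt,
                score_alone=r.score_alone, score_with_anchor=r.score_with_anchor,
                ref_score=r.reference_score, classes=";".join(sorted(r.classes)),
            )
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def plot(self, path, site_type: str) -> None:
        """Scatter of score-alone vs score-with-anchor with the identity
        diagonal and reference-score crosshairs."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        recs = [r for r in self.records if r.site_type == site_type]
        x = [r.score_alone for r in recs]
        y = [r.score_with_anchor for r in recs]
        ref = self.reference_scores[site_type]
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(x, y, s=8, alpha=0.6, color="#555555")
        lo = min(x + y + [ref]) - 0.5
        hi = max(x + y + [ref]) + 0.5
        ax.plot([lo, hi], [lo, hi], "--", color="black", lw=0.8)
        ax.axvline(ref, ls="--", color="tab:blue", lw=0.8)
        ax.axhline(ref, ls="--", color="tab:blue", lw=0.8)
        ax.plot([ref], [ref + self.anchor_deltas[site_type]], "o",
                color="tab:blue", ms=8)
        ax.set_xlabel("score, variant alone")
        ax.set_ylabel("score, variant in cis with anchor")
        ax.set_title(site_type)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def enumerate_snvs(w: SpliceWindow, exclude_anchor: bool = True) -> list[tuple[int, str]]:
    """All single-base substitutions over the window flanks.

    Every window position except the two consensus-dinucleotide positions
    and (by default) the anchor position is mutated to its three
    alternative bases: ``3 * (L - 2 - n_excluded)`` edits. An anchor at a
    dinucleotide position contradicts the reference invariant and is a
    hard error.
    """
    d1, d2 = w.dinucleotide_positions
    excluded = {d1, d2}
    if exclude_anchor:
        if w.anchor_position is None:
            raise ValueError("window has no anchor position set")
        if w.anchor_position in excluded:
            raise ValueError("anchor at a consensus dinucleotide position")
        excluded.add(w.anchor_position)
    return [
        (pos, alt)
        for pos in range(1, len(w) + 1)
        if pos not in excluded
        for alt in BASES
        if alt != w.sequence[pos - 1]
    ]


def classify_point(r: ScreenRecord) -> frozenset[str]:
    """Diagonal and retention classes for one screen record.

    Strict inequalities throughout: a point exactly on the diagonal is in
    neither diagonal class; retention-increasing requires the two-variant
    haplotype to score strictly above the reference.
    """
    classes = set()
    if r.score_with_anchor < r.score_alone:
        classes.add("anchor_decreases")
    elif r.score_with_anchor > r.score_alone:
        classes.add("anchor_increases")
    if r.score_with_anchor > r.reference_score:
        classes.add("retention_increasing")
    return frozenset(classes)


def run_screen(
    models: Mapping[str, ScorerModel],
    windows: Mapping[str, SpliceWindow],
    anchor_edits: Optional[Mapping[str, HaplotypeEdit]] = None,
) -> ScreenReport:
    """Run the saturation screen over one or more splice windows.

    For every enumerated substitution of each window: score alone, score in
    cis with that window's anchor allele, and the window's reference score.
    The anchor edit defaults to the alternative allele recorded at the
    window's ``anchor_position`` (the transversion/transition must be
    supplied via ``anchor_edits`` when ambiguous — by default the anchor's
    edit is taken from ``anchor_edits``; a missing entry is an error).
    """
    records: list[ScreenRecord] = []
    refs: dict[str, float] = {}
    anchor_deltas: dict[str, float] = {}
    for site, w in windows.items():
        model = models[site]
        if anchor_edits is None or site not in anchor_edits:
            raise ValueError(f"no anchor edit supplied for {site}")
        anchor = anchor_edits[site]
        ref = score(model, w)
        refs[site] = ref
        anchor_deltas[site] = score(model, w, anchor) - ref
        for pos, alt in enumerate_snvs(w):
            e = HaplotypeEdit.single(pos, alt)
            records.append(
                ScreenRecord(
                    site_type=site,
                    window_position=pos,
                    alt=alt,
                    score_alone=score(model, w, e),
                    score_with_anchor=score(model, w, e + anchor),
                    reference_score=ref,
                )
            )
    return ScreenReport(records, refs, anchor_deltas)
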