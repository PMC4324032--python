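"""Peak-to-gene annotation: distance to the nearest translational start and
classification of binding sites relative to coding sequences.

A bound region is *promoter-proximal* when it lies less than 200 bp upstream
of a translational start site (the classic operator position for a repressor
overlapping the promoter), and *intragenic* when it sits more than 200 bp
downstream of a start codon inside a coding sequence.  Sites within the first
200 bp of a CDS are kept apart as ``start_overlap`` rather than silently
folded into either published class, and everything else is ``distal``.

Distances are signed along the gene's own strand: negative means upstream of
the start codon, positive means downstream (into the gene), irrespective of
which genomic strand the gene lives on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import circ_distance, circ_signed_delta, reverse_complement

CATEGORIES = ("promoter_proximal", "intragenic", "start_overlap", "distal")

#: upstream/downstream cut used for both published classes, in bp
PROXIMAL_BP = 200


@dataclass(frozen=True)
class GeneModel:
    """A CDS with an explicit translational start.

    ``start_codon_pos`` is the first base of the start codon in forward
    (1-based) genome coordinates; for a minus-strand gene the CDS extends to
    coordinates *below* it, so ``end < start_codon_pos`` there.
    """

    name: str
    start_codon_pos: int
    end: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start_codon_pos == self.end:
            raise ValueError(f"degenerate gene {self.name!r}")
        lo, hi = self.span
        if lo >= hi:
            raise ValueError(f"degenerate gene {self.name!r}")

    @classmethod
    def from_forward(cls, name: str, start: int, end: int, strand: str) -> "GeneModel":
        """Build from forward-strand (start < end) coordinates, GFF3-style."""
        if start >= end:
            raise ValueError(f"gene {name!r}: start must be < end in forward coords")
        if strand == "+":
            return cls(name, start, end, "+")
        return cls(name, end, start, "-")

    @property
    def span(self) -> tuple[int, int]:
        """(low, high) forward coordinates of the CDS, inclusive."""
        return (min(self.start_codon_pos, self.end), max(self.start_codon_pos, self.end))

    @property
    def length(self) -> int:
        lo, hi = self.span
        return hi - lo + 1

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi


def nearest_start(
    peak_pos: int,
    genes: Sequence[GeneModel],
    genome_length: Optional[int] = None,
) -> tuple[GeneModel, int]:
    """Gene whose translational start is closest to ``peak_pos``.

    The signed distance is measured along the gene's strand (negative =
    upstream of the start codon).  Ties on |distance| are broken toward the
    gene for which the peak is upstream.
    """
    if not genes:
        raise ValueError("empty gene set")
    best_gene, best_d, best_key = None, None, None
    for g in genes:
        raw = peak_pos - g.start_codon_pos if g.strand == "+" else g.start_codon_pos - peak_pos
        d = int(circ_signed_delta(raw, 0, genome_length))
        key = (abs(d), 0 if d < 0 else 1)
        if best_key is None or key < best_key:
            best_gene, best_d, best_key = g, d, key
    return best_gene, best_d


def classify(
    peak_pos: int,
    signed_distance: int,
    nearest_gene: GeneModel,
    genes: Sequence[GeneModel],
) -> str:
    """Category of a peak given its signed distance to the nearest start."""
    d = signed_distance
    if -PROXIMAL_BP <= d < 0:
        return "promoter_proximal"
    if 0 <= d <= PROXIMAL_BP and nearest_gene.contains(peak_pos):
        return "start_overlap"
    if d > PROXIMAL_BP and any(g.contains(peak_pos) for g in genes):
        return "intragenic"
    return "distal"


@dataclass(frozen=True)
class PeakAnnotation:
    """One consensus peak placed relative to the annotation and the motif scan."""

    max_position: int
    chip_score: float
    nearest_gene: str
    signed_distance: int
    category: str
    motif_associated: bool
    hit_position: Optional[int] = None
    hit_strand: Optional[str] = None
    hit_p_value: Optional[float] = None
    match_count: Optional[int] = None


def annotate_peaks(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    genome_length: Optional[int] = None,
    hits: Optional[Sequence] = None,
    flank: int = 50,
    genome: Optional[str] = None,
    consensus: Optional[str] = None,
) -> list[PeakAnnotation]:
    """Annotate consensus peaks with nearest-start distance, category and motif status.

    ``hits`` (motif scan output) is optional; when given, a peak is
    motif-associated iff a hit starts within ``flank`` bp of the peak maximum,
    and — if ``genome`` and ``consensus`` are also given — the number of
    consensus-matching nucleotides at the associated box is recorded.
    """
    from .motif import associate_hits, match_count  # local import, no cycle at load

    assoc = [None] * len(peaks)
    if hits is not None:
        assoc = associate_hits(peaks, hits, flank=flank, genome_length=genome_length)

    out = []
    for peak, hit in zip(peaks, assoc):
        gene, d = nearest_start(peak.max_position, genes, genome_length)
        cat = classify(peak.max_position, d, gene, genes)
        mcount = None
        if hit is not None and genome is not None and consensus is not None:
            w = len(consensus)
            start0 = hit.position - 1
            if start0 + w <= len(genome):
                window = genome[start0 : start0 + w]
            else:  # wrap around the origin of a circular genome
                window = genome[start0:] + genome[: start0 + w - len(genome)]
            if hit.strand == "-":
                window = reverse_complement(window)
            mcount = match_count(window, consensus)
        out.append(
            PeakAnnotation(
                max_position=int(peak.max_position),
                chip_score=float(peak.chip_score),
                nearest_gene=gene.name,
                signed_distance=int(d),
                category=cat,
                motif_associated=hit is not None,
                hit_position=None if hit is None else int(hit.position),
                hit_strand=None if hit is None else hit.strand,
                hit_p_value=None if hit is None else float(hit.p_value),
                match_count=mcount,
            )
        )
    return out


def annotations_frame(annotations: Iterable[PeakAnnotation]) -> pd.DataFrame:
    cols = [
        "max_position",
        "chip_score",
        "nearest_gene",
        "signed_distance",
        "category",
        "motif_associated",
        "hit_position",
        "hit_strand",
        "hit_p_value",
        "match_count",
    ]
    rows = [{c: getattr(a, c) for c in cols} for a in annotations]
    return pd.DataFrame(rows, columns=cols)


def summarize(annotations: Sequence[PeakAnnotation]) -> dict[str, pd.DataFrame]:
    """Summary tables: per-peak, category counts, score vs consensus match,
    score vs distance to the nearest start (split by motif presence)."""
    per_peak = annotations_frame(annotations)
    counts = per_peak["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    category_counts = counts.rename_axis("category").reset_index(name="count")
    with_box = per_peak[per_peak["motif_associated"]]
    score_vs_match = with_box[["max_position", "chip_score", "match_count", "category"]].copy()
    score_vs_match["intragenic"] = score_vs_match["category"] == "intragenic"
    score_vs_distance = per_peak[
        ["max_position", "chip_score", "signed_distance", "motif_associated"]
    ].copy()
    return {
        "per_peak": per_peak,
        "category_counts": category_counts,
        "score_vs_match": score_vs_match.drop(columns="category"),
        "score_vs_distance": score_vs_distance,
    }
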