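"""Readers and writers for the pipeline's file formats.

Internally all coordinates are 1-based inclusive (GFF3-native); BED and
bedGraph output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModel, PeakAnnotation, annotations_frame
from .motif import MotifHit
from .normalize import RatioTrack
from .peaks import ConsensusPeak, Peak

PROBE_COLUMNS = ["probe_id", "position", "ip", "wce", "replicate"]


def write_fasta(sequence: str, path, seqid: str = "chromosome") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=seqid, description="")], path, "fasta")


def read_fasta(path) -> tuple[str, str]:
    """Returns (seqid, sequence) of the first record."""
    record = next(SeqIO.parse(path, "fasta"))
    return record.id, str(record.seq).upper()


def write_genes_gff3(
    genes: Sequence[GeneModel], path, seqid: str = "chromosome",
    genome_length: Optional[int] = None,
) -> None:
    lines = ["##gff-version 3"]
    if genome_length is not None:
        lines.append(f"##sequence-region {seqid} 1 {genome_length}")
    for g in genes:
        lo, hi = g.span
        lines.append(
            "\t".join(
                [seqid, "zurchip", "CDS", str(lo), str(hi), ".", g.strand, "0",
                 f"ID={g.name}"]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genes_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for f in db.features_of_type("CDS", order_by="start"):
        name = f.attributes.get("ID", [f.id])[0]
        genes.append(GeneModel.from_forward(name, f.start, f.end, f.strand))
    return genes


def write_probes_tsv(signals: pd.DataFrame, path) -> None:
    signals.to_csv(path, sep="\t", index=False)


def read_probes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(truth, path) -> None:
    rows = [asdict(s) for s in truth.sites]
    pd.DataFrame(
        rows, columns=["center", "strand", "fold", "category", "box_start", "has_box"]
    ).to_csv(path, sep="\t", index=False)


def write_track_tsv(track: RatioTrack, path) -> None:
    pd.DataFrame(
        {
            "position": track.positions,
            "m": track.m,
            "a": track.a,
            "replicate": track.replicate,
            "corrected": track.corrected,
        }
    ).to_csv(path, sep="\t", index=False)


def read_track_tsv(path) -> RatioTrack:
    df = pd.read_csv(path, sep="\t")
    return RatioTrack(
        df["position"].to_numpy(),
        df["m"].to_numpy(),
        df["a"].to_numpy(),
        replicate=str(df["replicate"].iloc[0]) if len(df) else "",
        corrected=bool(df["corrected"].iloc[0]) if len(df) else False,
    )


def write_bedgraph(
    track: RatioTrack, path, seqid: str = "chromosome",
    genome_length: Optional[int] = None,
) -> None:
    """One interval of one probe-spacing per probe, 0-based half-open."""
    pos = track.positions
    spacing = int(np.min(np.diff(pos))) if len(pos) > 1 else 1
    start = pos - 1
    end = start + spacing
    if genome_length is not None:
        end = np.minimum(end, genome_length)
    pd.DataFrame(
        {"chrom": seqid, "start": start, "end": end, "value": track.m}
    ).to_csv(path, sep="\t", index=False, header=False)


def write_peaks_tsv(peaks: Sequence[Peak], path) -> None:
    pd.DataFrame([asdict(p) for p in peaks]).to_csv(path, sep="\t", index=False)


def write_consensus_tsv(consensus: Sequence[ConsensusPeak], path) -> None:
    rows = []
    for c in consensus:
        row = {"max_position": c.max_position, "chip_score": c.chip_score}
        for tag, p in (("rep1", c.rep1), ("rep2", c.rep2)):
            for key, val in asdict(p).items():
                row[f"{tag}_{key}"] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_consensus_bed(
    consensus: Sequence[ConsensusPeak], path, seqid: str = "chromosome"
) -> None:
    """BED6: one record per consensus peak maximum, score = ChIPScore*100
    capped at 1000."""
    lines = []
    for i, c in enumerate(consensus):
        score = min(1000, int(round(c.chip_score * 100)))
        lines.append(
            "\t".join(
                [seqid, str(c.max_position - 1), str(c.max_position),
                 f"peak_{i + 1}", str(score), "."]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def write_hits_gff3(
    hits: Sequence[MotifHit], width: int, path, seqid: str = "chromosome"
) -> None:
    lines = ["##gff-version 3"]
    for i, h in enumerate(hits):
        score = -np.log10(h.p_value) if h.p_value > 0 else 999.0
        lines.append(
            "\t".join(
                [seqid, "zurchip", "TF_binding_site", str(h.position),
                 str(h.position + width - 1), f"{score:.3f}", h.strand, ".",
                 f"ID=hit_{i + 1}"]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_hits_tsv(hits: Sequence[MotifHit], path) -> None:
    pd.DataFrame([asdict(h) for h in hits]).to_csv(path, sep="\t", index=False)


def write_annotations_tsv(annotations: Sequence[PeakAnnotation], path) -> None:
    annotations_frame(annotations).to_csv(path, sep="\t", index=False)


def write_summary_tables(summary: dict, outdir, prefix: str = "summary") -> None:
    for name, df in summary.items():
        df.to_csv(f"{outdir}/{prefix}_{name}.tsv", sep="\t", index=False)
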