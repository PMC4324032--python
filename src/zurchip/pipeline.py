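"""End-to-end orchestration: simulate -> normalize -> call peaks -> scan -> annotate.

A run is fully determined by a :class:`RunConfig`; all randomness flows from
its single top-level seed.  Every stage writes its artifacts under the output
directory and the run ends with a ``manifest.json`` recording parameters,
library versions, per-stage counts, and SHA-256 checksums of every input and
output file, so reruns with an identical config are byte-for-byte verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels
import yaml

from . import __version__, io
from .annotate import annotate_peaks, summarize
from .motif import build_pwm, read_meme, scan
from .normalize import compute_ma, loess_correct
from .peaks import PeakCallingParams, call_peaks, chip_scores, consensus_peaks
from .simulate import (
    DEFAULT_BOX,
    SimParams,
    generate_genome,
    plant_sites,
    sample_box_alignment,
    simulate_probe_signals,
)

logger = logging.getLogger("zurchip")

ALL_STAGES = ("simulate", "normalize", "callpeaks", "scan", "annotate")


@dataclass
class RunConfig:
    outdir: str = "zurchip_run"
    seed: int = 0
    sim: SimParams = field(default_factory=SimParams)
    peak_params: PeakCallingParams = field(default_factory=PeakCallingParams)
    span: float = 0.4
    p_threshold: float = 1e-6
    flank: int = 50
    stages: tuple = ALL_STAGES
    n_replicates: int = 2
    # inputs used when the simulate stage is skipped
    genome_fasta: Optional[str] = None
    annotation_gff: Optional[str] = None
    probe_tables: Optional[tuple] = None
    pwm_file: Optional[str] = None
    # PWM built from a sampled alignment around the planted box when simulating
    pwm_nsites: int = 40
    pwm_mutation_rate: float = 0.05
    box: str = DEFAULT_BOX

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            for key in ("dye_bias_coeffs", "enrichment_range", "site_mix"):
                if key in raw["sim"]:
                    raw["sim"][key] = tuple(raw["sim"][key])
            raw["sim"] = SimParams(**raw["sim"])
        if "peak_params" in raw:
            raw["peak_params"] = PeakCallingParams(**raw["peak_params"])
        for key in ("stages", "probe_tables"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir")  # the manifest must not depend on where the run lives
    return json.loads(json.dumps(d, default=list))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    seqid = "chromosome"
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = [int(s) for s in ss.generate_state(config.n_replicates + 1)[1:]]

    manifest: dict = {
        "versions": {
            "zurchip": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "parameters": _params_dict(config),
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], counts: dict) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
                "counts": counts,
            }
        )
        logger.info("stage %s: %s", stage, counts)

    def require(stage: str, path, what: str) -> Path:
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                f"{stage} stage requires {what} file: {path}"
            )
        return Path(path)

    # ---- simulate ---------------------------------------------------------
    genome = genes = truth = None
    probe_files: list[Path] = []
    if "simulate" in stages:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        genome, genes = generate_genome(sim)
        genome, truth = plant_sites(genome, genes, config.box, sim)
        genome_fasta = outdir / "genome.fasta"
        annotation_gff = outdir / "genes.gff3"
        truth_tsv = outdir / "truth.tsv"
        io.write_fasta(genome, genome_fasta, seqid)
        io.write_genes_gff3(genes, annotation_gff, seqid, sim.genome_length)
        io.write_truth_tsv(truth, truth_tsv)
        outputs = [genome_fasta, annotation_gff, truth_tsv]
        for r, seed in enumerate(rep_seeds, start=1):
            signals = simulate_probe_signals(
                sim.genome_length, truth, sim, seed, replicate=f"rep{r}"
            )
            p = outdir / f"probes_rep{r}.tsv"
            io.write_probes_tsv(signals, p)
            probe_files.append(p)
        alignment = sample_box_alignment(
            truth.box, config.pwm_nsites, config.pwm_mutation_rate, seed=config.seed
        )
        pwm = build_pwm(alignment)
        pwm_file = outdir / "pwm.meme"
        from .motif import write_meme

        write_meme(pwm, pwm_file, name="operator_box")
        outputs += probe_files + [pwm_file]
        record(
            "simulate",
            outputs,
            {"genes": len(genes), "planted_sites": len(truth.sites),
             "probes": sim.genome_length // sim.probe_spacing},
        )
    else:
        genome_fasta = config.genome_fasta
        annotation_gff = config.annotation_gff
        pwm_file = config.pwm_file
        probe_files = [Path(p) for p in (config.probe_tables or ())]

    genome_length = config.sim.genome_length
    if genome is None and genome_fasta is not None and Path(genome_fasta).exists():
        seqid, genome = io.read_fasta(genome_fasta)
        genome_length = len(genome)

    # ---- normalize --------------------------------------------------------
    tracks = []
    if "normalize" in stages:
        if not probe_files:
            raise FileNotFoundError("normalize stage requires probe tables: none given")
        outputs = []
        for r, pf in enumerate(probe_files, start=1):
            require("normalize", pf, "probe table")
            signals = io.read_probes_tsv(pf)
            corrected = loess_correct(compute_ma(signals), span=config.span)
            tracks.append(corrected)
            tsv = outdir / f"corrected_rep{r}.tsv"
            bg = outdir / f"corrected_rep{r}.bedgraph"
            io.write_track_tsv(corrected, tsv)
            io.write_bedgraph(corrected, bg, seqid, genome_length)
            outputs += [tsv, bg]
        record("normalize", outputs, {"replicates": len(tracks),
                                      "probes": len(tracks[0]) if tracks else 0})

    # ---- callpeaks --------------------------------------------------------
    consensus = []
    if "callpeaks" in stages:
        if not tracks:
            raise FileNotFoundError(
                "callpeaks stage requires corrected tracks: run normalize first"
            )
        scored = []
        outputs = []
        for r, track in enumerate(tracks, start=1):
            peaks, smoothed = call_peaks(track, config.peak_params, genome_length)
            rep_scored = chip_scores(peaks)
            scored.append(rep_scored)
            ptsv = outdir / f"peaks_rep{r}.tsv"
            sbg = outdir / f"smoothed_rep{r}.bedgraph"
            io.write_peaks_tsv(rep_scored, ptsv)
            io.write_bedgraph(smoothed, sbg, seqid, genome_length)
            outputs += [ptsv, sbg]
        consensus = consensus_peaks(
            scored[0], scored[1], config.peak_params, genome_length
        )
        ctsv = outdir / "consensus_peaks.tsv"
        cbed = outdir / "consensus_peaks.bed"
        io.write_consensus_tsv(consensus, ctsv)
        io.write_consensus_bed(consensus, cbed, seqid)
        outputs += [ctsv, cbed]
        record(
            "callpeaks",
            outputs,
            {"peaks_per_replicate": [len(s) for s in scored],
             "consensus_peaks": len(consensus)},
        )

    # ---- scan -------------------------------------------------------------
    hits = []
    pwm = None
    if "scan" in stages:
        require("scan", genome_fasta, "genome FASTA")
        require("scan", pwm_file, "PWM (MEME format)")
        pwm = read_meme(pwm_file)
        hits = scan(
            genome, pwm, p_threshold=config.p_threshold,
            circular=config.peak_params.circular,
        )
        hgff = outdir / "hits.gff3"
        htsv = outdir / "hits.tsv"
        io.write_hits_gff3(hits, pwm.width, hgff, seqid)
        io.write_hits_tsv(hits, htsv)
        record("scan", [hgff, htsv], {"hits": len(hits)})

    # ---- annotate ---------------------------------------------------------
    if "annotate" in stages:
        require("annotate", annotation_gff, "annotation (GFF3)")
        genes = io.read_genes_gff3(annotation_gff)
        annotations = annotate_peaks(
            consensus, genes,
            genome_length=genome_length if config.peak_params.circular else None,
            hits=hits if "scan" in stages else None,
            flank=config.flank, genome=genome,
            consensus=pwm.consensus if pwm is not None else None,
        )
        atsv = outdir / "annotations.tsv"
        io.write_annotations_tsv(annotations, atsv)
        summary = summarize(annotations)
        io.write_summary_tables(summary, outdir)
        outputs = [atsv] + [outdir / f"summary_{k}.tsv" for k in summary]
        cat = {
            c: int((summary["per_peak"]["category"] == c).sum())
            for c in summary["per_peak"]["category"].unique()
        }
        record("annotate", outputs, {"annotated_peaks": len(annotations),
                                     "categories": cat})

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
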