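"""Shared fixtures: the default synthetic study, run once per session."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import zurchip as z
from zurchip.simulate import sample_box_alignment


@pytest.fixture(scope="session")
def default_study():
    """Full default synthetic study (200 kb circular genome, 20 planted sites
    at 8-32 fold, two replicates, fixed seed) run end to end through the
    library: simulate -> normalize -> call peaks -> consensus -> scan ->
    annotate."""
    master = 1
    sim = z.SimParams(seed=master)
    genome, genes = z.generate_genome(sim)
    genome, truth = z.plant_sites(genome, genes, z.DEFAULT_BOX, sim)
    ss = np.random.SeedSequence(master)
    rep_seeds = [int(s) for s in ss.generate_state(3)[1:]]
    params = z.PeakCallingParams()
    tracks, scored = [], []
    for r, seed in enumerate(rep_seeds, start=1):
        signals = z.simulate_probe_signals(sim.genome_length, truth, sim, seed, f"rep{r}")
        track = z.loess_correct(z.compute_ma(signals))
        tracks.append(track)
        peaks, _ = z.call_peaks(track, params, sim.genome_length)
        scored.append(z.chip_scores(peaks))
    consensus = z.consensus_peaks(scored[0], scored[1], params, sim.genome_length)
    pwm = z.build_pwm(sample_box_alignment(truth.box, seed=master))
    hits = z.scan(genome, pwm, p_threshold=1e-6, circular=True)
    annotations = z.annotate_peaks(
        consensus, genes, genome_length=sim.genome_length, hits=hits,
        genome=genome, consensus=pwm.consensus,
    )
    return SimpleNamespace(
        sim=sim, genome=genome, genes=genes, truth=truth, params=params,
        tracks=tracks, scored=scored, consensus=consensus, pwm=pwm, hits=hits,
        annotations=annotations,
    )
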