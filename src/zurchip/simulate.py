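"""Synthetic two-color tiling-array ChIP dataset with planted operator sites.

The generator emulates the measured object of a bacterial ChIP-on-chip
experiment: a circular chromosome densely covered by coding sequences, a set
of planted 20-nt operator boxes, probes at fixed spacing, and per-probe
IP/WCE intensity pairs for independent replicates.  The generative model is

    log2(WCE)  ~  Normal(wce_log_mean, wce_log_sd)                per probe
    E(p)       =  sum over sites  log2(fold) * max(0, 1 - d(p)/W)
    IP         =  WCE * 2 ** (E + g(A) + eps),   eps ~ Normal(0, sd)

where d(p) is the circular distance from probe p to a planted site centre,
W the sonicated-fragment half-width (a triangular first-order model of
fragment coverage), and g a polynomial dye bias evaluated at the pre-noise
average log2 intensity A = log2(WCE) + E/2.  Identical seeds give
bit-identical output; replicates share the enrichment structure but draw
independent WCE and noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import circ_distance, reverse_complement
from .annotate import GeneModel, classify, nearest_start

#: Default planted operator: a synthetic stand-in 20-nt perfect palindrome in
#: the style of Fur-family (Fur/Zur/PerR) boxes.  It is used only by the
#: synthetic study; real analyses supply their own aligned sites.
DEFAULT_BOX = "TAAATCGTAATTACGATTTA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Study conditions of the synthetic tiling-array experiment.

    Defaults describe a 200 kb circular chromosome tiled at 11 bp (29 probes
    span ~320 bp, matching the smoothing window of the peak caller), 500 bp
    sonication half-width, 20 planted sites at 8-32 fold enrichment, and a
    mildly curved polynomial dye bias on the MA cloud.
    """

    genome_length: int = 200_000
    gc_content: float = 0.435  # B. subtilis-like
    probe_spacing: int = 11
    fragment_width: int = 500
    wce_log_mean: float = 10.0
    wce_log_sd: float = 1.0
    replicate_noise_sd: float = 0.25
    #: ascending polynomial coefficients of g(A), i.e. g(A) = c0 + c1*A + c2*A^2 ...
    dye_bias_coeffs: tuple = (-0.3, 0.25, -0.02)
    n_sites: int = 20
    enrichment_range: tuple = (8.0, 32.0)
    min_site_spacing: int = 2000
    #: fraction of sites that are promoter-proximal / intragenic / intergenic
    site_mix: tuple = (0.5, 0.5, 0.0)
    #: fraction of planted sites whose box sequence is written into the genome
    box_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError(f"gc_content must be in (0, 1), got {self.gc_content}")
        if self.genome_length <= 10 * self.fragment_width:
            raise ValueError("genome_length must exceed 10 * fragment_width")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.enrichment_range[0] < 1 or self.enrichment_range[1] < self.enrichment_range[0]:
            raise ValueError("enrichment_range must satisfy 1 <= min <= max")
        for name in ("wce_log_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.site_mix) != 3 or min(self.site_mix) < 0 or sum(self.site_mix) <= 0:
            raise ValueError("site_mix must be 3 non-negative fractions")
        if not 0.0 <= self.box_fraction <= 1.0:
            raise ValueError("box_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedSite:
    center: int
    strand: str
    fold: float
    category: str
    box_start: int
    has_box: bool


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a synthetic run: planted sites, gene set, box sequence."""

    sites: tuple
    genes: tuple
    box: str
    genome_length: int


def generate_genome(params: SimParams) -> tuple[str, list[GeneModel]]:
    """Random circular chromosome plus a non-overlapping CDS annotation.

    Gene and gap lengths are drawn from ranges typical of a compact bacterial
    chromosome (genes 400-1500 bp, gaps 60-400 bp), which leaves well over
    half the genome coding.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng([params.seed, 0])
    gc = params.gc_content
    L = params.genome_length
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=L, p=probs)
    genome = bytes(_BASES[idx]).decode("ascii")

    genes: list[GeneModel] = []
    pos = 1
    while True:
        gap = int(rng.integers(60, 400))
        glen = int(rng.integers(400, 1500))
        start = pos + gap
        end = start + glen - 1
        if end > L - 60:  # genes never wrap the origin
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel.from_forward(f"gene{len(genes) + 1:04d}", start, end, strand))
        pos = end + 1
    return genome, genes


def _category_counts(n_sites: int, mix: Sequence[float]) -> tuple[int, int, int]:
    total = float(sum(mix))
    n_pp = int(round(n_sites * mix[0] / total))
    n_ig = int(round(n_sites * mix[1] / total))
    n_ig = min(n_ig, n_sites - n_pp)
    return n_pp, n_ig, n_sites - n_pp - n_ig


def plant_sites(
    genome: str,
    genes: Sequence[GeneModel],
    box,
    params: SimParams,
    sites: Optional[Sequence[tuple]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, SimTruth]:
    """Write operator boxes into the genome and record the ground truth.

    ``box`` is the operator sequence (or any object with a ``consensus``
    attribute, e.g. a Pwm).  Sites are placed strand-aware by category:
    promoter-proximal centres fall 80-180 bp upstream of a translational
    start, intragenic centres at least 280 bp inside a CDS and 280 bp from
    its stop, intergenic centres in gaps flanked by diverging starts.  All
    pairwise (circular) centre distances respect ``min_site_spacing``.

    ``sites`` optionally gives explicit placements as tuples
    ``(box_start, strand, fold, category)``, bypassing random placement.
    """
    box = getattr(box, "consensus", box)
    if not box or set(box.upper()) - set("ACGT"):
        raise ValueError("box must be a non-empty ACGT sequence")
    box = box.upper()
    w = len(box)
    half = w // 2
    L = len(genome)
    if rng is None:
        rng = np.random.default_rng([params.seed, 1])
    arr = bytearray(genome.encode("ascii"))

    placed: list[PlantedSite] = []

    def write_site(box_start: int, strand: str, fold: float, category: str, has_box: bool):
        if box_start < 1 or box_start + w - 1 > L:
            raise ValueError(f"box at {box_start} falls outside the genome")
        seq = box if strand == "+" else reverse_complement(box)
        if has_box:
            arr[box_start - 1 : box_start - 1 + w] = seq.encode("ascii")
        placed.append(
            PlantedSite(
                center=box_start + half,
                strand=strand,
                fold=float(fold),
                category=category,
                box_start=box_start,
                has_box=has_box,
            )
        )

    if sites is not None:
        for box_start, strand, fold, category in sites:
            write_site(int(box_start), strand, fold, category, True)
        return bytes(arr).decode("ascii"), SimTruth(tuple(placed), tuple(genes), box, L)

    n_pp, n_ig, n_inter = _category_counts(params.n_sites, params.site_mix)
    lo_f, hi_f = params.enrichment_range
    ig_genes = [g for g in genes if g.length >= 2 * 280 + 60]
    gaps = []
    for a, b in zip(genes, genes[1:]):
        gap_lo, gap_hi = a.span[1] + 1, b.span[0] - 1
        if a.strand == "+" and b.strand == "-" and gap_hi - gap_lo + 1 >= w + 20:
            gaps.append((gap_lo, gap_hi))

    def place(category: str):
        for _ in range(5000):
            if category == "promoter_proximal":
                g = genes[int(rng.integers(len(genes)))]
                d = int(rng.integers(80, 181))
                center = g.start_codon_pos - d if g.strand == "+" else g.start_codon_pos + d
                strand = g.strand
            elif category == "intragenic":
                if not ig_genes:
                    break
                g = ig_genes[int(rng.integers(len(ig_genes)))]
                d = int(rng.integers(280, g.length - 280 + 1))
                center = g.start_codon_pos + d if g.strand == "+" else g.start_codon_pos - d
                strand = g.strand
            else:
                if not gaps:
                    break
                gap_lo, gap_hi = gaps[int(rng.integers(len(gaps)))]
                center = int(rng.integers(gap_lo + half, gap_hi - half + 1))
                strand = "+" if rng.random() < 0.5 else "-"
            box_start = center - half
            if box_start < 1 or box_start + w - 1 > L:
                continue
            if any(
                circ_distance(center, s.center, L) < params.min_site_spacing for s in placed
            ):
                continue
            # the recorded category must be what the nearest-start rules say,
            # robustly to the array's positional resolution (+- 50 bp): dense
            # gene packing can put a site closer to a neighbour's start than
            # to the start of the gene it was placed against
            want = "distal" if category == "intergenic" else category
            stable = True
            for delta in (-50, 0, 50):
                p = (center + delta - 1) % L + 1
                g_near, d_near = nearest_start(p, genes, L)
                if classify(p, d_near, g_near, genes) != want:
                    stable = False
                    break
            if not stable:
                continue
            fold = 2.0 ** rng.uniform(math.log2(lo_f), math.log2(hi_f))
            has_box = bool(rng.random() < params.box_fraction)
            write_site(box_start, strand, fold, category, has_box)
            return
        raise ValueError(
            f"genome too small to place {params.n_sites} non-overlapping sites "
            f"(failed at category {category!r})"
        )

    for category, count in (
        ("promoter_proximal", n_pp),
        ("intragenic", n_ig),
        ("intergenic", n_inter),
    ):
        for _ in range(count):
            place(category)

    return bytes(arr).decode("ascii"), SimTruth(tuple(placed), tuple(genes), box, L)


def probe_positions(genome_length: int, probe_spacing: int) -> np.ndarray:
    """1-based probe centres at fixed spacing; count = floor(L / spacing)."""
    n = genome_length // probe_spacing
    return 1 + probe_spacing * np.arange(n, dtype=np.int64)


def expected_enrichment(
    positions: np.ndarray, truth: SimTruth, params: SimParams
) -> np.ndarray:
    """Noise-free expected log2 enrichment at each probe.

    Triangular kernel of half-width ``fragment_width`` around each planted
    site, scaled by log2 of the site's fold enrichment; kernels wrap around
    the circular origin.  Probes beyond the kernel support of every site get
    exactly zero.
    """
    E = np.zeros(len(positions))
    for site in truth.sites:
        d = circ_distance(positions, site.center, truth.genome_length).astype(float)
        E += math.log2(site.fold) * np.clip(1.0 - d / params.fragment_width, 0.0, 1.0)
    return E


def dye_bias(a: np.ndarray, params: SimParams) -> np.ndarray:
    """Polynomial dye bias g(A) in log2 units (ascending coefficients)."""
    return np.polynomial.polynomial.polyval(np.asarray(a, float), params.dye_bias_coeffs)


def simulate_probe_signals(
    genome_length: int,
    truth: SimTruth,
    params: SimParams,
    replicate_seed: int,
    replicate: str = "",
) -> pd.DataFrame:
    """Raw two-channel probe intensities for one replicate.

    Columns: probe_id, position, ip, wce.  Two calls with different
    ``replicate_seed`` values share the planted enrichment structure but draw
    independent control-channel intensities and log2 noise.
    """
    positions = probe_positions(genome_length, params.probe_spacing)
    E = expected_enrichment(positions, truth, params)
    rng = np.random.default_rng(replicate_seed)
    log2_wce = rng.normal(params.wce_log_mean, params.wce_log_sd, len(positions))
    noise = rng.normal(0.0, params.replicate_noise_sd, len(positions))
    a_pre = log2_wce + E / 2.0  # pre-noise average log2 intensity
    g = dye_bias(a_pre, params)
    wce = 2.0 ** log2_wce
    ip = wce * 2.0 ** (E + g + noise)
    rep = replicate or f"rep{replicate_seed}"
    return pd.DataFrame(
        {
            "probe_id": [f"probe_{i:06d}" for i in range(len(positions))],
            "position": positions,
            "ip": ip,
            "wce": wce,
            "replicate": rep,
        }
    )


def sample_box_alignment(
    box: str = DEFAULT_BOX,
    n_sites: int = 40,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> list[str]:
    """Aligned operator instances for PWM construction: the consensus with
    independent per-position substitutions at ``mutation_rate``."""
    rng = np.random.default_rng([seed, 2])
    bases = "ACGT"
    out = []
    for _ in range(n_sites):
        chars = list(box)
        for i, c in enumerate(chars):
            if rng.random() < mutation_rate:
                chars[i] = bases[int(rng.integers(4))]
        out.append("".join(chars))
    return out
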