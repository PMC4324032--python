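"""Position-weight-matrix construction, exact p-values, and genome scanning.

A PWM is built from user-supplied aligned binding sites (per-column base
counts plus a pseudocount).  Windows are scored by the log-odds, in bits, of
the window under the motif model against a zero-order background.  Hit
significance is the exact tail probability P(score >= s) of a random
background sequence of the motif's width, obtained by dynamic programming
over the per-column score distribution.

Per-column log-odds are quantized on a fixed grid (1e-3 bits by default) and
that quantized score is what the scanner, the p-value DP and any enumeration
all use, so the DP tail probabilities are exact for the score function
actually applied; the quantization perturbs the ideal log-odds of a
width-``w`` window by at most ``w``/2000 bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._util import circ_distance, reverse_complement

ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(ALPHABET)}


class Pwm:
    """4 x width probability matrix with a zero-order background model."""

    def __init__(
        self,
        probs: np.ndarray,
        background: Optional[np.ndarray] = None,
        counts: Optional[np.ndarray] = None,
        nsites: Optional[int] = None,
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError("probs must be a 4 x width matrix with width >= 1")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each probs column must be non-negative and sum to 1")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not math.isclose(background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be a 4-vector summing to 1")
        if np.any(background <= 0):
            raise ValueError("background frequencies must be positive")
        self.probs = probs
        self.background = background
        self.counts = None if counts is None else np.asarray(counts, dtype=float)
        self.nsites = nsites

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        # argmax takes the first (alphabetically smallest) base on ties
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))

    def log_odds(self, background: Optional[np.ndarray] = None) -> np.ndarray:
        """4 x width matrix of log2(p / background), in bits."""
        bg = self.background if background is None else np.asarray(background, dtype=float)
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / bg[:, None])

    def information_content(self) -> float:
        """Total information content in bits relative to a uniform background."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / 0.25), 0.0)
        return float(terms.sum())


def build_pwm(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.25,
    background: Optional[np.ndarray] = None,
) -> Pwm:
    """PWM from equal-length aligned sites over {A,C,G,T}.

    probs = (counts + pseudocount) / (n_sites + 4 * pseudocount) per column.
    """
    if len(aligned_sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    sites = [s.upper() for s in aligned_sites]
    w = len(sites[0])
    if w < 1 or any(len(s) != w for s in sites):
        raise ValueError("aligned sites must be non-empty and of equal length")
    counts = np.zeros((4, w))
    for s in sites:
        for j, c in enumerate(s):
            if c not in _IDX:
                raise ValueError(f"non-ACGT character {c!r} in aligned site {s!r}")
            counts[_IDX[c], j] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return Pwm(probs, background=background, counts=counts, nsites=len(sites))


def match_count(window: str, consensus: str) -> int:
    """Number of positions at which ``window`` agrees with ``consensus``."""
    if len(window) != len(consensus):
        raise ValueError(
            f"window length {len(window)} != consensus length {len(consensus)}"
        )
    return sum(a == b for a, b in zip(window.upper(), consensus.upper()))


def sequence_background(sequence: str) -> np.ndarray:
    """Strand-symmetric zero-order base frequencies of a sequence.

    Counts are Laplace-smoothed (+1 per base) and averaged with their
    complements, so scanning a sequence and its reverse complement uses the
    identical background.
    """
    counts = np.ones(4)
    codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    for i, ch in enumerate(b"ACGT"):
        counts[i] += int((codes == ch).sum())
    sym = (counts + counts[::-1]) / 2.0  # A<->T, C<->G
    return sym / sym.sum()


def quantized_log_odds(
    pwm: Pwm, background: Optional[np.ndarray] = None, granularity: float = 1e-3
) -> np.ndarray:
    """Integer log-odds matrix on the ``granularity``-bit grid."""
    lo = pwm.log_odds(background)
    if not np.all(np.isfinite(lo)):
        raise ValueError("log-odds not finite; use a positive pseudocount/background")
    return np.rint(lo / granularity).astype(np.int64)


def _int_score_distribution(
    K: np.ndarray, background: np.ndarray
) -> tuple[int, np.ndarray]:
    """Exact pmf of the integer window score under the background model.

    Returns (min_score, pmf) with pmf[k] = P(score == min_score + k).
    """
    cur = np.array([1.0])
    cur_min = 0
    for j in range(K.shape[1]):
        kmin = int(K[:, j].min())
        kmax = int(K[:, j].max())
        new = np.zeros(len(cur) + kmax - kmin)
        for b in range(4):
            off = int(K[b, j]) - kmin
            new[off : off + len(cur)] += background[b] * cur
        cur = new
        cur_min += kmin
    return cur_min, cur


def score_distribution(
    pwm: Pwm, background: Optional[np.ndarray] = None, granularity: float = 1e-3
) -> tuple[int, np.ndarray]:
    """Integer-score pmf of a background window under the quantized PWM."""
    bg = pwm.background if background is None else np.asarray(background, dtype=float)
    K = quantized_log_odds(pwm, bg, granularity)
    return _int_score_distribution(K, bg)


def score_pvalue(
    pwm: Pwm,
    threshold: float,
    background: Optional[np.ndarray] = None,
    granularity: float = 1e-3,
) -> float:
    """Exact tail probability P(window score >= threshold), threshold in bits.

    The threshold is snapped to the score grid with the same rounding rule as
    the per-column scores, so passing a score the scanner reported (or an
    ideal log-odds value within half a granularity of it) gives the exact
    tail probability of that attained score.
    """
    if threshold == -np.inf:
        return 1.0
    cur_min, pmf = score_distribution(pwm, background, granularity)
    ti = int(np.rint(threshold / granularity))
    lo = max(0, ti - cur_min)
    if lo >= len(pmf):
        return 0.0
    return float(min(1.0, pmf[lo:].sum()))


@dataclass(frozen=True)
class MotifHit:
    """A significant motif occurrence, reported by forward-strand start."""

    position: int  # 1-based start of the window on the forward strand
    strand: str
    log_odds: float  # bits
    p_value: float


def _encode(sequence: str) -> np.ndarray:
    codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    enc = np.full(len(codes), 4, dtype=np.int8)  # 4 = ambiguous (N etc.)
    for i, ch in enumerate(b"ACGT"):
        enc[codes == ch] = i
    return enc


def _window_scores(enc: np.ndarray, K5: np.ndarray, npos: int) -> np.ndarray:
    w = K5.shape[1]
    S = np.zeros(npos, dtype=np.int64)
    for j in range(w):
        S += K5[enc[j : j + npos], j]
    return S


def _dedup_palindromic(
    hits: list[MotifHit], width: int, genome_length: Optional[int]
) -> list[MotifHit]:
    """Drop the worse of two opposite-strand hits overlapping by >= width/2
    (the double report a palindromic motif produces)."""
    order = sorted(
        hits, key=lambda h: (h.p_value, -h.log_odds, h.strand != "+", h.position)
    )
    accepted: list[MotifHit] = []
    for h in order:
        clash = any(
            a.strand != h.strand
            and float(circ_distance(a.position, h.position, genome_length)) <= width // 2
            for a in accepted
        )
        if not clash:
            accepted.append(h)
    accepted.sort(key=lambda h: (h.position, h.strand))
    return accepted


def scan(
    sequence: str,
    pwm: Pwm,
    p_threshold: float = 1e-6,
    both_strands: bool = True,
    background: Union[str, np.ndarray] = "sequence",
    circular: bool = False,
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Scan a sequence with a PWM, emitting hits with exact p <= p_threshold.

    ``background`` is "sequence" (the scanned sequence's own strand-symmetric
    mononucleotide composition), "uniform", or an explicit 4-vector.
    Reverse-strand hits are reported by forward-strand start coordinate.
    Ambiguous bases contribute zero log-odds.  Overlapping opposite-strand
    hits of a palindromic motif are deduplicated to the better-scoring
    strand.  With ``circular`` the scan wraps around the origin.
    """
    w = pwm.width
    n = len(sequence)
    if n < w:
        return []
    if isinstance(background, str):
        if background == "sequence":
            bg = sequence_background(sequence)
        elif background == "uniform":
            bg = np.full(4, 0.25)
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, dtype=float)

    K = quantized_log_odds(pwm, bg, granularity)
    cur_min, pmf = _int_score_distribution(K, bg)
    tail = np.cumsum(pmf[::-1])[::-1]

    def pvalues(S: np.ndarray) -> np.ndarray:
        idx = S - cur_min
        p = np.ones(len(S))
        inside = (idx >= 0) & (idx < len(tail))
        p[inside] = np.minimum(1.0, tail[idx[inside]])
        p[idx >= len(tail)] = 0.0
        return p

    enc = _encode(sequence)
    ext = np.concatenate([enc, enc[: w - 1]]) if circular else enc
    npos = n if circular else n - w + 1

    matrices = [("+", K)]
    if both_strands:
        K_rc = K[[3, 2, 1, 0], :][:, ::-1]  # complement bases, reverse columns
        matrices.append(("-", K_rc))

    hits: list[MotifHit] = []
    for strand, mat in matrices:
        K5 = np.vstack([mat, np.zeros((1, w), dtype=np.int64)])
        S = _window_scores(ext, K5, npos)
        p = pvalues(S)
        for i in np.flatnonzero(p <= p_threshold):
            hits.append(
                MotifHit(
                    position=int(i) + 1,
                    strand=strand,
                    log_odds=float(S[i] * granularity),
                    p_value=float(p[i]),
                )
            )
    if both_strands:
        hits = _dedup_palindromic(hits, w, n if circular else None)
    else:
        hits.sort(key=lambda h: h.position)
    return hits


def associate_hits(
    peaks: Sequence,
    hits: Sequence[MotifHit],
    flank: int = 50,
    genome_length: Optional[int] = None,
) -> list[Optional[MotifHit]]:
    """Best (lowest-p) hit starting within ``flank`` bp of each peak maximum.

    Returns a list parallel to ``peaks`` with None where no hit qualifies,
    partitioning the peaks into with-box and without-box sets.
    """
    out: list[Optional[MotifHit]] = []
    for peak in peaks:
        best = None
        for h in hits:
            if float(circ_distance(h.position, peak.max_position, genome_length)) <= flank:
                if best is None or (h.p_value, h.position) < (best.p_value, best.position):
                    best = h
        out.append(best)
    return out


def write_meme(pwm: Pwm, path, name: str = "motif") -> None:
    """Write a PWM in MEME minimal motif text format."""
    bg = pwm.background
    nsites = pwm.nsites if pwm.nsites is not None else 20
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {nsites} E= 0",
    ]
    for j in range(pwm.width):
        lines.append(" " + " ".join(f"{pwm.probs[b, j]:.6f}" for b in range(4)))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_meme(path) -> Pwm:
    """Read the first motif of a MEME minimal motif text file."""
    background = None
    probs_rows: list[list[float]] = []
    width = None
    nsites = None
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        s = line.strip()
        if s.startswith("Background letter frequencies"):
            parts = next(lines).split()
            background = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
        elif s.startswith("letter-probability matrix"):
            fields = dict(
                zip([t.rstrip("=") for t in s.split()[2::2]], s.split()[3::2])
            )
            width = int(fields["w"])
            nsites = int(float(fields.get("nsites", 20)))
            for _ in range(width):
                probs_rows.append([float(x) for x in next(lines).split()])
            break
    if width is None:
        raise ValueError(f"no letter-probability matrix found in {path}")
    probs = np.array(probs_rows).T
    probs = probs / probs.sum(axis=0)  # re-normalize rounded columns
    return Pwm(probs, background=background, nsites=nsites)
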