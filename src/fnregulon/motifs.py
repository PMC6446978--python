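"""PWM scoring with exact p-values, both-strand scanning, and ZOOPS-EM
motif discovery.

Scores are log2-odds ("bits") against a 0-order background. P-values are
exact under that background, computed by dynamic programming over
integer-discretized per-column scores (the discretization, default 1,000
steps per bit, is the sole approximation). The scanner reports every window
on either strand whose p-value is at or below ``alpha`` (default 1e-5, no
multiple-testing correction); the p-value is per-strand — no doubling for
the two-strand search.

Motif discovery is a ZOOPS (zero-or-one occurrence per sequence)
expectation-maximization over both strands with multiple seeded restarts,
in the spirit of MEME's ZOOPS model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import PromoterRegion, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_ALPHA = 1e-5
DEFAULT_GRANULARITY = 1000


# ------------------------------------------------------------- background

@dataclass(frozen=True)
class Background:
    """0-order base composition (A, C, G, T)."""

    probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,) or (p <= 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive probabilities summing to 1")

    @classmethod
    def uniform(cls) -> "Background":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], pseudocount: float = 1.0) -> "Background":
        counts = np.full(4, pseudocount, dtype=float)
        for s in seqs:
            for b in s.upper():
                i = _BASE_INDEX.get(b)
                if i is not None:
                    counts[i] += 1
        return cls(tuple(counts / counts.sum()))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


def encode(seq: str) -> np.ndarray:
    """A, C, G, T -> 0..3; anything else -> -1 (windows containing it are
    skipped by the scanner)."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


# -------------------------------------------------------------------- PWM

@dataclass
class PWM:
    """Column probability model of a binding site (width x 4, rows sum to 1)."""

    matrix: np.ndarray
    pseudocount_weight: float = 0.0
    source_sites: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if self.pseudocount_weight > 0 and (self.matrix <= 0).any():
            raise ValueError("pseudocounted PWM must have all entries > 0")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, background: Background) -> np.ndarray:
        """width x 4 matrix of log2(p/bg); -inf where p == 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(background.array)

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1].copy(), self.pseudocount_weight)


def build_pwm(
    sites: Sequence[str],
    pseudocount_weight: float = 0.0,
    background: Background | None = None,
) -> PWM:
    """Estimate a PWM from aligned equal-length ACGT sites.

    Column probability = (count + pseudocount_weight * bg) / (n + pseudocount_weight).
    """
    if not sites:
        raise ValueError("need at least one site")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must be equal length")
    bg = (background or Background.uniform()).array
    counts = np.zeros((width, 4), dtype=float)
    for s in sites:
        enc = encode(s)
        if (enc < 0).any():
            raise ValueError(f"site {s!r} contains non-ACGT letters")
        counts[np.arange(width), enc] += 1.0
    mat = (counts + pseudocount_weight * bg) / (len(sites) + pseudocount_weight)
    return PWM(mat, pseudocount_weight, source_sites=list(sites))


def information_content(
    pwm: PWM, background: Background | None = None
) -> tuple[np.ndarray, float]:
    """Per-column and total relative entropy, in bits:
    IC_j = sum_b p_j(b) log2(p_j(b)/bg(b)), with 0 log 0 := 0."""
    bg = (background or Background.uniform()).array
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log2(p) - np.log2(bg)), 0.0)
    per_col = terms.sum(axis=1)
    return per_col, float(per_col.sum())


def log_odds_score(pwm: PWM, window: str, background: Background | None = None) -> float:
    """log2-odds of a single window of length = PWM width. Undefined (raises)
    for windows containing ambiguous bases; the scanner skips those."""
    bg = background or Background.uniform()
    enc = encode(window)
    if enc.size != pwm.width:
        raise ValueError("window length must equal PWM width")
    if (enc < 0).any():
        raise ValueError("window contains ambiguous bases; score undefined")
    return float(pwm.log_odds(bg)[np.arange(pwm.width), enc].sum())


# -------------------------------------------------- exact score p-values

class ScoreDistribution:
    """Exact null distribution of the integer-discretized log-odds score
    under the 0-order background, via column-by-column convolution."""

    def __init__(self, pwm: PWM, background: Background,
                 granularity: int = DEFAULT_GRANULARITY):
        if granularity < 1:
            raise ValueError("granularity must be >= 1")
        self.granularity = int(granularity)
        self.background = background
        lod = pwm.log_odds(background)
        if not np.isfinite(lod).all():
            # zero-probability PWM cells score -inf; floor far below anything
            # a passing window could use so the tail is unaffected
            floor = np.nanmin(np.where(np.isfinite(lod), lod, np.nan)) - 100.0
            lod = np.where(np.isfinite(lod), lod, floor)
        self.int_scores = np.rint(lod * self.granularity).astype(np.int64)

        bg = background.array
        col_mins = self.int_scores.min(axis=1)
        col_maxs = self.int_scores.max(axis=1)
        self.min_total = int(col_mins.sum())
        self.max_total = int(col_maxs.sum())
        span = self.max_total - self.min_total + 1
        pmf = np.zeros(span)
        pmf[0] = 1.0  # offset: index i <-> total score min_total + i
        reached = 0  # current max offset with mass
        for j in range(self.int_scores.shape[0]):
            new = np.zeros(span)
            for b in range(4):
                shift = self.int_scores[j, b] - col_mins[j]
                new[shift: reached + shift + 1] += bg[b] * pmf[: reached + 1]
            reached += col_maxs[j] - col_mins[j]
            pmf = new
        self.pmf = pmf
        # survival: P(score >= s)
        self.sf = pmf[::-1].cumsum()[::-1]

    def pvalue_int(self, int_score: int) -> float:
        if int_score <= self.min_total:
            return 1.0
        if int_score > self.max_total:
            return 0.0
        return float(self.sf[int_score - self.min_total])

    def pvalue(self, score_bits: float) -> float:
        """P(null score >= score) for a score in bits."""
        return self.pvalue_int(int(round(score_bits * self.granularity)))

    def threshold_int(self, alpha: float) -> int:
        """Smallest integer score s with P(score >= s) <= alpha."""
        if not 0.0 < alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        passing = np.nonzero(self.sf <= alpha)[0]
        if passing.size == 0:
            return self.max_total + 1  # nothing achieves the p-value
        return self.min_total + int(passing[0])

    def threshold(self, alpha: float) -> float:
        """Score threshold in bits; at alpha = 1 this is the minimum
        achievable score (every window passes)."""
        if math.isclose(alpha, 1.0):
            return self.min_total / self.granularity
        return self.threshold_int(alpha) / self.granularity


def score_threshold_for_pvalue(
    pwm: PWM,
    background: Background | None = None,
    alpha: float = DEFAULT_ALPHA,
    granularity: int = DEFAULT_GRANULARITY,
) -> float:
    """Exact-null score threshold (bits) such that P(score >= t) <= alpha."""
    bg = background or Background.uniform()
    return ScoreDistribution(pwm, bg, granularity).threshold(alpha)


# ---------------------------------------------------------------- scanning

@dataclass(frozen=True)
class MotifHit:
    """One significant PWM match within a promoter.

    ``offset`` is the 0-based leftmost position of the site in the promoter's
    given orientation; for a '-' hit the matched site is the reverse
    complement of promoter[offset : offset + width]."""

    anchor_id: str
    offset: int
    strand_relative: str
    score: float
    p_value: float
    matched_sequence: str = ""


def _window_int_scores(enc: np.ndarray, int_scores: np.ndarray) -> np.ndarray:
    """Integer score of every window; windows containing ambiguous bases get
    a sentinel below any real score."""
    w = int_scores.shape[0]
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    total = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    safe = np.where(enc < 0, 0, enc)
    for j in range(w):
        total += int_scores[j, safe[j: j + n]]
        bad |= enc[j: j + n] < 0
    total[bad] = np.iinfo(np.int64).min
    return total


def scan(
    pwm: PWM,
    promoters: Sequence[PromoterRegion],
    background: Background | None = None,
    alpha: float = DEFAULT_ALPHA,
    both_strands: bool = True,
    granularity: int = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Slide the PWM over each promoter (and, by default, its reverse
    complement) and report every window whose exact p-value <= alpha.
    Overlapping hits are all reported; promoters shorter than the motif
    yield no hits. The default background is estimated from the scanned
    promoter set itself."""
    if background is None:
        background = Background.from_sequences(p.sequence for p in promoters)
    dist = ScoreDistribution(pwm, background, granularity)
    cut = dist.threshold_int(alpha)
    w = pwm.width
    hits: list[MotifHit] = []
    for prom in promoters:
        seq = prom.sequence.upper()
        L = len(seq)
        if L < w:
            continue
        enc_f = encode(seq)
        strands = [("+", enc_f, seq)]
        if both_strands:
            rc = reverse_complement(seq)
            strands.append(("-", encode(rc), rc))
        for strand, enc, s in strands:
            totals = _window_int_scores(enc, dist.int_scores)
            for k in np.nonzero(totals >= cut)[0]:
                k = int(k)
                offset = k if strand == "+" else L - w - k
                hits.append(
                    MotifHit(
                        anchor_id=prom.anchor_id,
                        offset=offset,
                        strand_relative=strand,
                        score=totals[k] / dist.granularity,
                        p_value=dist.pvalue_int(int(totals[k])),
                        matched_sequence=s[k: k + w],
                    )
                )
    return hits


# ------------------------------------------------------- ZOOPS-EM discovery

@dataclass
class DiscoveryResult:
    pwm: PWM
    occupancy: float
    log_likelihood: float
    ll_trace: list[float]
    converged: bool
    n_restarts: int = 1


def _zoops_em_run(
    encs: list[np.ndarray],
    init_matrix: np.ndarray,
    background: Background,
    width: int,
    max_iter: int,
    tol: float,
    pseudocount: float,
) -> tuple[np.ndarray, float, list[float], bool]:
    """One EM run. ``encs`` holds, per sequence, the stacked valid windows
    (forward + reverse strand) as an (n_windows, width) int array.

    The recorded trace is the Dirichlet-penalized log-likelihood (MAP
    objective), which EM increases monotonically."""
    bg = background.array
    log_bg = np.log(bg)
    # per-window background log-likelihood, to form likelihood ratios
    win_bg_ll = [log_bg[w].sum(axis=1) for w in encs]
    mat = init_matrix.copy()
    gamma = 0.5
    alpha_prior = pseudocount * bg  # Dirichlet(1 + alpha_prior) per column
    trace: list[float] = []
    converged = False
    col_idx = np.arange(width)
    for _ in range(max_iter):
        log_mat = np.log(mat)
        ll = 0.0
        site_counts = np.zeros((width, 4))
        gamma_num = 0.0
        for w_enc, bgll in zip(encs, win_bg_ll):
            n = w_enc.shape[0]
            if n == 0:
                ll += math.log1p(-gamma) if gamma < 1 else -math.inf
                continue
            # log P(window | motif) - log P(window | background)
            llr = log_mat[col_idx[None, :], w_enc].sum(axis=1) - bgll
            # responsibilities: no-site vs site at (position, strand)
            m = llr.max()
            site_mass = (gamma / n) * np.exp(llr - m).sum()
            no_site_mass = (1.0 - gamma) * math.exp(-m)
            denom = site_mass + no_site_mass
            ll += m + math.log(denom)  # background term is a constant; omitted
            z = (gamma / n) * np.exp(llr - m) / denom
            gamma_num += z.sum()
            np.add.at(site_counts, (col_idx[None, :], w_enc), z[:, None])
        log_prior = float((alpha_prior * np.log(mat)).sum())
        trace.append(ll + log_prior)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        # M-step
        gamma = min(max(gamma_num / len(encs), 1e-6), 1.0 - 1e-6)
        mat = site_counts + alpha_prior
        mat /= mat.sum(axis=1, keepdims=True)
    return mat, gamma, trace, converged


def discover_motif(
    promoters: Sequence[PromoterRegion],
    width: int = 14,
    n_restarts: int = 5,
    seed: int = 0,
    background: Background | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.25,
) -> DiscoveryResult:
    """De novo ZOOPS-EM motif discovery over both strands.

    Each restart is seeded from a width-long subsequence of a distinct
    promoter (smoothed toward the background); the model with the highest
    final objective wins. Non-convergence within ``max_iter`` returns the
    best-so-far model with ``converged=False`` and a warning.
    """
    if len(promoters) < 4:
        raise ValueError("need at least 4 promoters for motif discovery")
    if not 6 <= width <= 30:
        raise ValueError("width must be in [6, 30]")
    seqs = [p.sequence.upper() for p in promoters]
    if min(len(s) for s in seqs) < width:
        raise ValueError("width exceeds the shortest promoter")
    if background is None:
        background = Background.from_sequences(seqs)
    bg = background.array

    encs: list[np.ndarray] = []
    seed_windows: list[np.ndarray] = []
    for s in seqs:
        fwd = encode(s)
        rev = encode(reverse_complement(s))
        wins = []
        for enc in (fwd, rev):
            n = enc.size - width + 1
            idx = np.arange(n)[:, None] + np.arange(width)[None, :]
            w = enc[idx]
            w = w[(w >= 0).all(axis=1)]
            wins.append(w)
        seed_windows.append(wins[0])
        encs.append(np.vstack(wins) if wins else np.empty((0, width), dtype=np.int64))

    rng = np.random.default_rng(seed)
    # substring seeding: screen many candidate k-mer starts with two EM
    # iterations each, then run full EM only from the most promising ones
    # (otherwise restarts almost never initialize near a true site)
    n_candidates = max(8 * n_restarts, 40)
    order = rng.permutation(len(seqs))
    candidates: list[tuple[float, np.ndarray]] = []
    for r in range(n_candidates):
        src = seed_windows[order[r % len(order)]]
        if src.shape[0] == 0:
            continue
        kmer = src[rng.integers(src.shape[0])]
        init = np.tile(bg * 0.3, (width, 1))
        init[np.arange(width), kmer] += 0.7
        init /= init.sum(axis=1, keepdims=True)
        _, _, short_trace, _ = _zoops_em_run(
            encs, init, background, width, 2, tol, pseudocount
        )
        candidates.append((short_trace[-1], init))
    candidates.sort(key=lambda c: c[0], reverse=True)

    best: tuple[float, np.ndarray, float, list[float], bool] | None = None
    for _, init in candidates[:n_restarts]:
        mat, gamma, trace, conv = _zoops_em_run(
            encs, init, background, width, max_iter, tol, pseudocount
        )
        # phase refinement: EM has a column-shift ambiguity (a model offset
        # by a column or two from the true site is a nearby local optimum),
        # so hill-climb over shifted re-initializations until the objective
        # stops improving
        for _ in range(width):
            improved = False
            for shift in (-2, -1, 1, 2):
                shifted = np.tile(bg, (width, 1))
                if shift > 0:
                    shifted[: width - shift] = mat[shift:]
                else:
                    shifted[-shift:] = mat[: width + shift]
                s_mat, s_gamma, s_trace, s_conv = _zoops_em_run(
                    encs, shifted, background, width, max_iter, tol, pseudocount
                )
                if s_trace[-1] > trace[-1] + 1e-9:
                    mat, gamma, trace, conv = s_mat, s_gamma, s_trace, s_conv
                    improved = True
            if not improved:
                break
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], mat, gamma, trace, conv)
    assert best is not None
    obj, mat, gamma, trace, conv = best
    if not conv:
        logger.warning("motif EM did not converge within %d iterations; "
                       "returning best-so-far model", max_iter)
    return DiscoveryResult(
        pwm=PWM(mat, pseudocount_weight=pseudocount),
        occupancy=gamma,
        log_likelihood=obj,
        ll_trace=trace,
        converged=conv,
        n_restarts=n_restarts,
    )


# ---------------------------------------------------------------- file I/O

def write_meme(pwm: PWM, background: Background, path: str | Path,
               motif_name: str = "MOTIF_1", n_sites: int = 20) -> None:
    """MEME minimal motif text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.5f}" for b, p in zip(BASES, background.probs)))
        fh.write(f"\n\nMOTIF {motif_name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {n_sites} E= 0\n"
        )
        for row in pwm.matrix:
            fh.write("  " + "  ".join(f"{p:.6f}" for p in row) + "\n")


def read_meme(path: str | Path) -> tuple[PWM, Background]:
    lines = Path(path).read_text().splitlines()
    bg = Background.uniform()
    rows: list[list[float]] = []
    width = None
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = Background(tuple(float(parts[k]) for k in (1, 3, 5, 7)))
            i += 2
            continue
        if line.startswith("letter-probability matrix"):
            width = int(line.split("w=")[1].split()[0])
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            i += width + 1
            continue
        i += 1
    if width is None:
        raise ValueError(f"no motif found in {path}")
    mat = np.asarray(rows)
    mat /= mat.sum(axis=1, keepdims=True)  # renormalize printed rounding
    return PWM(mat), bg


def write_hits(hits: Sequence[MotifHit], path: str | Path,
               motif_id: str = "MOTIF_1", width: int | None = None) -> None:
    """FIMO-style TSV (1-based start/stop within the promoter)."""
    import pandas as pd

    rows = []
    for h in hits:
        w = width if width is not None else len(h.matched_sequence)
        rows.append({
            "motif_id": motif_id,
            "sequence_name": h.anchor_id,
            "start": h.offset + 1,
            "stop": h.offset + w,
            "strand": h.strand_relative,
            "score": round(h.score, 4),
            "p-value": f"{h.p_value:.3g}",
            "matched_sequence": h.matched_sequence,
        })
    pd.DataFrame(
        rows, columns=["motif_id", "sequence_name", "start", "stop", "strand",
                       "score", "p-value", "matched_sequence"],
    ).to_csv(path, sep="\t", index=False)
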