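"""Position-weight-matrix scoring, scanning and empirical threshold calibration.

A PFM (per-column base counts) is converted to a log-odds matrix against a
background composition.  Window scores are min-max normalized to [0, 1] —
the "match score" convention — so thresholds are comparable across motifs of
different lengths and information content.  The score cutoff is not chosen on
theoretical grounds: it is calibrated empirically so that scanning a
motif-free negative-control sequence set yields no more than a stated number
of hits per 10 kbp (the false-positive allowance).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as _bio_motifs

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DegeneratePWMError(ValueError):
    """Raised when a matrix cannot discriminate any sequence (min == max score)."""


@dataclass
class PWM:
    """Position frequency matrix with log-odds scoring.

    Parameters
    ----------
    counts
        4 x L non-negative matrix, rows in A, C, G, T order.
    pseudocount
        Added to every cell before normalization (default 0.25).
    background
        Background base composition (A, C, G, T); uniform by default.
        Log-odds are ``log2(p[b, j] / background[b])``.
    """

    counts: np.ndarray
    name: str = "pwm"
    pseudocount: float = 0.25
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 4:
            raise ValueError("motif must have at least 4 columns")
        if np.any(self.counts < 0):
            raise ValueError("negative counts in PFM")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be a 4-vector summing to 1")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be positive")

        padded = self.counts + self.pseudocount
        colsums = padded.sum(axis=0)
        if np.any(colsums <= 0):
            raise ValueError("column of all zeros with pseudocount 0")
        self.probabilities = padded / colsums
        with np.errstate(divide="ignore"):  # zero cells at pseudocount 0 -> -inf
            self.logodds = np.log2(self.probabilities) - np.log2(self.background)[:, None]
        self.min_score = float(self.logodds.min(axis=0).sum())
        self.max_score = float(self.logodds.max(axis=0).sum())
        if not self.min_score < self.max_score:
            raise DegeneratePWMError(
                f"degenerate PWM {self.name!r}: min_score == max_score"
            )
        # row 4 (= N or other) scores -inf so windows containing N never hit
        self._lookup = np.vstack([self.logodds, np.full(self.length, -np.inf)])
        # scoring the reverse complement of a forward window == scoring the
        # forward window with the reverse-complemented matrix
        rc = self.logodds[::-1, ::-1]
        self._lookup_rc = np.vstack([rc, np.full(self.length, -np.inf)])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.logodds.argmax(axis=0))

    def normalize(self, raw: np.ndarray | float):
        """Map raw log-odds sums onto the [0, 1] match-score scale."""
        return (raw - self.min_score) / (self.max_score - self.min_score)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PWM({self.name!r}, length={self.length})"


@dataclass(frozen=True)
class MotifHit:
    """One predicted binding site on a scanned sequence.

    ``offset`` is the 0-based start of the window on the forward strand and
    ``site`` is the forward-strand spelling of the matched subsequence,
    whichever strand matched.
    """

    seq_id: str
    offset: int
    strand: str
    match_score: float
    site: str


@dataclass
class CalibrationResult:
    threshold: float
    allowed_rate: float
    achieved_rate: float
    total_bp: int
    n_hits: int
    note: str = ""


def read_jaspar(path_or_handle) -> PWM:
    """Read a JASPAR-format PFM (4 rows ``A  [ ... ]`` ...) into a :class:`PWM`."""
    if hasattr(path_or_handle, "read"):
        m = _bio_motifs.read(path_or_handle, "jaspar")
    else:
        with open(path_or_handle) as fh:
            m = _bio_motifs.read(fh, "jaspar")
    counts = np.array([m.counts[b] for b in BASES], dtype=float)
    return PWM(counts, name=m.name or m.matrix_id or "pwm")


def write_jaspar(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, b in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in pwm.counts[i])
            fh.write(f"{b}  [ {vals} ]\n")


def _window_scores(pwm: PWM, codes: np.ndarray, strand: str) -> np.ndarray:
    """Raw log-odds of every window on one strand, vectorized.

    Returns an array of length ``len(codes) - L + 1`` (empty if the sequence
    is shorter than the motif).  Windows containing non-ACGT bases get -inf.
    """
    L = pwm.length
    n = codes.shape[0] - L + 1
    if n <= 0:
        return np.empty(0)
    table = pwm._lookup if strand == "+" else pwm._lookup_rc
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    with np.errstate(invalid="ignore"):
        return table[win, np.arange(L)].sum(axis=1)


def score_window(pwm: PWM, seq: str, offset: int, strand: str = "+") -> float:
    """Normalized match score of the window ``seq[offset:offset+L]``.

    Strand ``-`` scores the reverse complement of that same window; windows
    containing N score ``-inf`` and can never pass a threshold in [0, 1].
    """
    L = pwm.length
    if offset < 0 or offset + L > len(seq):
        raise ValueError(f"window [{offset}, {offset + L}) outside sequence")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    codes = encode(seq[offset : offset + L])
    table = pwm._lookup if strand == "+" else pwm._lookup_rc
    raw = float(table[codes, np.arange(L)].sum())
    return float(pwm.normalize(raw))


def scan(
    pwm: PWM,
    seq: str,
    threshold: float,
    seq_id: str = "seq",
    strands: str = "both",
) -> list[MotifHit]:
    """All windows (offset x strand) scoring at or above ``threshold``.

    Hits are sorted by offset, then strand (+ before -).  Overlapping hits
    are reported individually, never merged; the two strands of a
    reverse-palindromic site yield two hits.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    codes = encode(seq)
    L = pwm.length
    hits: list[tuple[int, str, float]] = []
    which = ("+", "-") if strands == "both" else (strands,)
    for strand in which:
        norm = pwm.normalize(_window_scores(pwm, codes, strand))
        for off in np.nonzero(norm >= threshold)[0]:
            hits.append((int(off), strand, float(norm[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [
        MotifHit(seq_id, off, strand, score, seq[off : off + L].upper())
        for off, strand, score in hits
    ]


def negative_set_scores(pwm: PWM, sequences: Iterable[str]) -> tuple[np.ndarray, int]:
    """Pooled finite window scores (both strands) and total bp of a sequence set."""
    all_scores = []
    total_bp = 0
    for seq in sequences:
        total_bp += len(seq)
        codes = encode(seq)
        for strand in "+-":
            raw = _window_scores(pwm, codes, strand)
            if raw.size:
                norm = pwm.normalize(raw)
                all_scores.append(norm[np.isfinite(norm)])
    scores = np.concatenate(all_scores) if all_scores else np.empty(0)
    return scores, total_bp


def hit_rate(pwm: PWM, sequences: Sequence[str], threshold: float) -> float:
    """Hits per 10 kbp of sequence at ``threshold`` (both strands pooled)."""
    scores, total_bp = negative_set_scores(pwm, sequences)
    if total_bp == 0:
        return 0.0
    return float((scores >= threshold).sum()) / total_bp * 10_000.0


def order_statistic_threshold(scores: np.ndarray, n_allow: int) -> tuple[float, str]:
    """Smallest t in ``scores U {1.0}`` with ``#{s >= t} <= n_allow``.

    Returns (threshold, note); the note is non-empty only when no attained
    score satisfies the allowance (ties at the maximum), in which case the
    threshold is set just above the maximum.
    """
    scores_sorted = np.sort(np.asarray(scores, dtype=float))
    n = scores_sorted.size
    if n == 0:
        raise ValueError("empty score multiset")
    if n_allow >= n:
        return float(scores_sorted[0]), ""
    uniq = np.unique(scores_sorted)
    counts_ge = n - np.searchsorted(scores_sorted, uniq, side="left")
    ok = np.nonzero(counts_ge <= n_allow)[0]
    if ok.size:
        return float(uniq[ok[0]]), ""
    if 1.0 > scores_sorted[-1]:
        return 1.0, ""
    return (
        float(np.nextafter(scores_sorted[-1], np.inf)),
        "allowance unreachable at any attained score; threshold set just above max",
    )


def calibrate_threshold(
    pwm: PWM,
    negative_set: Sequence[str],
    allowed_rate: float = 3.0,
) -> CalibrationResult:
    """Choose the match-score cutoff from a motif-free negative-control set.

    With ``S`` the multiset of all window scores over the negative set (both
    strands) and ``N_allow = floor(allowed_rate * total_bp / 10000)``, the
    threshold is the smallest score ``t`` in ``S U {1.0}`` such that
    ``|{s in S : s >= t}| <= N_allow``.  Ties at the threshold all count as
    hits, so the guarantee ``achieved_rate <= allowed_rate`` holds exactly on
    the calibration set — this is the "no more than the allowance per 10 kbp"
    rule implemented by exact order statistics rather than a score grid.
    """
    if allowed_rate <= 0:
        raise ValueError("allowed_rate must be positive")
    scores, total_bp = negative_set_scores(pwm, negative_set)
    if scores.size == 0:
        raise ValueError("negative set contains no scorable windows")
    if total_bp < 100 * pwm.length:
        warnings.warn(
            f"negative set is only {total_bp} bp (< 100 x motif length); "
            "calibration may be unreliable",
            stacklevel=2,
        )
    n_allow = math.floor(allowed_rate * total_bp / 10_000.0)
    threshold, note = order_statistic_threshold(scores, n_allow)
    n_hits = int((scores >= threshold).sum())
    achieved = n_hits / total_bp * 10_000.0
    return CalibrationResult(
        threshold=threshold,
        allowed_rate=allowed_rate,
        achieved_rate=achieved,
        total_bp=total_bp,
        n_hits=n_hits,
        note=note,
    )
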