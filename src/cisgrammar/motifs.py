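"""Position-matrix models of TF binding specificity and motif scanning.

A :class:`MotifModel` holds a position frequency matrix (PFM) together with
the derived log-odds position weight matrix (PWM, bits), the energy weight
matrix (EWM, dimensionless RT units, zero for the consensus base at every
position), the per-position information content (bits) and the consensus
word.  Scanning reports every window, on either strand, whose log-odds
score has an exact tail p-value at or below a threshold; the null score
distribution of a random background word is computed by dynamic programming
over a discretized per-position score table, so the p-values are exact up to
the discretization bin width.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import motifs as _biomotifs

from ._seq import BASES, encode, revcomp

#: default score-discretization bin width (log-odds units) for the p-value DP
DEFAULT_BIN_WIDTH = 1e-3

#: default pseudocount added to each base frequency before renormalization
DEFAULT_PSEUDOCOUNT = 1e-3

UNIFORM_BACKGROUND = np.full(4, 0.25)


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed."""


@dataclass(frozen=True)
class SiteHit:
    """A motif match on one strand of a sequence.

    Coordinates are 0-based half-open; a hit on the minus strand scores the
    reverse complement of ``sequence[start:end]``.
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    tf: str
    score: float
    pvalue: float

    @property
    def length(self) -> int:
        return self.end - self.start


class MotifModel:
    """A TF's PFM plus derived PWM, EWM, information content and consensus.

    Parameters
    ----------
    name
        TF identifier (e.g. ``"O"`` or ``"OCT4"``).
    pfm
        4 x L matrix of per-position base counts or frequencies, rows in
        A, C, G, T order.  Columns are renormalized after adding
        ``pseudocount`` to each frequency.
    background
        Genomic base composition used for the log-odds scores and the null
        score distribution.  Defaults to uniform.
    pseudocount
        Frequency added to every entry before renormalization, so that
        log-ratios are finite even for count columns containing zeros.
    """

    def __init__(
        self,
        name: str,
        pfm: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        bin_width: float = DEFAULT_BIN_WIDTH,
    ):
        pfm = np.asarray(pfm, dtype=float)
        if pfm.ndim != 2 or pfm.shape[0] != 4:
            raise ValueError(f"PFM must be 4 x L, got shape {pfm.shape}")
        if np.any(pfm < 0):
            raise ValueError("PFM entries must be non-negative")
        colsums = pfm.sum(axis=0)
        if np.any(colsums <= 0):
            bad = int(np.flatnonzero(colsums <= 0)[0])
            raise ValueError(f"PFM column {bad} sums to zero")

        self.name = name
        self.pseudocount = float(pseudocount)
        self.background = (
            UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
        )
        if self.background.shape != (4,) or not math.isclose(self.background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background must be a 4-vector summing to 1")
        self.bin_width = float(bin_width)

        freq = pfm / colsums
        freq = freq + self.pseudocount
        freq = freq / freq.sum(axis=0)
        self.pfm = freq

        #: log-odds scores in bits
        self.pwm = np.log2(self.pfm / self.background[:, None])
        self._consensus_idx = np.argmax(self.pfm, axis=0)
        #: binding energies in RT units, 0 for the consensus base
        self.ewm = np.log(self.pfm[self._consensus_idx, np.arange(self.length)][None, :] / self.pfm)
        #: information content per position, bits (uniform-background form)
        self.ic = 2.0 + (self.pfm * np.log2(self.pfm)).sum(axis=0)
        self.consensus = "".join(BASES[i] for i in self._consensus_idx)

        # integer-binned PWM for the exact-p-value DP; kept consistent with
        # the binned window scores used during scanning
        self._pwm_int = np.round(self.pwm / self.bin_width).astype(np.int64)
        self._null_cache: tuple[int, np.ndarray] | None = None

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    # ---------------------------------------------------------------- null

    def _null_distribution(self) -> tuple[int, np.ndarray]:
        """(offset, tail) of the binned null score distribution.

        ``tail[s - offset]`` is P(score >= s * bin_width) for a random word
        drawn from the background, where ``s`` runs over attainable binned
        scores.
        """
        if self._null_cache is not None:
            return self._null_cache
        lo = int(self._pwm_int.min(axis=0).sum())
        hi = int(self._pwm_int.max(axis=0).sum())
        probs = np.zeros(hi - lo + 1)
        # DP over positions: convolve the running distribution with each
        # column's 4-point score distribution
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(self.length):
            col = self._pwm_int[:, j]
            new_lo = cur_lo + int(col.min())
            new_hi = cur_lo + len(cur) - 1 + int(col.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                off = cur_lo + int(col[b]) - new_lo
                new[off : off + len(cur)] += self.background[b] * cur
            cur, cur_lo = new, new_lo
        probs[cur_lo - lo : cur_lo - lo + len(cur)] = cur
        tail = np.cumsum(probs[::-1])[::-1]
        # guard against accumulated float error at the low end
        tail = np.minimum(tail, 1.0)
        self._null_cache = (lo, tail)
        return self._null_cache

    def score_pvalue(self, score: float) -> float:
        """Exact tail probability P(score of a random background word >= score).

        Exact up to the discretization bin width.  Scores above the maximum
        attainable return the probability of the top-scoring word set (never
        zero); scores below the minimum return 1.
        """
        lo, tail = self._null_distribution()
        s = int(np.round(score / self.bin_width))
        idx = int(np.clip(s - lo, 0, len(tail) - 1))
        p = float(tail[idx])
        return max(p, float(tail[-1]))

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest binned score whose tail p-value is <= ``p_threshold``."""
        lo, tail = self._null_distribution()
        idx = np.searchsorted(-tail, -p_threshold, side="left")
        if idx >= len(tail):
            # even the best word is more common than the threshold
            return lo + len(tail)
        return lo + int(idx)

    # ---------------------------------------------------------------- scan

    def _window_scores(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Binned-integer window scores and a validity mask (no-N windows)."""
        L = self.length
        n = len(codes) - L + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = (win >= 0).all(axis=1)
        safe = np.where(win >= 0, win, 0)
        scores = self._pwm_int[safe, np.arange(L)].sum(axis=1)
        return scores, valid

    def scan(
        self,
        seq: str,
        p_threshold: float = 1e-3,
        sequence_id: str = "seq",
    ) -> list[SiteHit]:
        """All windows on both strands with exact p-value <= ``p_threshold``.

        Windows containing N (or any non-ACGT character) are skipped.  A
        sequence shorter than the motif yields an empty list.  Hits are
        sorted by start, then strand (+ before -).
        """
        L = self.length
        codes = encode(seq)
        if len(codes) < L:
            return []
        lo, tail = self._null_distribution()
        thr = self.score_threshold(p_threshold)
        hits: list[SiteHit] = []
        for strand, strand_codes in (("+", codes), ("-", encode(revcomp(seq)))):
            scores, valid = self._window_scores(strand_codes)
            for i in np.flatnonzero(valid & (scores >= thr)):
                s = int(scores[i])
                pval = float(tail[int(np.clip(s - lo, 0, len(tail) - 1))])
                if strand == "+":
                    start = int(i)
                else:
                    start = len(seq) - int(i) - L
                # float log-odds score of the matched word
                word = strand_codes[i : i + L]
                fscore = float(self.pwm[word, np.arange(L)].sum())
                hits.append(
                    SiteHit(sequence_id, start, start + L, strand, self.name, fscore, max(pval, float(tail[-1])))
                )
        hits.sort(key=lambda h: (h.start, h.strand))
        return hits

    # ------------------------------------------------------------- scoring

    def score_word(self, word: str) -> float:
        """Float log-odds score (bits) of a single word of motif length."""
        codes = encode(word)
        if len(codes) != self.length or np.any(codes < 0):
            raise ValueError("word must be ACGT-only and of motif length")
        return float(self.pwm[codes, np.arange(self.length)].sum())

    def __repr__(self) -> str:  # pragma: no cover
        return f"MotifModel({self.name!r}, L={self.length}, consensus={self.consensus!r})"


# ------------------------------------------------------------------ file IO


def load_pfm(
    path: str | Path,
    format: str = "jaspar",
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    name: str | None = None,
) -> MotifModel:
    """Load a single motif from a JASPAR raw-count or MEME-minimal file.

    Parsing is delegated to ``Bio.motifs``; the returned model renormalizes
    columns after adding the pseudocount and caches the derived PWM/EWM/IC
    and consensus.
    """
    models = load_pfms(path, format=format, background=background, pseudocount=pseudocount)
    if name is not None:
        for m in models:
            if m.name == name:
                return m
        raise MotifParseError(f"no motif named {name!r} in {path}")
    if len(models) != 1:
        raise MotifParseError(f"{path} contains {len(models)} motifs; pass name= to pick one")
    return models[0]


def load_pfms(
    path: str | Path,
    format: str = "jaspar",
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MotifModel]:
    """Load every motif in a JASPAR (``format="jaspar"``) or MEME minimal
    (``format="meme"``) file."""
    fmt = {"jaspar": "jaspar", "meme": "minimal", "minimal": "minimal"}.get(format.lower())
    if fmt is None:
        raise ValueError(f"unsupported motif format {format!r}")
    text = Path(path).read_text()
    try:
        records = _biomotifs.parse(io.StringIO(text), fmt)
        parsed = list(records)
    except Exception as exc:  # biopython raises assorted exception types
        raise MotifParseError(f"failed to parse {path} as {format}: {exc}") from exc
    if not parsed:
        raise MotifParseError(f"no motifs found in {path}")
    out = []
    for rec in parsed:
        counts = np.array([list(rec.counts[b]) for b in BASES], dtype=float)
        mname = rec.name or getattr(rec, "base_id", None)
        try:
            out.append(
                MotifModel(mname or Path(path).stem, counts, background=background, pseudocount=pseudocount)
            )
        except ValueError as exc:
            raise MotifParseError(f"{path}: motif {mname!r}: {exc}") from exc
    return out


def write_hits_bed(hits: Iterable[SiteHit], path: str | Path) -> None:
    """Write hits as 6-column BED (name=TF, score=log-odds x 100, strand)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.tf}\t{int(round(h.score * 100))}\t{h.strand}\n"
            )


def scan(
    motif: MotifModel,
    seq: str,
    p_threshold: float = 1e-3,
    sequence_id: str = "seq",
) -> list[SiteHit]:
    """Functional alias for :meth:`MotifModel.scan`."""
    return motif.scan(seq, p_threshold=p_threshold, sequence_id=sequence_id)


def score_pvalue(motif: MotifModel, score: float) -> float:
    """Functional alias for :meth:`MotifModel.score_pvalue`."""
    return motif.score_pvalue(score)
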