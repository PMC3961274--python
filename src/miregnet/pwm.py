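"""Match-style position-weight-matrix scanning of promoter sequences.

Transcription factors are predicted for the network by scanning 1,000-nt
promoter regions with positional base-frequency matrices. Each window is
scored with the information-weighted matrix similarity

    I(i)  = sum_b f(i,b) * ln(4 * f(i,b))        (0 * ln 0 := 0)
    S(w)  = sum_i I(i) * f(i, w_i)
    MSS   = (S - S_min) / (S_max - S_min)

where ``S_min``/``S_max`` use the per-position minimum/maximum frequencies,
so the consensus window scores 1 and the anti-consensus 0. The core
similarity (CSS) applies the same normalized score to the 5 consecutive
positions with the largest total information content (the "core"). A hit is
emitted when both scores meet their cutoffs; both strands are scanned and
coordinates are 0-based, half-open on the + strand of the promoter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

from .io import ContractError, ParseError

logger = logging.getLogger("miregnet")

__all__ = [
    "BASES",
    "PositionWeightMatrix",
    "PromoterSequence",
    "BindingSiteHit",
    "information_vector",
    "matrix_similarity",
    "core_similarity",
    "scan_promoter",
    "scan_promoters",
    "predicted_tf_set",
    "read_transfac",
    "write_transfac",
    "read_counts_tsv",
    "read_promoters_fasta",
    "write_hits_bed",
    "write_hits_json",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
CORE_LENGTH = 5
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_CSS_CUTOFF = 0.75
DEFAULT_MSS_CUTOFF = 0.85
EXPECTED_PROMOTER_LENGTH = 1000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BindingSiteHit:
    """One PWM match on a promoter (+-strand coordinates, half-open)."""

    tf: str
    gene: str
    start: int
    strand: str
    css: float
    mss: float


@dataclass
class PromoterSequence:
    """A promoter region owned by a gene; expected (not enforced) 1,000 nt."""

    gene: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(BASES + "N")
        if bad:
            raise ParseError(
                f"promoter {self.gene!r} contains invalid characters {sorted(bad)}"
            )
        if len(self.sequence) != EXPECTED_PROMOTER_LENGTH:
            logger.warning(
                "promoter %s is %d nt (expected %d)",
                self.gene, len(self.sequence), EXPECTED_PROMOTER_LENGTH,
            )


class PositionWeightMatrix:
    """Per-position base frequencies of a TF binding motif.

    Frequencies are derived from counts with a pseudocount per cell and
    normalized to sum to 1 at every position. The information vector, score
    bounds and core offset are precomputed once.
    """

    def __init__(self, name: str, frequencies: np.ndarray) -> None:
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4:
            raise ContractError("frequency matrix must have shape (L, 4)")
        if freqs.shape[0] < 4:
            raise ContractError("matrix length must be >= 4")
        if np.any(freqs < 0):
            raise ContractError("frequencies must be non-negative")
        rowsum = freqs.sum(axis=1, keepdims=True)
        if np.any(rowsum <= 0):
            raise ContractError("every position needs positive total frequency")
        self.name = name
        self.frequencies = freqs / rowsum
        self._info = information_vector(self)
        # per-window score bounds for MSS normalization
        self._smin = float(np.sum(self._info * self.frequencies.min(axis=1)))
        self._smax = float(np.sum(self._info * self.frequencies.max(axis=1)))
        self.core_start = self._find_core_start()

    @classmethod
    def from_counts(
        cls, name: str, counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float)
        return cls(name, counts + pseudocount)

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    @property
    def information(self) -> np.ndarray:
        return self._info

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=1))

    @property
    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmin(self.frequencies, axis=1))

    def reverse_complement(self) -> "PositionWeightMatrix":
        # reverse positions, swap A<->T and C<->G columns
        return PositionWeightMatrix(self.name, self.frequencies[::-1, ::-1])

    def _find_core_start(self) -> int | None:
        if self.length < CORE_LENGTH:
            return None
        sums = np.convolve(self._info, np.ones(CORE_LENGTH), mode="valid")
        return int(np.argmax(sums))  # argmax takes the leftmost maximum


def information_vector(pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-position information content I(i) = sum_b f ln(4f), with 0 ln 0 = 0."""
    f = pwm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return np.maximum(terms.sum(axis=1), 0.0)


def _encode(window: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[b] for b in window), dtype=np.intp,
                           count=len(window))
    except KeyError as exc:
        raise ContractError(f"invalid base {exc.args[0]!r} in window") from exc


def _normalized_score(pwm: PositionWeightMatrix, codes: np.ndarray,
                      positions: slice) -> float:
    f = pwm.frequencies[positions]
    info = pwm._info[positions]
    smin = float(np.sum(info * f.min(axis=1)))
    smax = float(np.sum(info * f.max(axis=1)))
    if smax - smin < 1e-12:
        return 1.0
    s = float(np.sum(info * f[np.arange(f.shape[0]), codes[positions]]))
    return (s - smin) / (smax - smin)


def matrix_similarity(pwm: PositionWeightMatrix, window: str) -> float:
    """MSS of a window against the full matrix, in [0, 1]."""
    if len(window) != pwm.length:
        raise ContractError(
            f"window length {len(window)} != matrix length {pwm.length}"
        )
    return _normalized_score(pwm, _encode(window.upper()), slice(None))


def core_similarity(pwm: PositionWeightMatrix, window: str) -> float:
    """CSS: the MSS formula restricted to the 5-position core.

    For matrices shorter than the core the rule degenerates to the MSS.
    """
    if len(window) != pwm.length:
        raise ContractError(
            f"window length {len(window)} != matrix length {pwm.length}"
        )
    if pwm.core_start is None:
        return matrix_similarity(pwm, window)
    core = slice(pwm.core_start, pwm.core_start + CORE_LENGTH)
    return _normalized_score(pwm, _encode(window.upper()), core)


def _strand_scores(pwm: PositionWeightMatrix,
                   codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MSS/CSS for every window start; returns (valid, mss, css)."""
    L, n = pwm.length, codes.size
    n_win = n - L + 1
    starts = np.arange(n_win)
    valid = np.ones(n_win, dtype=bool)
    scores = np.zeros(n_win)
    core = (slice(pwm.core_start, pwm.core_start + CORE_LENGTH)
            if pwm.core_start is not None else slice(None))
    core_scores = np.zeros(n_win)
    n_mask = codes < 0
    for j in range(L):
        col = codes[starts + j]
        valid &= ~n_mask[starts + j]
        contrib = pwm._info[j] * pwm.frequencies[j, np.where(col < 0, 0, col)]
        scores += contrib
        if core == slice(None) or (core.start <= j < core.stop):
            core_scores += contrib
    if pwm._smax - pwm._smin < 1e-12:
        mss = np.ones(n_win)
    else:
        mss = (scores - pwm._smin) / (pwm._smax - pwm._smin)
    f_core = pwm.frequencies[core]
    i_core = pwm._info[core]
    smin_c = float(np.sum(i_core * f_core.min(axis=1)))
    smax_c = float(np.sum(i_core * f_core.max(axis=1)))
    if smax_c - smin_c < 1e-12:
        css = np.ones(n_win)
    else:
        css = (core_scores - smin_c) / (smax_c - smin_c)
    return valid, mss, css


def scan_promoter(
    promoter: PromoterSequence,
    pwm: PositionWeightMatrix,
    css_cutoff: float = DEFAULT_CSS_CUTOFF,
    mss_cutoff: float = DEFAULT_MSS_CUTOFF,
) -> list[BindingSiteHit]:
    """Slide the matrix over both strands and emit hits meeting both cutoffs.

    Windows containing N (hard-masked runs) are skipped. Minus-strand hits
    are reported at the +-strand coordinate of the window start. Hits are
    sorted by (start, strand), '+' before '-'.
    """
    for cutoff in (css_cutoff, mss_cutoff):
        if not 0.0 <= cutoff <= 1.0:
            raise ContractError("cutoffs must lie in [0, 1]")
    seq = promoter.sequence
    if len(seq) < pwm.length:
        logger.warning(
            "promoter %s (%d nt) shorter than matrix %s (%d nt); no scan",
            promoter.gene, len(seq), pwm.name, pwm.length,
        )
        return []
    codes = np.fromiter(
        (_BASE_INDEX.get(b, -1) for b in seq), dtype=np.intp, count=len(seq)
    )
    hits: list[BindingSiteHit] = []
    rc_pwm = pwm.reverse_complement()
    for strand, matrix in (("+", pwm), ("-", rc_pwm)):
        # a window on the - strand read 5'->3' is the reverse complement of
        # the + strand window; scoring the rc-matrix on the + strand window
        # is equivalent and keeps coordinates in + strand space
        valid, mss, css = _strand_scores(matrix, codes)
        keep = valid & (mss >= mss_cutoff) & (css >= css_cutoff)
        for start in np.nonzero(keep)[0]:
            hits.append(BindingSiteHit(
                tf=pwm.name, gene=promoter.gene, start=int(start),
                strand=strand, css=float(css[start]), mss=float(mss[start]),
            ))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_promoters(
    promoters: Iterable[PromoterSequence],
    pwms: Iterable[PositionWeightMatrix],
    css_cutoff: float = DEFAULT_CSS_CUTOFF,
    mss_cutoff: float = DEFAULT_MSS_CUTOFF,
) -> list[BindingSiteHit]:
    """Scan every promoter with every matrix."""
    pwm_list = list(pwms)
    hits: list[BindingSiteHit] = []
    for promoter in promoters:
        for pwm in pwm_list:
            hits.extend(scan_promoter(promoter, pwm, css_cutoff, mss_cutoff))
    return hits


def predicted_tf_set(
    hits: Iterable[BindingSiteHit],
    promoter_owners: set[str] | None = None,
) -> set[str]:
    """Distinct TFs with >= 1 binding-site hit (optionally restricted to
    hits on the given promoter-owner genes); feeds the tf1000 integration."""
    return {
        h.tf for h in hits
        if promoter_owners is None or h.gene in promoter_owners
    }


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_transfac(path: str | Path,
                  pseudocount: float = DEFAULT_PSEUDOCOUNT,
                  ) -> list[PositionWeightMatrix]:
    """Read a TRANSFAC-dialect flat file (DE / P0 / numbered rows / XX //)."""
    with open(path, encoding="utf-8") as handle:
        parsed = bio_motifs.parse(handle, "transfac", strict=False)
    out = []
    for m in parsed:
        name = m.get("DE") or m.get("ID") or m.get("AC") or "unnamed"
        counts = np.column_stack([np.asarray(m.counts[b], dtype=float)
                                  for b in BASES])
        out.append(PositionWeightMatrix.from_counts(name, counts, pseudocount))
    if not out:
        raise ParseError(f"no matrices found in {path}")
    return out


def write_transfac(pwms: Sequence[PositionWeightMatrix],
                   path_or_handle: str | Path | TextIO,
                   scale: int = 100) -> None:
    """Write matrices in the TRANSFAC dialect (frequencies scaled to counts)."""

    def _write(fh: TextIO) -> None:
        for pwm in pwms:
            fh.write(f"ID {pwm.name}\nDE {pwm.name}\n")
            fh.write("P0      A      C      G      T\n")
            counts = np.rint(pwm.frequencies * scale).astype(int)
            for i, row in enumerate(counts, start=1):
                cells = "".join(f"{c:7d}" for c in row)
                fh.write(f"{i:02d}{cells}\n")
            fh.write("XX\n//\n")

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)  # type: ignore[arg-type]
    else:
        with open(path_or_handle, "w", encoding="utf-8") as fh:
            _write(fh)


def read_counts_tsv(path: str | Path, name: str | None = None,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    ) -> PositionWeightMatrix:
    """Read a simple 4-column (A C G T) count TSV; '#' comments allowed.

    A first row of base letters is treated as a header.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            if not rows and all(c.strip().upper() in BASES for c in cols):
                continue
            try:
                rows.append([float(c) for c in cols])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count") from exc
    if not rows:
        raise ParseError(f"no count rows in {path}")
    return PositionWeightMatrix.from_counts(
        name or path.stem, np.asarray(rows), pseudocount
    )


def read_promoters_fasta(path: str | Path) -> list[PromoterSequence]:
    """Read promoter sequences from FASTA; record ids are owner gene names."""
    return [
        PromoterSequence(gene=record.id, sequence=str(record.seq))
        for record in SeqIO.parse(str(path), "fasta")
    ]


def write_hits_bed(hits: Sequence[BindingSiteHit],
                   pwms: Sequence[PositionWeightMatrix],
                   path: str | Path) -> None:
    """Write hits as BED6-compatible TSV: gene, start, end, TF, 1000*MSS, strand."""
    lengths = {p.name: p.length for p in pwms}
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            end = h.start + lengths[h.tf]
            fh.write(f"{h.gene}\t{h.start}\t{end}\t{h.tf}\t"
                     f"{round(1000 * h.mss)}\t{h.strand}\n")


def write_hits_json(hits: Sequence[BindingSiteHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            [
                {"tf": h.tf, "gene": h.gene, "start": h.start,
                 "strand": h.strand, "css": h.css, "mss": h.mss}
                for h in hits
            ],
            fh, indent=2,
        )
        fh.write("\n")
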