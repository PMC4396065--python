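"""Regulatory-motif screening: JASPAR PWM scanning and consensus-box detection.

Guides whose sequence contains a common regulatory element (CCAAT box,
TATA box, GC box) risk cutting conserved regulatory sites at their
off-target loci, so such candidates are flagged and can be filtered out.

PWM scoring: counts -> probabilities with a pseudocount of 1 per cell,
log2 odds against a uniform 0.25 background, both strands scanned; a hit
is any window scoring at least ``threshold_fraction`` of the maximum
attainable score.  Consensus motifs are matched exactly under IUPAC
degeneracy and scored by their length.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs

from .sequence import reverse_complement

__all__ = [
    "PositionFrequencyMatrix",
    "MotifHit",
    "ConsensusMotif",
    "CCAAT_BOX",
    "TATA_BOX",
    "GC_BOX",
    "COMMON_ELEMENTS",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "pwm_scan",
    "consensus_scan",
    "flag_common_elements",
    "consensus_to_pfm",
]

_ROWS = "ACGT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class PositionFrequencyMatrix:
    """A 4 x L matrix of base counts (rows A, C, G, T)."""

    motif_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("matrix has an all-zero column")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    def log_odds(self) -> np.ndarray:
        """log2-odds weights vs uniform background, pseudocount 1 per cell."""
        probs = (self.counts + 1.0) / (self.counts.sum(axis=0) + 4.0)
        return np.log2(probs / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ROWS[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence in a scanned sequence.

    ``offset`` is the 0-based start of the match footprint in the scanned
    sequence (reference orientation); ``matched`` is the matching text as
    read 5'->3' on the hit strand.
    """

    motif_name: str
    offset: int
    strand: str
    score: float
    matched: str


@dataclass(frozen=True)
class ConsensusMotif:
    name: str
    iupac: str

    def __post_init__(self) -> None:
        bad = set(self.iupac) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters: {sorted(bad)}")


# Canonical textbook consensi for the three common core-promoter elements.
CCAAT_BOX = ConsensusMotif("CCAAT_box", "CCAAT")
TATA_BOX = ConsensusMotif("TATA_box", "TATAWAW")
GC_BOX = ConsensusMotif("GC_box", "GGGCGG")
COMMON_ELEMENTS = (CCAAT_BOX, TATA_BOX, GC_BOX)


def read_jaspar_pfm(path) -> list[PositionFrequencyMatrix]:
    """Parse a JASPAR-format PFM text file (bracketed A/C/G/T count rows)."""
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:
        raise ValueError(f"cannot parse JASPAR file {path}: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[base]) for base in _ROWS], dtype=float)
        name = m.name or m.matrix_id or "motif"
        out.append(PositionFrequencyMatrix(str(name), counts))
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out


def write_jaspar_pfm(pfms: list[PositionFrequencyMatrix], path) -> None:
    """Write matrices in JASPAR format (``>name`` plus bracketed count rows)."""
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_name} {pfm.motif_name}\n")
            for i, base in enumerate(_ROWS):
                row = " ".join(f"{v:g}" for v in pfm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


_BASE_INDEX = {b: i for i, b in enumerate(_ROWS)}


def _score_windows(seq: str, weights: np.ndarray) -> np.ndarray:
    """Score of every window of length L in seq; N-containing windows -> -inf."""
    L = weights.shape[1]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
    scores = np.full(n, 0.0)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = idx[j : j + n]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, weights[col.clip(0), j], 0.0)
    scores[~valid] = -np.inf
    return scores


def pwm_scan(
    sequence: str, pfm: PositionFrequencyMatrix, threshold_fraction: float = 0.8
) -> list[MotifHit]:
    """All windows on either strand scoring >= threshold_fraction x max score."""
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    sequence = sequence.upper()
    weights = pfm.log_odds()
    L = pfm.length
    threshold = threshold_fraction * pfm.max_score
    hits: list[MotifHit] = []
    fwd = _score_windows(sequence, weights)
    for j in np.flatnonzero(fwd >= threshold - 1e-9):
        hits.append(
            MotifHit(pfm.motif_name, int(j), "+", float(fwd[j]), sequence[j : j + L])
        )
    rc = reverse_complement(sequence)
    rev = _score_windows(rc, weights)
    for j in np.flatnonzero(rev >= threshold - 1e-9):
        offset = len(sequence) - int(j) - L
        hits.append(
            MotifHit(pfm.motif_name, offset, "-", float(rev[j]), rc[j : j + L])
        )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _iupac_match(text: str, pattern: str) -> bool:
    return all(b in IUPAC[p] for b, p in zip(text, pattern))


def consensus_scan(sequence: str, motif: ConsensusMotif) -> list[MotifHit]:
    """Exact IUPAC matches of the consensus on both strands; score = length."""
    sequence = sequence.upper()
    L = len(motif.iupac)
    hits: list[MotifHit] = []
    for j in range(len(sequence) - L + 1):
        window = sequence[j : j + L]
        if _iupac_match(window, motif.iupac):
            hits.append(MotifHit(motif.name, j, "+", float(L), window))
        rc_window = reverse_complement(window)
        if _iupac_match(rc_window, motif.iupac):
            hits.append(MotifHit(motif.name, j, "-", float(L), rc_window))
    return hits


def flag_common_elements(site) -> list[str]:
    """Names of common regulatory boxes present anywhere in the 23-nt site.

    Accepts a :class:`~sgselect.candidates.CandidateSite` or a plain
    sequence string.
    """
    seq = site.sequence if hasattr(site, "sequence") else str(site)
    return [m.name for m in COMMON_ELEMENTS if consensus_scan(seq, m)]


def consensus_to_pfm(motif: ConsensusMotif) -> PositionFrequencyMatrix:
    """Degenerate one-hot matrix for a consensus (allowed bases count 1)."""
    counts = np.zeros((4, len(motif.iupac)))
    for j, p in enumerate(motif.iupac):
        for b in IUPAC[p]:
            counts[_BASE_INDEX[b], j] = 1.0
    return PositionFrequencyMatrix(motif.name, counts)
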