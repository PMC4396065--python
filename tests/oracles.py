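"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive — regex lookahead, sliding-window
Hamming comparison, quadratic overlap, direct summation — and shares no
code with the implementation under test.
"""

from __future__ import annotations

import math
import re

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


_PATTERN = re.compile(r"(?=(G[ACGT]{19}[ACGT]GG))")


def regex_scan_oracle(seq: str, region_start: int = 0) -> set[tuple[int, str]]:
    """All G-N19-NGG site (ref_start, strand) pairs via regex lookahead."""
    sites = set()
    for m in _PATTERN.finditer(seq):
        sites.add((region_start + m.start(), "+"))
    n = len(seq)
    for m in _PATTERN.finditer(rc(seq)):
        sites.add((region_start + n - m.start() - 23, "-"))
    return sites


def brute_offtargets_oracle(
    sequences: dict[str, str],
    protospacer: str,
    max_mm: int,
    exclude: tuple[str, int, str] | None = None,
) -> set[tuple[str, int, str, int]]:
    """Sliding-window Hamming scan of every 23-nt window on both strands.

    Returns (seq_name, ref_start, strand, mismatch_count) tuples for
    windows with an N-free NGG PAM and <= max_mm mismatches over the
    20-nt protospacer alignment; ``exclude`` drops the on-target locus.
    """
    hits = set()
    parr = np.frombuffer(protospacer.encode(), dtype=np.uint8)
    G, N = ord("G"), ord("N")
    for name, seq in sequences.items():
        n = len(seq)
        if n < 23:
            continue
        for strand in ("+", "-"):
            s = seq if strand == "+" else rc(seq)
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            win = np.lib.stride_tricks.sliding_window_view(arr, 23)
            pam_ok = (win[:, 20] != N) & (win[:, 21] == G) & (win[:, 22] == G)
            mism = (win[:, :20] != parr) | (win[:, :20] == N)
            counts = mism.sum(axis=1)
            for i in np.flatnonzero(pam_ok & (counts <= max_mm)):
                ref_start = int(i) if strand == "+" else n - int(i) - 23
                key = (name, ref_start, strand)
                if key == exclude:
                    continue
                hits.add((name, ref_start, strand, int(counts[i])))
    return hits


def overlap_counts_oracle(hit_spans, exons, peaks):
    """Quadratic all-pairs classification: exon > tfbs > ncdna.

    ``hit_spans``: (seq_name, start, end) triples; ``exons`` likewise;
    ``peaks``: (tf_name, seq_name, start, end).  Returns a category list.
    """
    cats = []
    for name, s, e in hit_spans:
        in_exon = any(n == name and s < ee and es < e for n, es, ee in exons)
        in_peak = any(n == name and s < pe and ps < e for _, n, ps, pe in peaks)
        cats.append("exon" if in_exon else ("tfbs" if in_peak else "ncdna"))
    return cats


def binom_upper_tail_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def pwm_scores_oracle(seq: str, counts: np.ndarray):
    """Per-position, per-strand log2-odds scores computed base by base.

    counts: 4 x L (rows A,C,G,T).  Returns {(offset, strand): score}
    with offsets in the forward sequence; N-containing windows omitted.
    """
    L = counts.shape[1]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = (counts + 1.0) / (counts.sum(axis=0) + 4.0)
    weights = np.log2(probs / 0.25)
    out = {}
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        for j in range(len(s) - L + 1):
            window = s[j : j + L]
            if "N" in window:
                continue
            score = sum(weights[idx[b], p] for p, b in enumerate(window))
            offset = j if strand == "+" else len(seq) - j - L
            out[(offset, strand)] = score
    return out
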