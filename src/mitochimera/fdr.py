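"""Reverse-decoy databases and simple target-decoy q-values.

Vendor search scores are taken as given; the estimator here is the plain
target-decoy competition q-value: at a score threshold s,
FDR(s) = #(decoys >= s) / max(1, #(targets >= s)), and the q-value of a
hit is the minimum FDR over all thresholds that still accept it.  This
replaces semi-supervised rescoring (Percolator), which operates on
spectral features outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np


@dataclass(frozen=True)
class ScoredHit:
    peptide: str
    score: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


def reverse_decoy(sequence: str) -> str:
    """Full-sequence reversal (the decoy transform)."""
    return sequence[::-1]


def make_decoy_db(
    records: Iterable[Tuple[str, str]], tag: str = "decoy"
) -> List[Tuple[str, str]]:
    """Reverse every (header, sequence) record; headers gain a decoy tag.

    Record count is preserved; a palindromic sequence stays identical but
    is still tagged.
    """
    return [(f"{header}|{tag}", reverse_decoy(seq)) for header, seq in records]


def qvalues(hits: Sequence[ScoredHit]) -> np.ndarray:
    """Target-decoy q-value for each hit, aligned with the input order.

    Tied scores share a q; q is monotone non-decreasing as score
    decreases and capped at 1.  Raises if there is no target hit.
    """
    hits = list(hits)
    scores = np.array([h.score for h in hits], dtype=float)
    decoy = np.array([h.is_decoy for h in hits], dtype=bool)
    if len(hits) == 0 or decoy.all():
        raise ValueError("at least one target hit is required")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = decoy[order]
    cum_decoy = np.cumsum(d_sorted)
    cum_target = np.cumsum(~d_sorted)

    # at threshold = s_sorted[i], counts include the whole tie group
    n = len(hits)
    fdr = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        fdr[i : j + 1] = cum_decoy[j] / max(1, cum_target[j])
        i = j + 1

    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)

    q = np.empty(n)
    q[order] = q_sorted
    return q
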