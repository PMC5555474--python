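"""Pairwise global alignment with affine gaps.

Thin wrapper over ``Bio.Align.PairwiseAligner`` with the package's scoring
convention: match +1, mismatch -1, gap open -5 (charged on the first gapped
column), gap extend -1. The first optimal alignment in Biopython's
deterministic enumeration order is returned, so results are reproducible.
"""

from __future__ import annotations

import warnings

from Bio import Align

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = -1.0


def _aligner(free_end_gaps: bool) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    if free_end_gaps:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a.target_end_gap_score = 0.0
            a.query_end_gap_score = 0.0
    return a


def pairwise_align(
    query: str,
    reference: str,
    *,
    free_end_gaps: bool = False,
) -> tuple[str, str, float]:
    """Globally align ``query`` to ``reference``.

    Returns ``(gapped_query, gapped_reference, score)`` with equal gapped
    lengths. With ``free_end_gaps`` terminal gaps in either sequence are not
    penalised (overlap / semi-global alignment), appropriate when one
    sequence may be a truncated fragment of the other.
    """
    if not query or not reference:
        raise ValueError("both sequences must be non-empty")
    aln = _aligner(free_end_gaps).align(reference.upper(), query.upper())[0]
    return aln[1], aln[0], aln.score


def alignment_score(gapped_a: str, gapped_b: str) -> float:
    """Score an existing alignment under the package convention."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("gapped lengths differ")
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(gapped_a, gapped_b):
        if x == "-" and y == "-":
            raise ValueError("column gapped in both sequences")
        if x == "-":
            score += GAP_EXTEND if in_gap_a else GAP_OPEN
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += GAP_EXTEND if in_gap_b else GAP_OPEN
            in_gap_b, in_gap_a = True, False
        else:
            score += MATCH if x == y else MISMATCH
            in_gap_a = in_gap_b = False
    return score
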