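"""Dinucleotide-context classification of RIP mutations.

Every C→T difference of a query relative to the highest-GC consensus is
classified by the consensus base in the nearest non-gap column 3' of the
site; every G→A difference by the nearest non-gap consensus base 5' of the
site, which is the reverse-complement reading of the same class (a TpG→TpA
change is a CpA→TpA change on the other strand). The four classes follow
the RIPCAL colour convention:

* ``CpA``  — CpA↔TpA or TpG↔TpA
* ``CpC``  — CpC↔TpC or GpG↔GpA
* ``CpG``  — CpG↔TpG or CpG↔CpA
* ``CpT``  — CpT↔TpT or ApG↔ApA

Context is always read from the consensus, never from the mutated query:
in a heavily RIPped copy the neighbouring base may itself be mutated, which
would corrupt the context class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqs import GAP, complement_base

CONTEXT_CLASSES = ("CpA", "CpC", "CpG", "CpT")


@dataclass
class RipProfile:
    context_counts: dict[str, int]
    rip_rate: float
    dominance: float
    dominance_clamped: bool
    aligned_sites: int

    @property
    def total_rip(self) -> int:
        return sum(self.context_counts.values())


def _nearest_base(consensus: str, column: int, direction: int) -> str | None:
    j = column + direction
    while 0 <= j < len(consensus):
        if consensus[j] != GAP:
            return consensus[j]
        j += direction
    return None


def classify_rip_context(
    consensus: str,
    column: int,
    ref_base: str,
    alt_base: str,
) -> str:
    """Context class of a single C→T or G→A difference.

    Returns one of ``CpA``/``CpC``/``CpG``/``CpT`` or ``"unclassified"``
    when the flanking neighbour does not exist (sequence edge) or is not an
    unambiguous base.
    """
    if (ref_base, alt_base) not in (("C", "T"), ("G", "A")):
        raise ValueError(f"not a RIP substitution: {ref_base}->{alt_base}")
    if not 0 <= column < len(consensus):
        raise ValueError("column outside alignment")
    if ref_base == "C":
        nb = _nearest_base(consensus, column, +1)
        ctx = None if nb is None else "Cp" + nb
    else:
        nb = _nearest_base(consensus, column, -1)
        ctx = None if nb is None else "Cp" + complement_base(nb)
    return ctx if ctx in CONTEXT_CLASSES else "unclassified"


def compute_rip_profile(gapped_query: str, gapped_consensus: str) -> RipProfile:
    """Classify all RIP differences of a query against the consensus.

    ``rip_rate`` is (C→T + G→A count) / aligned sites, with aligned sites the
    gap-free unambiguous comparable columns — the same denominator as the
    mutation-spectrum rates, so the two stay mutually consistent.
    ``dominance`` is the CpA-class count over the summed other three
    classes; when those are empty the denominator is clamped to 1 and
    flagged.
    """
    if len(gapped_query) != len(gapped_consensus):
        raise ValueError("gapped lengths differ")
    counts = dict.fromkeys((*CONTEXT_CLASSES, "unclassified"), 0)
    aligned = 0
    for i, (q, c) in enumerate(zip(gapped_query, gapped_consensus)):
        if q == GAP or c == GAP or q not in "ACGT" or c not in "ACGT":
            continue
        aligned += 1
        if (c, q) in (("C", "T"), ("G", "A")):
            counts[classify_rip_context(gapped_consensus, i, c, q)] += 1
    total = sum(counts.values())
    rate = total / aligned if aligned else 0.0
    others = counts["CpC"] + counts["CpG"] + counts["CpT"]
    clamped = others == 0
    dominance = counts["CpA"] / max(1, others)
    return RipProfile(counts, rate, dominance, clamped, aligned)


def windowed_rip(
    alignment: dict[str, str],
    consensus_id: str,
    window: int = 50,
    step: int = 50,
) -> pd.DataFrame:
    """Windowed per-class RIP mutation track (heat-map style output).

    One row per (sequence, window): the four context-class counts plus
    ``unclassified``, the invariant-column and gap-column tallies. With
    ``step == window`` the windows partition the alignment, so column sums
    reproduce the global profile counts.
    """
    if not 1 <= step <= window:
        raise ValueError("need window >= step >= 1")
    consensus = alignment[consensus_id]
    ncol = len(consensus)
    window = min(window, ncol) if ncol else window
    rows = []
    for sid, seq in alignment.items():
        if sid == consensus_id:
            continue
        if len(seq) != ncol:
            raise ValueError(f"sequence {sid} length differs from consensus")
        if ncol <= window:
            starts = [0]
        else:
            starts = list(range(0, ncol - window + 1, step))
            if starts[-1] + window < ncol:  # truncated tail window keeps tiling exact
                starts.append(starts[-1] + step)
        for s in starts:
            e = min(ncol, s + window)
            counts = dict.fromkeys((*CONTEXT_CLASSES, "unclassified"), 0)
            invariant = gaps = 0
            for i in range(s, e):
                q, c = seq[i], consensus[i]
                if q == GAP or c == GAP:
                    gaps += 1
                    continue
                if (c, q) in (("C", "T"), ("G", "A")):
                    counts[classify_rip_context(consensus, i, c, q)] += 1
                elif q == c:
                    invariant += 1
            rows.append(
                {
                    "sequence_id": sid,
                    "window_start": s,
                    "window_end": e,
                    **counts,
                    "invariant": invariant,
                    "gap": gaps,
                }
            )
    return pd.DataFrame(rows)
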