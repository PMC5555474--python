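"""Small shared sequence helpers.

Conventions used across the package:

* plain DNA strings over the uppercase alphabet ``ACGT`` (IUPAC ambiguity
  codes are tolerated on input but excluded from all rate denominators);
* gap character ``-`` in aligned (gapped) strings;
* intervals are 0-based half-open in memory and 1-based inclusive in every
  emitted TSV.
"""

from __future__ import annotations

import numpy as np

GAP = "-"
DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

# byte codes for vectorised column arithmetic: transitions (A<->G, C<->T)
# differ by exactly 2 in this encoding, transversions by an odd amount.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement, preserving common ambiguity codes and gaps."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Encode a (possibly gapped) string as uint8; non-ACGT -> 255."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def gc_fraction(seq: str) -> float:
    """G+C over counted (non-gap, non-ambiguous) bases.

    Raises ``ValueError`` if nothing is countable.
    """
    codes = encode(seq)
    counted = codes != 255
    n = int(counted.sum())
    if n == 0:
        raise ValueError("no unambiguous bases to compute GC content over")
    gc = int(np.isin(codes, (1, 2)).sum())  # C=1, G=2
    return gc / n


def check_dna(seq: str, *, what: str = "sequence") -> None:
    """Require a strict ACGT string (the simulator's input contract)."""
    if not seq or set(seq) - set(DNA):
        bad = sorted(set(seq) - set(DNA))
        raise ValueError(f"{what} must be non-empty over ACGT; offending characters: {bad}")


def wrap_fasta(records: list[tuple[str, str]], width: int = 80) -> str:
    """Serialize (id, seq) pairs as FASTA wrapped at ``width`` columns."""
    out = []
    for name, seq in records:
        out.append(f">{name}")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
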