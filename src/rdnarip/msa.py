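"""Reference-anchored multiple alignment.

Each sequence is aligned pairwise to a designated reference and the pairwise
alignments are merged on reference coordinates, inserting shared gap columns
where any sequence carries an insertion. This is deterministic and entirely
adequate for rDNA paralog sets, which are colinear with the reference by
construction; it is not a general progressive aligner.
"""

from __future__ import annotations

from .align import pairwise_align
from .seqs import GAP


def reference_anchored_msa(
    sequences: dict[str, str],
    reference_id: str,
    *,
    free_end_gaps: bool = True,
) -> dict[str, str]:
    """Multiple alignment of ``sequences`` anchored on ``reference_id``.

    Returns gapped strings of equal length, reference included.
    """
    ref = sequences[reference_id]
    R = len(ref)
    # per sequence: insertions before each reference position (and after the
    # last), plus the residue (or gap) matched to each reference position
    profiles: dict[str, tuple[list[str], list[str]]] = {}
    for sid, seq in sequences.items():
        if sid == reference_id:
            continue
        gq, gr, _ = pairwise_align(seq, ref, free_end_gaps=free_end_gaps)
        ins = [""] * (R + 1)
        matched = [GAP] * R
        rpos = 0
        for cq, cr in zip(gq, gr):
            if cr == GAP:
                if cq != GAP:
                    ins[rpos] += cq
            else:
                if cq != GAP:
                    matched[rpos] = cq
                rpos += 1
        profiles[sid] = (ins, matched)

    ins_len = [0] * (R + 1)
    for ins, _ in profiles.values():
        for k in range(R + 1):
            ins_len[k] = max(ins_len[k], len(ins[k]))

    out: dict[str, str] = {}
    for sid in sequences:
        parts = []
        if sid == reference_id:
            for k in range(R):
                parts.append(GAP * ins_len[k])
                parts.append(ref[k])
            parts.append(GAP * ins_len[R])
        else:
            ins, matched = profiles[sid]
            for k in range(R):
                parts.append(ins[k].ljust(ins_len[k], GAP))
                parts.append(matched[k])
            parts.append(ins[R].ljust(ins_len[R], GAP))
        out[sid] = "".join(parts)
    return out
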