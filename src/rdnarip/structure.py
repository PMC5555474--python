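"""Mapping mutations onto an rRNA secondary-structure pairing table.

A curated structure model (e.g. from comparative rRNA databases) is consumed
as a two-column table of 1-based paired positions, or as a dot-bracket
string. A mutation at a paired position is *disrupting* when the
post-mutation base pair is no longer one of the six pairs tolerated in rRNA
helices — the four Watson-Crick pairs plus the G·U wobble (DNA read as RNA,
T ≡ U). A strict Watson-Crick mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class PairingTable:
    """1-based position pairs (i < j) on a reference subunit."""

    pairs: list[tuple[int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[int] = set()
        norm = []
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"self-pairing at position {i}")
            i, j = (i, j) if i < j else (j, i)
            if i in seen or j in seen:
                raise ValueError(f"position appears in more than one pair: {(i, j)}")
            seen.update((i, j))
            norm.append((i, j))
        self.pairs = sorted(norm)

    @property
    def partner(self) -> dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class StructureImpact:
    n_paired_mut: int
    n_unpaired_mut: int
    disrupted_pairs: list[tuple[tuple[int, int], str, str]]  # (pair, ref bases, mutated bases)

    @property
    def n_disrupting(self) -> int:
        return len(self.disrupted_pairs)


def read_pairing_tsv(path) -> PairingTable:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j = line.split("\t")[:2]
            pairs.append((int(i), int(j)))
    return PairingTable(pairs, source=str(path))


def pairs_from_dot_bracket(db: str) -> PairingTable:
    """Convert a dot-bracket string to 1-based pairs.

    Only nested round brackets are supported; square/curly brackets would
    denote pseudoknots and are rejected.
    """
    if set(db) - set(".()"):
        bad = sorted(set(db) - set(".()"))
        raise ValueError(f"unsupported dot-bracket characters (pseudoknots?): {bad}")
    stack: list[int] = []
    pairs = []
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced bracket at position {pos}")
            pairs.append((stack.pop(), pos))
    if stack:
        raise ValueError(f"unbalanced brackets, {len(stack)} left open")
    return PairingTable(pairs, source="dot-bracket")


def map_mutations_to_structure(
    mutations: list[tuple[int, str, str]],
    table: PairingTable,
    reference: str,
    *,
    strict_wc: bool = False,
) -> StructureImpact:
    """Count paired/unpaired mutations and collect disrupted pairs.

    ``mutations`` are (1-based reference position, ref_base, alt_base).
    Positions must lie on the reference and their ref_base must match it;
    offending entries are reported together in one error.
    """
    allowed = WC_PAIRS if strict_wc else VALID_PAIRS
    bad = []
    for pos, ref_base, _ in mutations:
        if not 1 <= pos <= len(reference):
            bad.append((pos, ref_base, "position outside reference"))
        elif reference[pos - 1] != ref_base:
            bad.append((pos, ref_base, f"reference has {reference[pos - 1]}"))
    if bad:
        raise ValueError(f"mutations inconsistent with reference: {bad}")
    for i, j in table.pairs:
        if j > len(reference):
            raise ValueError(f"pair {(i, j)} outside reference length {len(reference)}")

    partner = table.partner
    mutated = {pos: alt for pos, _, alt in mutations}
    n_paired = n_unpaired = 0
    disrupted = []
    seen_pairs: set[tuple[int, int]] = set()
    for pos, _ref_base, _alt in mutations:
        if pos not in partner:
            n_unpaired += 1
            continue
        n_paired += 1
        i, j = min(pos, partner[pos]), max(pos, partner[pos])
        if (i, j) in seen_pairs:
            continue  # compensatory partner already assessed with this pair
        seen_pairs.add((i, j))
        ref_i, ref_j = reference[i - 1], reference[j - 1]
        new_i = mutated.get(i, ref_i)
        new_j = mutated.get(j, ref_j)
        if (new_i, new_j) not in allowed:
            disrupted.append(((i, j), ref_i + ref_j, new_i + new_j))
    return StructureImpact(n_paired, n_unpaired, disrupted)


def position_annotation(
    table: PairingTable,
    reference: str,
    impact: StructureImpact,
) -> list[tuple[int, str]]:
    """Per-position class for a BED-like emission: paired/unpaired/disrupted."""
    disrupted_pos = {p for pair, _, _ in impact.disrupted_pairs for p in pair}
    partner = table.partner
    out = []
    for pos in range(1, len(reference) + 1):
        if pos in disrupted_pos:
            out.append((pos, "disrupted"))
        elif pos in partner:
            out.append((pos, "paired"))
        else:
            out.append((pos, "unpaired"))
    return out
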