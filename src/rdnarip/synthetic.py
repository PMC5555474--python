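"""Synthetic rDNA assemblies with RIP-mutated paralogs and a known truth table.

The generator emulates the situation the downstream analyses assume: a fungal
genome carrying N copies of the 45S rDNA unit (18S-ITS1-5.8S-ITS2-28S-IGS),
of which a subset has been hit by repeat-induced point mutation (RIP) —
C→T transitions classified by their 3' neighbour and the strand-symmetric
G→A transitions classified by their 5' neighbour — plus a very low rate of
background substitutions emulating sequencing/assembly noise. Paralogs are
embedded in contigs with random non-rDNA flanks, on either strand, and a
share of them is truncated to mimic partial assembly of repeats.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` instances, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .seqs import check_dna, complement_base, gc_fraction, revcomp

SUBUNIT_ORDER = ("18S", "ITS1", "5.8S", "ITS2", "28S", "IGS")
CODING_SUBUNITS = ("18S", "5.8S", "28S")
RIP_CONTEXTS = ("CpA", "CpC", "CpG", "CpT")

#: unit layout used throughout the package's examples: a ~7.7 kb repeat with
#: gene and spacer lengths in the range reported for filamentous ascomycetes.
DEFAULT_SUBUNIT_LENGTHS = {
    "18S": 1800,
    "ITS1": 200,
    "5.8S": 160,
    "ITS2": 200,
    "28S": 3300,
    "IGS": 2000,
}
#: functional coding genes sit in the observed high-GC band (>=0.46);
#: spacers are near 0.50 in these taxa.
DEFAULT_SUBUNIT_GC = {
    "18S": 0.48,
    "ITS1": 0.50,
    "5.8S": 0.48,
    "ITS2": 0.50,
    "28S": 0.48,
    "IGS": 0.50,
}


class MutationEvent(NamedTuple):
    """One simulated substitution.

    ``context`` is one of the four RIP dinucleotide classes (``CpA`` ...
    ``CpT``, G→A events reported via their reverse-complement C context)
    or ``"background"`` for non-RIP noise.
    """

    position: int
    ref_base: str
    alt_base: str
    context: str


@dataclass(frozen=True)
class UnitTemplate:
    """A reference 45S repeat with per-subunit coordinates."""

    subunit_lengths: dict[str, int]
    subunit_gc: dict[str, float]
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def boundaries(self) -> dict[str, tuple[int, int]]:
        """0-based half-open interval of each subunit on the unit."""
        out, pos = {}, 0
        for name in SUBUNIT_ORDER:
            if name in self.subunit_lengths:
                out[name] = (pos, pos + self.subunit_lengths[name])
                pos += self.subunit_lengths[name]
        return out

    def subunit_sequence(self, name: str) -> str:
        s, e = self.boundaries[name]
        return self.sequence[s:e]


@dataclass
class RipParams:
    """Parameters of the RIP + noise process applied to pseudogene copies.

    ``context_rates`` are per-eligible-site mutation probabilities keyed by
    the C-strand dinucleotide context; they are applied symmetrically to G
    sites via the reverse-complement context (TpG sites behave like CpA).
    The default rates put the CpA class first, matching the dominance of
    CpA↔TpA mutations observed in RIP-affected fungal genomes, and produce
    overall RIP rates in the ~15-25% band seen in rDNA pseudogenes.
    """

    n_paralogs: int = 10
    pseudogene_fraction: float = 0.8
    context_rates: dict[str, float] = field(
        default_factory=lambda: {"CpA": 0.75, "CpC": 0.18, "CpG": 0.22, "CpT": 0.18}
    )
    background_rate: float = 0.001
    intron_rate: float = 0.0
    intron_length: int = 60
    rounds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_paralogs < 1:
            raise ValueError("n_paralogs must be positive")
        if not 0.0 <= self.pseudogene_fraction <= 1.0:
            raise ValueError("pseudogene_fraction must lie in [0, 1]")
        for ctx in self.context_rates:
            if ctx not in RIP_CONTEXTS:
                raise ValueError(f"unknown RIP context {ctx!r}")
            if not 0.0 <= self.context_rates[ctx] <= 1.0:
                raise ValueError(f"context rate for {ctx} outside [0, 1]")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must lie in [0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class TruthTable:
    """Ground truth for one synthetic assembly.

    ``records`` holds one row per paralog (contig placement, strand,
    pseudogene and completeness flags); ``sequences`` the plus-strand
    sequence of each embedded repeat region; ``logs`` the full mutation log
    of each pseudogene, positions 0-based on that paralog's complete unit
    (before any truncation).
    """

    records: pd.DataFrame
    sequences: dict[str, str]
    logs: dict[str, list[MutationEvent]]

    def to_tsv(self, path) -> None:
        """Emit with 1-based inclusive coordinates and a {+,-} strand column."""
        df = self.records.copy()
        df["start"] = df["start"] + 1
        df.to_csv(path, sep="\t", index=False)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with realized GC fixed at round(length * gc) bases."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("GC target must lie in (0, 1)")
    n_gc = int(round(length * gc))
    bases = np.empty(length, dtype="<U1")
    at = rng.choice(np.array(["A", "T"]), size=length)
    bases[:] = at
    gc_pos = rng.choice(length, size=n_gc, replace=False)
    bases[gc_pos] = rng.choice(np.array(["G", "C"]), size=n_gc)
    return "".join(bases)


def generate_reference_unit(
    subunit_lengths: dict[str, int] | None = None,
    subunit_gc: dict[str, float] | None = None,
    rng_seed: int = 0,
) -> UnitTemplate:
    """Build a random 45S unit hitting each subunit's GC target within 1 pp."""
    lengths = dict(DEFAULT_SUBUNIT_LENGTHS if subunit_lengths is None else subunit_lengths)
    gc = dict(DEFAULT_SUBUNIT_GC if subunit_gc is None else subunit_gc)
    missing = set(lengths) - set(gc)
    if missing:
        raise ValueError(f"no GC target for subunits: {sorted(missing)}")
    rng = np.random.default_rng(rng_seed)
    parts = []
    for name in SUBUNIT_ORDER:
        if name not in lengths:
            continue
        parts.append(random_dna(lengths[name], gc[name], rng))
    return UnitTemplate(lengths, gc, "".join(parts))


def rip_context_of(sequence: str, position: int) -> str | None:
    """RIP context class of a C or G site, read from ``sequence`` itself.

    C sites are classified by the 3' neighbour, G sites by the complement of
    the 5' neighbour (a TpG site is a CpA site on the minus strand).
    Returns ``None`` for non-C/G bases and for edge sites whose neighbour
    does not exist.
    """
    base = sequence[position]
    if base == "C":
        if position + 1 >= len(sequence):
            return None
        return "Cp" + sequence[position + 1]
    if base == "G":
        if position == 0:
            return None
        return "Cp" + complement_base(sequence[position - 1])
    return None


def apply_rip(
    sequence: str,
    params: RipParams,
    rng_seed: int | None = None,
) -> tuple[str, list[MutationEvent]]:
    """Apply context-biased RIP transitions plus background noise.

    RIP is applied in a single pass per round against a snapshot of the
    sequence at the start of the round (default one round, i.e. contexts are
    read from the original, unmutated sequence — which makes the logged
    contexts exactly recoverable). Background substitutions are drawn
    uniformly over the ten non-RIP substitution classes and never touch a
    site already RIPped.
    """
    check_dna(sequence, what="apply_rip input")
    rng = np.random.default_rng(params.seed if rng_seed is None else rng_seed)
    current = list(sequence)
    log: list[MutationEvent] = []
    mutated: set[int] = set()

    for _ in range(params.rounds):
        snapshot = "".join(current)
        for i in range(len(snapshot)):
            ctx = rip_context_of(snapshot, i)
            if ctx is None:
                continue
            rate = params.context_rates.get(ctx, 0.0)
            if rng.random() < rate:
                ref = snapshot[i]
                alt = "T" if ref == "C" else "A"
                current[i] = alt
                log.append(MutationEvent(i, ref, alt, ctx))
                mutated.add(i)

    if params.background_rate > 0.0:
        _BACKGROUND_ALTS = {"A": "CGT", "C": "AG", "G": "CT", "T": "ACG"}
        for i, ref in enumerate(sequence):
            if i in mutated:
                continue
            if rng.random() < params.background_rate:
                alts = _BACKGROUND_ALTS[ref]
                alt = alts[rng.integers(len(alts))]
                current[i] = alt
                log.append(MutationEvent(i, ref, alt, "background"))

    log.sort(key=lambda ev: ev.position)
    return "".join(current), log


def replay_log(sequence: str, log: list[MutationEvent]) -> str:
    """Re-apply a mutation log; used to verify log completeness."""
    out = list(sequence)
    for ev in log:
        out[ev.position] = ev.alt_base
    return "".join(out)


def diverge(sequence: str, rate: float, rng_seed: int) -> str:
    """Neutral divergence: uniform random substitutions at ``rate`` per site.

    Used to derive the functional rDNA unit of a related "species" from a
    common ancestral template.
    """
    check_dna(sequence, what="diverge input")
    rng = np.random.default_rng(rng_seed)
    out = list(sequence)
    hit = np.nonzero(rng.random(len(sequence)) < rate)[0]
    for i in hit:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[rng.integers(3)]
    return "".join(out)


def build_synthetic_assembly(
    template: UnitTemplate,
    params: RipParams,
    fragmentation: dict | None = None,
    rng_seed: int | None = None,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Emit contigs carrying functional and RIPped paralogs, plus the truth.

    ``fragmentation`` keys: ``complete_fraction`` (share of paralogs embedded
    full-length, default 0.7) and ``flank_lengths`` (random non-rDNA flank on
    each side of the repeat, default 400 bp). Functional copies are exact
    replicas of the template, matching the within-genome identity of
    functional rDNA repeats; truncated copies keep a random contiguous
    30-70% window of the unit. A random subset of repeats is placed on the
    minus strand.
    """
    frag = {"complete_fraction": 0.7, "flank_lengths": 400}
    if fragmentation:
        frag.update(fragmentation)
    flank = frag["flank_lengths"]
    left_flank, right_flank = (flank, flank) if isinstance(flank, int) else flank

    n = params.n_paralogs
    if n < 2:
        raise ValueError("need at least two paralogs")
    n_pseudo = int(round(params.pseudogene_fraction * n))
    if n_pseudo == n:
        warnings.warn(
            "all paralogs are pseudogenes; downstream classification has no "
            "functional reference",
            stacklevel=2,
        )
    n_complete = int(round(frag["complete_fraction"] * n))

    rng = np.random.default_rng(params.seed if rng_seed is None else rng_seed)
    pseudo_idx = set(rng.choice(n, size=n_pseudo, replace=False).tolist())
    complete_idx = set(rng.choice(n, size=n_complete, replace=False).tolist())

    contigs: list[tuple[str, str]] = []
    rows = []
    sequences: dict[str, str] = {}
    logs: dict[str, list[MutationEvent]] = {}

    for i in range(n):
        pid = f"paralog_{i:02d}"
        unit = template.sequence
        intron_insertions: list[tuple[str, int, int]] = []
        if params.intron_rate > 0.0:
            # insert intron-like sequence into coding genes (18S/28S), offsets
            # applied right-to-left so earlier coordinates stay valid
            bounds = template.boundaries
            for sub in ("28S", "18S"):
                if sub in bounds and rng.random() < params.intron_rate:
                    s, e = bounds[sub]
                    pos = int(rng.integers(s + 20, e - 20))
                    ins = random_dna(params.intron_length, 0.40, rng)
                    unit = unit[:pos] + ins + unit[pos:]
                    intron_insertions.append((sub, pos, params.intron_length))

        is_pseudo = i in pseudo_idx
        if is_pseudo:
            sub_seed = int(rng.integers(2**31))
            unit, log = apply_rip(unit, params, rng_seed=sub_seed)
        else:
            log = []
        logs[pid] = log

        complete = i in complete_idx
        if complete:
            kept, unit_offset = unit, 0
        else:
            frac = rng.uniform(0.3, 0.7)
            keep_len = max(1, int(round(frac * len(unit))))
            unit_offset = int(rng.integers(0, len(unit) - keep_len + 1))
            kept = unit[unit_offset : unit_offset + keep_len]

        strand = "-" if rng.random() < 0.5 else "+"
        lf = random_dna(left_flank, 0.5, rng) if left_flank else ""
        rf = random_dna(right_flank, 0.5, rng) if right_flank else ""
        placed = revcomp(kept) if strand == "-" else kept
        contig_id = f"contig_{i:03d}"
        contigs.append((contig_id, lf + placed + rf))
        start = len(lf)
        rows.append(
            {
                "paralog_id": pid,
                "contig_id": contig_id,
                "start": start,
                "end": start + len(kept),
                "strand": strand,
                "is_pseudogene": is_pseudo,
                "complete": complete,
                "unit_offset": unit_offset,
                "n_introns": len(intron_insertions),
            }
        )
        sequences[pid] = kept

    truth = TruthTable(pd.DataFrame(rows), sequences, logs)
    return contigs, truth


def synthetic_pairing_table(reference: str, n_stems: int = 40, rng_seed: int = 0):
    """Derive a synthetic secondary-structure pairing table from a sequence.

    Scans random centres for short complementary stems (Watson-Crick only)
    and returns non-overlapping 1-based position pairs. This is a synthetic
    stand-in for a curated rRNA structure model, adequate for exercising the
    structure-impact stage on simulated data.
    """
    from .structure import PairingTable

    rng = np.random.default_rng(rng_seed)
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    for _ in range(n_stems * 20):
        if len(pairs) >= n_stems * 4:
            break
        center = int(rng.integers(20, len(reference) - 20))
        loop = int(rng.integers(3, 8))
        s, e = center - loop // 2, center + (loop + 1) // 2
        t = 0
        while s - t >= 0 and e + t < len(reference) and t < 12:
            i, j = s - t, e + t
            if (reference[i], reference[j]) not in wc or i in used or j in used:
                break
            pairs.append((i + 1, j + 1))
            used.update((i, j))
            t += 1
    pairs.sort()
    return PairingTable(pairs=pairs, source="synthetic stem scan")
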