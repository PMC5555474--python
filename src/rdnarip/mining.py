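"""Finding rDNA repeats in assemblies by iterative query expansion.

The search emulates the iterated-BLAST strategy used to exhaustively mine
rDNA paralogs from WGS assemblies: every sequence recovered in one round is
used as a query in the next, until a round contributes no new locus. This
matters because RIP-decayed copies can fall below the identity floor
relative to the functional gene yet remain well above it relative to a
moderately decayed intermediate copy.

The default engine is self-contained: exact k-mer seeding to locate
candidate loci, then local affine-gap refinement of each locus (clipped to
the seeded extents plus a margin) to obtain boundaries and identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .align import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH, pairwise_align
from .seqs import DNA, revcomp
from .synthetic import CODING_SUBUNITS, SUBUNIT_ORDER, UnitTemplate


@dataclass
class RepeatHit:
    """One mined repeat locus, 0-based half-open on the plus strand."""

    contig_id: str
    start: int
    end: int
    strand: str
    identity: float
    matched_subunits: set[str] = field(default_factory=set)
    complete: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SubunitAnnotation:
    present: bool
    coverage: float
    interval: tuple[int, int] | None  # on the extracted plus-strand hit
    sequence: str  # intron-excised, ungapped
    introns_removed: list[tuple[int, int]]  # (position in cleaned seq, length)


@dataclass
class AnnotatedUnit:
    """A strand-normalized repeat with located subunit boundaries."""

    paralog_id: str
    sequence: str
    subunits: dict[str, SubunitAnnotation]

    @property
    def complete(self) -> bool:
        """All six subunits present with near-full coverage of coding genes."""
        if any(n not in self.subunits or not self.subunits[n].present for n in SUBUNIT_ORDER):
            return False
        return all(self.subunits[n].coverage >= 0.95 for n in CODING_SUBUNITS)


_LOCAL_ALIGNER = Align.PairwiseAligner()
_LOCAL_ALIGNER.mode = "local"
_LOCAL_ALIGNER.match_score = MATCH
_LOCAL_ALIGNER.mismatch_score = MISMATCH
_LOCAL_ALIGNER.open_gap_score = GAP_OPEN
_LOCAL_ALIGNER.extend_gap_score = GAP_EXTEND

#: margin added around seed-cluster extents before banded-style refinement
_REFINE_MARGIN = 200


def _refine_locus(query: str, window: str, window_offset: int):
    """Local affine-gap refinement of a candidate locus.

    Returns (start, end, identity) on the window's parent coordinates;
    ambiguous (non-ACGT) columns are excluded from the identity denominator.
    ``None`` when no positive-scoring alignment exists.
    """
    try:
        aln = _LOCAL_ALIGNER.align(window, query)[0]
    except (IndexError, ValueError):
        return None
    blocks = aln.aligned[0]
    if len(blocks) == 0:
        return None
    gq, gw = aln[1], aln[0]
    matches = n_amb = columns = 0
    for cq, cw in zip(gq, gw):
        columns += 1
        if cw not in DNA and cw != "-":
            n_amb += 1
        elif cq == cw:
            matches += 1
    identity = matches / max(1, columns - n_amb)
    return window_offset + int(blocks[0][0]), window_offset + int(blocks[-1][1]), identity


def _seed_clusters(query: str, target: str, k: int) -> list[tuple[int, int, int, int]]:
    """Cluster exact k-mer seed matches into candidate loci.

    Returns (target_start, target_end, query_start, query_end) extents.
    """
    if len(query) < k or len(target) < k:
        return []
    kmer_qpos: dict[str, int] = {}
    for i in range(len(query) - k + 1):
        kmer_qpos.setdefault(query[i : i + k], i)
    matches = [
        (i, kmer_qpos[target[i : i + k]])
        for i in range(len(target) - k + 1)
        if target[i : i + k] in kmer_qpos
    ]
    if not matches:
        return []
    clusters, run = [], [matches[0]]
    for m in matches[1:]:
        if m[0] - run[-1][0] > len(query):
            clusters.append(run)
            run = [m]
        else:
            run.append(m)
    clusters.append(run)
    out = []
    for run in clusters:
        ts = run[0][0]
        te = run[-1][0] + k
        qs = min(q for _, q in run)
        qe = max(q for _, q in run) + k
        out.append((ts, te, qs, qe))
    return out


def _search_query(
    query: str,
    contig_id: str,
    contig_seq: str,
    *,
    min_identity: float,
    min_hit_length: int,
    k: int,
    covered: list[tuple[int, int]] | None = None,
) -> list[RepeatHit]:
    """All acceptable loci of one query on one contig (both strands).

    Candidate loci whose extent is already >50% covered by an interval in
    ``covered`` (plus-strand contig coordinates) are skipped unrefined.
    """
    hits = []
    L = len(contig_seq)
    for strand in "+-":
        target = contig_seq if strand == "+" else revcomp(contig_seq)
        for ts, te, qs, qe in _seed_clusters(query, target, k):
            ps, pe = (ts, te) if strand == "+" else (L - te, L - ts)
            if covered and any(
                min(pe, ce) - max(ps, cs) > 0.5 * (pe - ps) for cs, ce in covered
            ):
                continue
            ws = max(0, ts - _REFINE_MARGIN)
            we = min(len(target), te + _REFINE_MARGIN)
            sub_q = query[max(0, qs - _REFINE_MARGIN) : min(len(query), qe + _REFINE_MARGIN)]
            window = target[ws:we]
            # one seed cluster can span several tandem/adjacent copies; mask
            # each accepted locus and re-refine until nothing acceptable is left
            for _ in range(20):
                refined = _refine_locus(sub_q, window, ws)
                if refined is None:
                    break
                s, e, ident = refined
                if ident < min_identity or e - s < min_hit_length:
                    break
                window = window[: s - ws] + "N" * (e - s) + window[e - ws :]
                ps, pe = (s, e) if strand == "+" else (L - e, L - s)
                hits.append(RepeatHit(contig_id, ps, pe, strand, ident))
    return hits


def _merge_close(hits: list[RepeatHit], gap: int = 100) -> list[RepeatHit]:
    """Union hits within ``gap`` bp on the same contig and strand."""
    out: list[RepeatHit] = []
    for h in sorted(hits, key=lambda h: (h.contig_id, h.strand, h.start, h.end)):
        if (
            out
            and out[-1].contig_id == h.contig_id
            and out[-1].strand == h.strand
            and h.start <= out[-1].end + gap
        ):
            out[-1].end = max(out[-1].end, h.end)
            out[-1].identity = max(out[-1].identity, h.identity)
        else:
            out.append(RepeatHit(h.contig_id, h.start, h.end, h.strand, h.identity))
    return out


def _overlap_fraction(h: RepeatHit, other: RepeatHit) -> float:
    if h.contig_id != other.contig_id:
        return 0.0
    inter = min(h.end, other.end) - max(h.start, other.start)
    return max(0, inter) / max(1, h.length)


def extract_hit_sequence(hit: RepeatHit, contig_seq: str) -> str:
    """Strand-normalized sequence of the hit (repeat orientation)."""
    seq = contig_seq[hit.start : hit.end]
    return revcomp(seq) if hit.strand == "-" else seq


def iterative_search(
    assembly: list[tuple[str, str]],
    seed_query: str,
    params: dict | None = None,
) -> list[RepeatHit]:
    """Query-expansion homology search for all repeat loci in an assembly.

    ``params`` keys (with defaults): ``min_identity`` 0.70, chosen to capture
    copies decayed by ~20-25% RIP with headroom below the ~80% identity floor
    of the RIP substrate requirement; ``min_hit_length`` 200; ``max_rounds``
    10; ``k`` 12 (seed word size).
    """
    p = {"min_identity": 0.70, "min_hit_length": 200, "max_rounds": 10, "k": 12}
    if params:
        p.update(params)
    if len(seed_query) < p["min_hit_length"]:
        raise ValueError(
            f"seed query ({len(seed_query)} bp) shorter than min_hit_length {p['min_hit_length']}"
        )
    if not assembly:
        return []
    contig_seq = {cid: seq.upper() for cid, seq in assembly}

    accepted: list[RepeatHit] = []
    queries = [seed_query.upper()]
    for _ in range(p["max_rounds"]):
        found: list[RepeatHit] = []
        for q in queries:
            for cid, cseq in contig_seq.items():
                covered = [
                    (h.start, h.end) for h in accepted + found if h.contig_id == cid
                ]
                found.extend(
                    _search_query(
                        q,
                        cid,
                        cseq,
                        min_identity=p["min_identity"],
                        min_hit_length=p["min_hit_length"],
                        k=p["k"],
                        covered=covered,
                    )
                )
        found = _merge_close(found)
        new = [
            h
            for h in found
            if not any(_overlap_fraction(h, a) > 0.5 for a in accepted)
        ]
        if not new:
            break
        accepted = _merge_close(accepted + new)
        queries = [extract_hit_sequence(h, contig_seq[h.contig_id]) for h in new]
    return sorted(accepted, key=lambda h: (h.contig_id, h.start))


def excise_introns(
    aligned_query: str,
    aligned_ref: str,
    min_insert: int = 50,
) -> tuple[str, list[tuple[int, int]]]:
    """Remove intron-like insertions from an aligned query.

    Maximal runs of at least ``min_insert`` consecutive reference-gap columns
    are dropped from the query; every other column is preserved in order.
    Reported positions are 0-based offsets into the cleaned, ungapped query.
    """
    if len(aligned_query) != len(aligned_ref):
        raise ValueError("gapped lengths differ")
    keep: list[str] = []
    removed: list[tuple[int, int]] = []
    qpos = 0  # non-gap query characters emitted so far
    i, n = 0, len(aligned_ref)
    while i < n:
        if aligned_ref[i] == "-":
            j = i
            while j < n and aligned_ref[j] == "-":
                j += 1
            run_q = aligned_query[i:j]
            run_len = sum(1 for c in run_q if c != "-")
            if run_len >= min_insert:
                removed.append((qpos, run_len))
            else:
                keep.append(run_q)
                qpos += run_len
            i = j
        else:
            keep.append(aligned_query[i])
            if aligned_query[i] != "-":
                qpos += 1
            i += 1
    return "".join(keep), removed


def annotate_subunits(
    hit_sequence: str,
    reference_unit: UnitTemplate,
    params: dict | None = None,
) -> AnnotatedUnit | None:
    """Locate subunit boundaries on a strand-normalized hit.

    The hit is aligned semi-globally to the full reference unit and each
    subunit's reference interval is projected through the alignment. A
    subunit is *present* when its reference coverage reaches
    ``min_subunit_coverage`` (default 0.9 for coding genes, 0.5 for
    spacers — partial spacers are still informative for RIP profiling).
    Insertion runs of at least ``min_insert`` bp (default 50) inside a
    subunit are excised as introns. Returns ``None`` when no subunit can be
    located.
    """
    p = {"min_subunit_coverage": 0.9, "spacer_coverage": 0.5, "min_insert": 50}
    if params:
        p.update(params)
    gq, gr, _ = pairwise_align(hit_sequence, reference_unit.sequence, free_end_gaps=True)

    # per-column reference position (or -1 on insertion columns)
    ref_pos, hit_pos = [], []
    r = q = 0
    for cr, cq in zip(gr, gq):
        ref_pos.append(r if cr != "-" else -1)
        hit_pos.append(q if cq != "-" else -1)
        if cr != "-":
            r += 1
        if cq != "-":
            q += 1

    subunits: dict[str, SubunitAnnotation] = {}
    any_present = False
    for name, (s, e) in reference_unit.boundaries.items():
        cols = [i for i, rp in enumerate(ref_pos) if s <= rp < e]
        aligned_hit = [hit_pos[i] for i in cols if hit_pos[i] >= 0 and gq[i] != "-"]
        coverage = len(aligned_hit) / (e - s)
        thr = p["min_subunit_coverage"] if name in CODING_SUBUNITS else p["spacer_coverage"]
        if not aligned_hit:
            subunits[name] = SubunitAnnotation(False, 0.0, None, "", [])
            continue
        first, last = cols[0], cols[-1]
        # include insertion columns internal to the subunit span
        sub_q = gq[first : last + 1]
        sub_r = gr[first : last + 1]
        cleaned, removed = excise_introns(sub_q, sub_r, p["min_insert"])
        seq = cleaned.replace("-", "")
        present = coverage >= thr
        any_present = any_present or present
        subunits[name] = SubunitAnnotation(
            present, coverage, (min(aligned_hit), max(aligned_hit) + 1), seq, removed
        )
    if not any_present:
        return None
    return AnnotatedUnit("", hit_sequence, subunits)
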