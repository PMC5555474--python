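"""GC grouping, substitution spectra and pseudogene calling.

The classification logic follows the operational definition of an rDNA
pseudogene in RIP-affected fungi: a paralog whose GC content falls in a
band strictly below (not overlapping) the functional copies, and whose
substitution spectrum relative to the highest-GC reference copy is
dominated by C→T and G→A transitions, with all other substitution classes
at sequencing-noise levels (<0.1% of aligned sites by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .align import pairwise_align  # noqa: F401  (re-exported: module surface)
from .seqs import GAP, encode, gc_fraction

SUBSTITUTION_CLASSES = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)  # 12 directed classes, reference base first


@dataclass
class ParalogRecord:
    paralog_id: str
    subunit: str
    sequence: str
    gc: float
    group: str = "unassigned"  # high_gc | low_gc | unassigned
    call: str = "undetermined"  # functional | pseudogene | undetermined
    complete: bool = True


@dataclass
class MutationSpectrum:
    """Directed substitution counts of a query relative to a reference."""

    counts: dict[str, int]
    indel_columns: int
    aligned_sites: int

    @property
    def rates(self) -> dict[str, float]:
        if self.aligned_sites == 0:
            return {c: 0.0 for c in SUBSTITUTION_CLASSES}
        return {c: n / self.aligned_sites for c, n in self.counts.items()}

    @property
    def total_substitutions(self) -> int:
        return sum(self.counts.values())


def gc_content(sequence: str) -> float:
    """G+C fraction over non-gap, non-ambiguous bases."""
    return gc_fraction(sequence)


def split_gc_groups(
    values: list[tuple[str, float]],
    min_gap: float = 2.0,
) -> tuple[list[tuple[str, float]], list[tuple[str, float]], float]:
    """Split ids into high/low GC groups at the largest gap.

    ``values`` carries GC in percent. If the largest gap between adjacent
    sorted values is below ``min_gap`` percentage points there is no
    bimodality and everything is returned as the high group.
    """
    if len(values) < 2:
        return list(values), [], 0.0
    ordered = sorted(values, key=lambda t: (t[1], t[0]))
    gaps = [ordered[i + 1][1] - ordered[i][1] for i in range(len(ordered) - 1)]
    imax = int(np.argmax(gaps))
    if gaps[imax] < min_gap:
        return list(values), [], max(gaps)
    low = ordered[: imax + 1]
    high = ordered[imax + 1 :]
    return high, low, gaps[imax]


def mutation_spectrum(gapped_query: str, gapped_reference: str) -> MutationSpectrum:
    """Per-column directed substitution counts (reference base → query base).

    Columns gapped in either sequence count as ``indel_columns`` and are
    excluded from ``aligned_sites``; columns with an ambiguity code in
    either sequence are excluded from both numerator and denominator.
    """
    if len(gapped_query) != len(gapped_reference):
        raise ValueError("gapped lengths differ")
    q = encode(gapped_query)
    r = encode(gapped_reference)
    qg = np.frombuffer(gapped_query.encode(), dtype=np.uint8) == ord(GAP)
    rg = np.frombuffer(gapped_reference.encode(), dtype=np.uint8) == ord(GAP)
    indel = qg | rg
    valid = (~indel) & (q != 255) & (r != 255)
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    diff = valid & (q != r)
    for i in np.nonzero(diff)[0]:
        counts[f"{'ACGT'[r[i]]}>{'ACGT'[q[i]]}"] += 1
    return MutationSpectrum(counts, int(indel.sum()), int(valid.sum()))


def transition_rates(spectrum: MutationSpectrum) -> dict[str, float]:
    """G→A, C→T and pooled other-substitution rates per aligned site."""
    n = spectrum.aligned_sites
    if n == 0:
        return {"gA_rate": 0.0, "cT_rate": 0.0, "other_rate": 0.0}
    ga = spectrum.counts["G>A"]
    ct = spectrum.counts["C>T"]
    other = spectrum.total_substitutions - ga - ct
    return {"gA_rate": ga / n, "cT_rate": ct / n, "other_rate": other / n}


def choose_reference(records: list[ParalogRecord]) -> ParalogRecord:
    """Highest-GC complete sequence; ties broken lexicographically by id."""
    pool = [r for r in records if r.complete] or list(records)
    return min(pool, key=lambda r: (-r.gc, r.paralog_id))


def call_pseudogene(
    record: ParalogRecord,
    spectrum: MutationSpectrum,
    thresholds: dict | None = None,
) -> str:
    """Apply the pseudogene decision rule against the highest-GC reference.

    pseudogene ⇔ low-GC group AND non-RIP substitutions consistent with the
    noise ceiling AND at least one G→A/C→T transition. High-GC paralogs are
    functional; low-GC paralogs with excess non-RIP substitutions are
    flagged undetermined for review.

    The noise ceiling (``max_other_rate``, default 0.001 — the error-like
    rate of non-transition changes in sequenced pseudogenes) is tested as a
    one-sided binomial hypothesis rather than compared point-wise: on a
    short subunit the observed other-rate fluctuates around the true noise
    rate, and a point comparison would reject about half of genuine
    pseudogenes whenever noise sits at the ceiling. A paralog is only
    deemed undetermined when its other-substitution count is statistically
    incompatible with the ceiling (``alpha``, default 0.001).
    """
    thr = {"max_other_rate": 0.001, "alpha": 0.001}
    if thresholds:
        thr.update(thresholds)
    if record.group == "unassigned":
        raise ValueError(f"paralog {record.paralog_id} has no GC group assigned")
    rates = transition_rates(spectrum)
    if record.group == "high_gc":
        return "functional"
    other_count = spectrum.total_substitutions - spectrum.counts["G>A"] - spectrum.counts["C>T"]
    p_noise = stats.binom.sf(other_count - 1, spectrum.aligned_sites, thr["max_other_rate"])
    if p_noise >= thr["alpha"] and (rates["gA_rate"] + rates["cT_rate"] > 0):
        return "pseudogene"
    return "undetermined"


def classify_paralogs(
    records: list[ParalogRecord],
    *,
    min_gap: float = 2.0,
    thresholds: dict | None = None,
) -> tuple[list[ParalogRecord], dict[str, MutationSpectrum], str]:
    """Group by GC, build spectra vs the highest-GC reference, call each paralog.

    Convenience driver used by the pipeline: operates on one subunit's
    paralog set. Returns the updated records, per-id spectra, and the
    reference id.
    """
    high, low, _ = split_gc_groups([(r.paralog_id, 100 * r.gc) for r in records], min_gap)
    high_ids = {i for i, _ in high}
    for r in records:
        r.group = "high_gc" if r.paralog_id in high_ids else "low_gc"
    ref = choose_reference([r for r in records if r.group == "high_gc"])
    spectra: dict[str, MutationSpectrum] = {}
    for r in records:
        gq, gr, _ = pairwise_align(r.sequence, ref.sequence, free_end_gaps=not r.complete)
        spec = mutation_spectrum(gq, gr)
        spectra[r.paralog_id] = spec
        r.call = call_pseudogene(r, spec, thresholds)
    return records, spectra, ref.paralog_id


@dataclass
class PrimerWindow:
    """A candidate pseudogene-discriminating primer site."""

    start_column: int  # 0-based alignment column
    sequence: str  # pseudogene consensus over the window, gaps stripped
    min_mismatches: int  # vs the closest functional sequence
    has_3prime_diff: bool
    gc: float
    warnings: list[str] = field(default_factory=list)


def find_discriminating_sites(
    alignment: dict[str, str],
    labels: dict[str, str],
    params: dict | None = None,
) -> list[PrimerWindow]:
    """Find windows where pseudogenes are unanimous and differ from all
    functional copies — the basis for pseudogene-specific primer design.

    Defaults: window 20 columns, at least 2 differences vs every functional
    sequence, and at least one fixed difference within the 3 terminal 3'
    positions (primer specificity lives at the 3' end). Windows whose
    pseudogene consensus has GC < 0.25 carry a low-complexity warning: in
    heavily RIPped targets the discriminating windows become so AT-rich that
    primers may fail.
    """
    p = {"window": 20, "min_diffs": 2, "require_3prime_diff": True}
    if params:
        p.update(params)
    w = p["window"]
    pseudo = [alignment[i] for i in sorted(alignment) if labels[i] == "pseudogene"]
    func = [alignment[i] for i in sorted(alignment) if labels[i] == "functional"]
    if not pseudo or not func:
        raise ValueError("need at least one sequence per label")
    ncol = len(pseudo[0])
    out: list[PrimerWindow] = []
    c = 0
    while c + w <= ncol:
        cols = range(c, c + w)
        ok = all(
            len({s[j] for s in pseudo}) == 1 and pseudo[0][j] != GAP for j in cols
        )
        if not ok:
            c += 1
            continue
        consensus = pseudo[0][c : c + w]
        per_func = []
        fixed_diff_cols = []
        for j in cols:
            if all(f[j] != pseudo[0][j] for f in func):
                fixed_diff_cols.append(j)
        for f in func:
            per_func.append(sum(1 for j in cols if f[j] != pseudo[0][j]))
        min_mm = min(per_func)
        has3 = any(j >= c + w - 3 for j in fixed_diff_cols)
        if min_mm >= p["min_diffs"] and (has3 or not p["require_3prime_diff"]):
            gc = gc_fraction(consensus) if set(consensus) & set("ACGT") else 0.0
            warn = ["low_complexity"] if gc < 0.25 else []
            out.append(PrimerWindow(c, consensus, min_mm, has3, gc, warn))
            c += w
        else:
            c += 1
    return out
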