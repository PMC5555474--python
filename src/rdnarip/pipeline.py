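"""End-to-end orchestration: simulate → mine → classify → RIP → structure →
phylogeny → report.

The pipeline runs either on a synthetic assembly (bundled simulator, known
truth table) or on a user assembly with a supplied reference unit. All stage
outputs are plain TSV/FASTA/Newick files under one output directory, the
configuration is echoed verbatim, and every source of randomness derives
from the single configured seed, so a run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as cls
from . import mining, msa, phylo, ripprofile, structure, synthetic
from .seqs import read_fasta, wrap_fasta

CODING = synthetic.CODING_SUBUNITS


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | assembly
    seed: int = 0
    outdir: str = "rdnarip_out"
    assembly_fasta: str | None = None  # assembly mode
    reference_unit_fasta: str | None = None
    pairing_table: str | None = None  # TSV; synthetic mode derives its own
    # synthetic block
    n_paralogs: int = 10
    pseudogene_fraction: float = 0.8
    context_rates: dict = field(
        default_factory=lambda: dict(synthetic.RipParams().context_rates)
    )
    background_rate: float = 0.001
    complete_fraction: float = 0.7
    flank_lengths: int = 400
    # mining block
    min_identity: float = 0.70
    min_hit_length: int = 200
    max_rounds: int = 10
    # classification block
    min_gc_gap: float = 2.0
    max_other_rate: float = 0.001
    # rip block
    rip_window: int = 50
    # phylo block
    model: str = "k2p"
    n_bootstrap: int = 100
    deletion: str = "auto"  # auto: complete if all complete, else pairwise

    @classmethod
    def from_yaml(cls_, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls_)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls_(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    outdir: Path
    truth: synthetic.TruthTable | None
    hits: list[mining.RepeatHit]
    records: dict[str, list[cls.ParalogRecord]]  # per subunit
    reference_ids: dict[str, str]
    profiles: dict[str, dict[str, ripprofile.RipProfile]]
    trees: dict[str, phylo.Tree]
    purity: dict[str, dict]
    summary: pd.DataFrame
    confusion: dict | None


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    return max(0, inter) / max(1, b[1] - b[0])


def match_hits_to_truth(
    hits: list[mining.RepeatHit], truth: synthetic.TruthTable, min_overlap: float = 0.9
) -> dict[str, str]:
    """Map hit key -> truth paralog_id by interval overlap on the contig."""
    out = {}
    for h in hits:
        for row in truth.records.itertuples():
            if row.contig_id != h.contig_id:
                continue
            if _overlap_fraction((h.start, h.end), (row.start, row.end)) >= min_overlap:
                out[f"{h.contig_id}:{h.start}-{h.end}"] = row.paralog_id
                break
    return out


def mutations_vs_reference(gapped_query: str, gapped_ref: str) -> list[tuple[int, str, str]]:
    """Substitutions as (1-based reference position, ref base, alt base)."""
    out = []
    rpos = 0
    for cq, cr in zip(gapped_query, gapped_ref):
        if cr == "-":
            continue
        rpos += 1
        if cq != "-" and cq in "ACGT" and cr in "ACGT" and cq != cr:
            out.append((rpos, cr, cq))
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    # --- stage: input -----------------------------------------------------
    truth = None
    if config.mode == "synthetic":
        template = synthetic.generate_reference_unit(rng_seed=config.seed)
        params = synthetic.RipParams(
            n_paralogs=config.n_paralogs,
            pseudogene_fraction=config.pseudogene_fraction,
            context_rates=dict(config.context_rates),
            background_rate=config.background_rate,
            seed=config.seed,
        )
        contigs, truth = synthetic.build_synthetic_assembly(
            template,
            params,
            {"complete_fraction": config.complete_fraction, "flank_lengths": config.flank_lengths},
        )
        (outdir / "contigs.fasta").write_text(wrap_fasta(contigs))
        truth.to_tsv(outdir / "truth.tsv")
        (outdir / "reference_unit.fasta").write_text(
            wrap_fasta([("reference_unit", template.sequence)])
        )
    elif config.mode == "assembly":
        if not (config.assembly_fasta and config.reference_unit_fasta):
            raise ValueError("assembly mode needs assembly_fasta and reference_unit_fasta")
        contigs = read_fasta(config.assembly_fasta)
        ref_records = read_fasta(config.reference_unit_fasta)
        template = synthetic.UnitTemplate(
            {name: len(seq) for name, seq in ref_records},
            {name: cls.gc_content(seq) for name, seq in ref_records},
            "".join(seq for _, seq in ref_records),
        )
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # --- stage: mining ----------------------------------------------------
    hits = mining.iterative_search(
        contigs,
        template.sequence,
        {
            "min_identity": config.min_identity,
            "min_hit_length": config.min_hit_length,
            "max_rounds": config.max_rounds,
        },
    )
    contig_seq = dict(contigs)
    units: dict[str, mining.AnnotatedUnit] = {}
    for h in hits:
        seq = mining.extract_hit_sequence(h, contig_seq[h.contig_id])
        unit = mining.annotate_subunits(seq, template)
        if unit is None:
            continue
        unit.paralog_id = f"{h.contig_id}:{h.start}-{h.end}"
        h.matched_subunits = {n for n, s in unit.subunits.items() if s.present}
        h.complete = unit.complete
        units[unit.paralog_id] = unit
    pd.DataFrame(
        [
            {
                "contig": h.contig_id,
                "start": h.start + 1,
                "end": h.end,
                "strand": h.strand,
                "identity": round(h.identity, 4),
                "complete": h.complete,
            }
            for h in hits
        ]
    ).to_csv(outdir / "hits.tsv", sep="\t", index=False)

    # --- stage: classification + RIP + structure + phylo, per subunit -----
    records: dict[str, list[cls.ParalogRecord]] = {}
    reference_ids: dict[str, str] = {}
    profiles: dict[str, dict[str, ripprofile.RipProfile]] = {}
    trees: dict[str, phylo.Tree] = {}
    purity: dict[str, dict] = {}
    summary_rows = []
    class_rows = []

    for subunit in CODING:
        recs = []
        for pid in sorted(units):
            ann = units[pid].subunits.get(subunit)
            if ann is None or not ann.present or not ann.sequence:
                continue
            recs.append(
                cls.ParalogRecord(
                    paralog_id=pid,
                    subunit=subunit,
                    sequence=ann.sequence,
                    gc=cls.gc_content(ann.sequence),
                    complete=ann.coverage >= 0.95,
                )
            )
        if len(recs) < 2:
            continue
        recs, spectra, ref_id = cls.classify_paralogs(
            recs,
            min_gap=config.min_gc_gap,
            thresholds={"max_other_rate": config.max_other_rate},
        )
        records[subunit] = recs
        reference_ids[subunit] = ref_id

        # multiple alignment anchored on the highest-GC reference
        seqs = {r.paralog_id: r.sequence for r in recs}
        aln = msa.reference_anchored_msa(seqs, ref_id)

        prof = {
            pid: ripprofile.compute_rip_profile(aln[pid], aln[ref_id])
            for pid in aln
            if pid != ref_id
        }
        profiles[subunit] = prof
        track = ripprofile.windowed_rip(aln, ref_id, config.rip_window, config.rip_window)
        track.to_csv(outdir / f"rip_track_{subunit}.tsv", sep="\t", index=False)

        # structure impact against the reference subunit
        ref_seq = seqs[ref_id]
        if config.pairing_table:
            table = structure.read_pairing_tsv(config.pairing_table)
        else:
            table = synthetic.synthetic_pairing_table(ref_seq, rng_seed=config.seed)
        impact_rows = []
        for r in recs:
            if r.paralog_id == ref_id:
                continue
            muts = mutations_vs_reference(aln[r.paralog_id], aln[ref_id])
            muts = [m for m in muts if m[0] <= len(ref_seq)]
            imp = structure.map_mutations_to_structure(muts, table, ref_seq)
            impact_rows.append(
                {
                    "paralog_id": r.paralog_id,
                    "n_paired_mut": imp.n_paired_mut,
                    "n_unpaired_mut": imp.n_unpaired_mut,
                    "n_disrupting": imp.n_disrupting,
                }
            )
        pd.DataFrame(impact_rows).to_csv(
            outdir / f"structure_impact_{subunit}.tsv", sep="\t", index=False
        )

        # phylogeny over classified (non-undetermined) paralogs
        phylo_ids = [r.paralog_id for r in recs if r.call in ("functional", "pseudogene")]
        tr = None
        if len(phylo_ids) >= 3:
            sub_aln = {pid: aln[pid] for pid in phylo_ids}
            deletion = config.deletion
            if deletion == "auto":
                all_complete = all(r.complete for r in recs if r.paralog_id in phylo_ids)
                deletion = "complete" if all_complete else "pairwise"
            tr = phylo.bootstrap_support(
                sub_aln,
                model=config.model,
                n_replicates=config.n_bootstrap,
                rng_seed=config.seed + 1,
                deletion=deletion,
            )
            trees[subunit] = tr
            (outdir / f"tree_{subunit}.nwk").write_text(tr.newick() + "\n")
            labels = {
                r.paralog_id: r.call for r in recs if r.paralog_id in set(phylo_ids)
            }
            purity[subunit] = phylo.clade_purity(tr, labels)

        for r in recs:
            rates = cls.transition_rates(spectra[r.paralog_id])
            class_rows.append(
                {
                    "paralog_id": r.paralog_id,
                    "subunit": subunit,
                    "gc": round(r.gc, 4),
                    "group": r.group,
                    **{k: round(v, 6) for k, v in rates.items()},
                    "rip_rate": round(
                        prof[r.paralog_id].rip_rate if r.paralog_id in prof else 0.0, 6
                    ),
                    "call": r.call,
                }
            )

        low = [r for r in recs if r.group == "low_gc"]
        rates_low = [cls.transition_rates(spectra[r.paralog_id]) for r in low]
        aln_all = {r.paralog_id: aln[r.paralog_id] for r in recs}
        summary_rows.append(
            {
                "subunit": subunit,
                "n_paralogs": len(recs),
                "n_pseudogene_calls": sum(r.call == "pseudogene" for r in recs),
                "avg_p_distance": round(phylo.average_p_distance(aln_all), 6),
                "gA_rate": round(
                    float(pd.Series([x["gA_rate"] for x in rates_low]).mean()) if low else 0.0, 6
                ),
                "cT_rate": round(
                    float(pd.Series([x["cT_rate"] for x in rates_low]).mean()) if low else 0.0, 6
                ),
                "rip_rate": round(
                    float(pd.Series([prof[r.paralog_id].rip_rate for r in low]).mean())
                    if low
                    else 0.0,
                    6,
                ),
            }
        )

    pd.DataFrame(class_rows).to_csv(outdir / "classification.tsv", sep="\t", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    # --- stage: truth comparison (synthetic mode) -------------------------
    confusion = None
    if truth is not None:
        hit_to_truth = match_hits_to_truth(hits, truth)
        truth_flag = dict(zip(truth.records.paralog_id, truth.records.is_pseudogene))
        tp = fp = tn = fn = 0
        for subunit, recs in records.items():
            for r in recs:
                tid = hit_to_truth.get(r.paralog_id)
                if tid is None or r.call == "undetermined":
                    continue
                actual = truth_flag[tid]
                called = r.call == "pseudogene"
                tp += called and actual
                fp += called and not actual
                tn += (not called) and (not actual)
                fn += (not called) and actual
        confusion = {
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "n_truth_repeats": int(len(truth.records)),
            "n_hits": len(hits),
        }
        (outdir / "confusion.json").write_text(json.dumps(confusion, indent=2) + "\n")

    return PipelineResult(
        outdir=outdir,
        truth=truth,
        hits=hits,
        records=records,
        reference_ids=reference_ids,
        profiles=profiles,
        trees=trees,
        purity=purity,
        summary=summary,
        confusion=confusion,
    )


def summarize_prealigned(
    alignments: dict[str, dict[str, str]],
    species: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Table-1-style summary from existing alignments (mining skipped).

    ``alignments`` maps subunit name → {sequence id → gapped sequence}.
    ``species`` optionally maps sequence id → species; when given, average
    p-distance and G→A / C→T rates are computed per species (against that
    species' highest-GC sequence) and then averaged across species,
    otherwise the whole alignment is treated as one set.
    """
    rows = []
    for subunit, aln in alignments.items():
        groups: dict[str, list[str]] = {}
        for sid in aln:
            sp = species.get(sid, "all") if species else "all"
            groups.setdefault(sp, []).append(sid)
        per_species = []
        for sp, ids in sorted(groups.items()):
            if len(ids) < 2:
                continue
            sub = {i: aln[i] for i in ids}
            ref = min(ids, key=lambda i: (-cls.gc_content(aln[i].replace("-", "")), i))
            ga, ct, rip = [], [], []
            for i in ids:
                if i == ref:
                    continue
                spec = cls.mutation_spectrum(sub[i], sub[ref])
                rates = cls.transition_rates(spec)
                prof = ripprofile.compute_rip_profile(sub[i], sub[ref])
                ga.append(rates["gA_rate"])
                ct.append(rates["cT_rate"])
                rip.append(prof.rip_rate)
            per_species.append(
                {
                    "species": sp,
                    "n": len(ids),
                    "avg_p_distance": phylo.average_p_distance(sub),
                    "gA_rate": float(pd.Series(ga).mean()),
                    "cT_rate": float(pd.Series(ct).mean()),
                    "rip_rate": float(pd.Series(rip).mean()),
                }
            )
        for r in per_species:
            rows.append({"subunit": subunit, **r})
        if per_species:
            df = pd.DataFrame(per_species)
            rows.append(
                {
                    "subunit": subunit,
                    "species": "average",
                    "n": int(df["n"].sum()),
                    "avg_p_distance": float(df["avg_p_distance"].mean()),
                    "gA_rate": float(df["gA_rate"].mean()),
                    "cT_rate": float(df["cT_rate"].mean()),
                    "rip_rate": float(df["rip_rate"].mean()),
                }
            )
    return pd.DataFrame(rows)
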