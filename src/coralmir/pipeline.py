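"""End-to-end orchestration: simulate -> qc -> discover -> conserve ->
targets -> enrich, with a machine-readable manifest.

Each stage writes its outputs under the run directory and appends a manifest
row (stage, file, sha256, row count); identical configuration + seed gives
identical checksums.  The log records the read funnel (raw -> kept ->
mapped -> stacks -> candidates -> bona fide), which never increases stage to
stage.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conserve as _conserve
from .discover import (
    Alignment,
    ClassifyThresholds,
    GenomeIndex,
    BonaFideVerdict,
    HairpinMetrics,
    PrecursorCandidate,
    call_stacks,
    classify,
    duplex_metrics,
    excise_precursors,
    map_reads,
    score_candidate,
)
from .enrich import AnnotationSet, enrich, propagate
from .errors import ConfigError, DegenerateCandidateError
from .fold import fold_hairpin
from .formats import SeqRecord, SmallRead, read_fasta, to_rna_lower, write_records
from .qc import QCParams, run_qc
from .simulate import (
    SimConfig,
    TruthTable,
    make_contaminants,
    make_known_reference,
    simulate_genome,
    simulate_ontology,
    simulate_reads,
    simulate_transcripts,
    write_annotations,
    write_obo,
)
from .targets import UTR3, extract_utr3, longest_orf, predict_targets

logger = logging.getLogger("coralmir")

__all__ = ["PipelineConfig", "DiscoveryOutput", "run_discovery", "run_all"]


@dataclass
class PipelineConfig:
    """All stage parameters, anchored to the study's published defaults."""

    seed: int = 42
    outdir: str = "run"
    prefix: str = "spi"
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCParams = field(default_factory=QCParams)
    thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    map_min_len: int = 18
    max_loci: int = 5
    stack_min_count: int = 10
    stack_merge_gap: int = 2
    excise_flank: int = 70
    cons_max_mismatch: int = 3
    cons_max_offset: int = 3
    ddg_cutoff: float = -10.0
    utr_min_len: int = 100
    alpha: float = 0.01

    def __post_init__(self) -> None:
        self.sim = replace_seed(self.sim, self.seed)
        if not self.qc.adapter3:
            self.qc.adapter3 = self.sim.adapter3
        # the 5' adapter sits upstream of the sequencing primer and is never
        # read, so the pipeline trims only the 3' adapter by default; 5'
        # trimming stays available through QCParams for libraries that need it

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        qcp = QCParams(**raw.pop("qc", {}))
        th = ClassifyThresholds(**raw.pop("thresholds", {}))
        try:
            return cls(sim=sim, qc=qcp, thresholds=th, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def replace_seed(sim: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace

    return replace(sim, seed=seed)


@dataclass
class DiscoveryOutput:
    alignments: list[Alignment]
    stacks: list
    entries: list[tuple[PrecursorCandidate, HairpinMetrics]]
    verdicts: dict[str, BonaFideVerdict]
    hits: dict[str, list]
    passers: list[tuple[PrecursorCandidate, HairpinMetrics, BonaFideVerdict]]
    names: dict[str, str]
    degenerate: list[str] = field(default_factory=list)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for cand, m in self.entries:
            v = self.verdicts[cand.id]
            rows.append({
                "candidate": cand.id, "contig": cand.contig,
                "strand": cand.strand, "mature_seq": cand.mature_seq,
                "overhang3": m.overhang3,
                "five_prime_consistency": round(m.five_prime_consistency, 4),
                "stem_mismatches": m.stem_mismatches,
                "mature_count": m.mature_count, "star_count": m.star_count,
                "loop_count": m.loop_count,
                "mature_paired_fraction": round(m.mature_paired_fraction, 4),
                "score": round(v.score, 3), "passed": v.passed,
                "rescued": v.rescued_by_conservation,
                "failed": ";".join(v.failed),
                "name": self.names.get(cand.id, ""),
            })
        return pd.DataFrame(rows)


def run_discovery(reads: list[SmallRead], genome: list[SeqRecord],
                  known: list[SeqRecord], config: PipelineConfig
                  ) -> DiscoveryOutput:
    """Map reads, call stacks, excise/fold candidates, compute metrics,
    gather conservation hits, classify, deduplicate overlapping candidates
    and name the passing set."""
    index = GenomeIndex(genome)
    alns = map_reads(reads, index, config.map_min_len, config.max_loci)
    stacks = call_stacks(alns, index, config.stack_min_count,
                         config.stack_merge_gap)

    local_reads: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for a in alns:
        L = len(index.contigs[a.contig])
        p = a.start if a.strand == "+" else L - a.end
        local_reads.setdefault((a.contig, a.strand), []).append((p, a.length))

    entries: list[tuple[PrecursorCandidate, HairpinMetrics]] = []
    degenerate: list[str] = []
    for stack in stacks:
        for cand in excise_precursors(stack, index, config.excise_flank):
            try:
                fr = fold_hairpin(cand.seq)
            except ConfigError:
                continue
            cand.fold = fr
            window = [
                (p, ln) for p, ln in local_reads[(cand.contig, cand.strand)]
                if p + ln > cand.local_start and p < cand.local_end
            ]
            try:
                m = duplex_metrics(cand, fr, window)
            except DegenerateCandidateError:
                degenerate.append(cand.id)
                continue
            entries.append((cand, m))

    hits = {
        cand.id: _conserve.match_known(cand.id, cand.mature_seq, known,
                                       config.cons_max_mismatch,
                                       config.cons_max_offset)
        for cand, _ in entries
    }
    verdict_list = classify(entries, {c: len(h) for c, h in hits.items()},
                            config.thresholds)
    verdicts = {v.candidate_id: v for v in verdict_list}

    # deduplicate passing candidates whose windows overlap on the genome
    # (a hairpin is typically hit by a mature- and a star-anchored stack)
    passers_all = [(c, m, verdicts[c.id]) for c, m in entries
                   if verdicts[c.id].passed]
    clusters: list[list] = []
    for item in sorted(passers_all,
                       key=lambda t: (t[0].contig, t[0].strand,
                                      t[0].genomic_span(len(index.contigs[t[0].contig]))[0])):
        cand = item[0]
        span = cand.genomic_span(len(index.contigs[cand.contig]))
        placed = False
        for cl in clusters:
            prev = cl[-1][0]
            pspan = prev.genomic_span(len(index.contigs[prev.contig]))
            if (prev.contig == cand.contig
                    and min(span[1], pspan[1]) > max(span[0], pspan[0])):
                cl.append(item)
                placed = True
                break
        if not placed:
            clusters.append([item])
    passers = [max(cl, key=lambda t: (t[2].score, t[0].id)) for cl in clusters]

    names = _conserve.assign_names(
        [(c.id, v.score) for c, _, v in passers],
        {c.id: hits[c.id] for c, _, _ in passers},
        prefix=config.prefix,
    )
    return DiscoveryOutput(alns, stacks, entries, verdicts, hits, passers,
                           names, degenerate)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _rows(path: Path) -> int:
    return sum(1 for _ in open(path))


def run_all(config: PipelineConfig) -> pd.DataFrame:
    """Execute every stage on a synthetic dataset; return the manifest."""
    out = Path(config.outdir)
    for sub in ("data", "qc", "mirna", "targets", "go"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    manifest_rows: list[dict] = []

    def register(stage: str, path: Path) -> None:
        manifest_rows.append({
            "stage": stage, "file": str(path.relative_to(out)),
            "sha256": _sha256(path), "rows": _rows(path),
        })

    try:
        logger.info("config: seed=%d ddg_cutoff=%.1f alpha=%.3f max_loci=%d "
                    "min_score=%.1f", config.seed, config.ddg_cutoff,
                    config.alpha, config.max_loci, config.thresholds.min_score)

        # -- simulate ----------------------------------------------------
        genome, truth = simulate_genome(config.sim)
        reads, truth = simulate_reads(genome, truth, config.sim)
        known = make_known_reference(truth, config.sim)
        contaminants = make_contaminants(config.sim)
        matures = [SeqRecord(h.mature_id, h.mature_seq) for h in truth.hairpins]
        transcripts, site_truth = simulate_transcripts(matures, config.sim)

        write_records(genome, out / "data/genome.fa")
        write_records(reads, out / "data/reads.fastq", "fastq")
        write_records(known, out / "data/known_mirnas.fa")
        write_records(contaminants, out / "data/contaminants.fa")
        write_records(transcripts, out / "data/transcripts.fa")
        truth.hairpin_frame().to_csv(out / "data/truth_hairpins.tsv", sep="\t", index=False)
        site_truth.site_frame().to_csv(out / "data/truth_sites.tsv", sep="\t", index=False)
        truth.origin_frame().to_csv(out / "data/truth_reads.tsv", sep="\t", index=False)
        for f in ("genome.fa", "reads.fastq", "known_mirnas.fa",
                  "contaminants.fa", "transcripts.fa", "truth_hairpins.tsv",
                  "truth_sites.tsv", "truth_reads.tsv"):
            register("simulate", out / "data" / f)
        logger.info("simulate: %d contigs, %d reads, %d transcripts",
                    len(genome), len(reads), len(transcripts))

        # -- qc ----------------------------------------------------------
        clean, report = run_qc(reads, config.qc, contaminants)
        write_records(clean, out / "qc/clean.fastq", "fastq")
        report.as_frame().to_csv(out / "qc/qc_report.tsv", sep="\t", index=False)
        report.composition.to_csv(out / "qc/composition.tsv", sep="\t", index=False)
        for f in ("clean.fastq", "qc_report.tsv", "composition.tsv"):
            register("qc", out / "qc" / f)
        logger.info("qc funnel: %s (emptied by trim: %d)",
                    report.counts, report.n_emptied_by_trim)

        # -- discover + conserve ----------------------------------------
        disc = run_discovery(clean, genome, known, config)
        disc.metrics_frame().to_csv(out / "mirna/verdicts.tsv", sep="\t", index=False)
        # mature sequences printed in the lower-case RNA dialect
        with open(out / "mirna/mature.fa", "w") as mf:
            for c, _, _ in disc.passers:
                mf.write(f">{disc.names[c.id]}\n{to_rna_lower(c.mature_seq)}\n")
        with open(out / "mirna/precursors.gff3", "w") as gf:
            gf.write("##gff-version 3\n")
            index = GenomeIndex(genome)
            for c, _, v in disc.passers:
                s, e = c.genomic_span(len(index.contigs[c.contig]))
                gf.write(f"{c.contig}\tcoralmir\tpre_miRNA\t{s + 1}\t{e}\t"
                         f"{v.score:.2f}\t{c.strand}\t.\t"
                         f"ID={disc.names[c.id]}\n")
        for f in ("verdicts.tsv", "mature.fa", "precursors.gff3"):
            register("discover", out / "mirna" / f)
        hit_rows = [
            {"query": h.query_id, "subject": h.subject_id, "offset": h.offset,
             "overlap": h.overlap, "mismatches": h.mismatches, "family": h.family}
            for hs in disc.hits.values() for h in hs
        ]
        pd.DataFrame(hit_rows, columns=["query", "subject", "offset", "overlap",
                                        "mismatches", "family"]
                     ).to_csv(out / "mirna/conservation_hits.tsv", sep="\t", index=False)
        register("conserve", out / "mirna/conservation_hits.tsv")
        n_pass = len(disc.passers)
        logger.info("discover funnel: mapped=%d stacks=%d candidates=%d bona_fide=%d",
                    len(disc.alignments), len(disc.stacks), len(disc.entries), n_pass)

        # -- targets -----------------------------------------------------
        utrs: list[UTR3] = []
        for t in transcripts:
            u = extract_utr3(t, longest_orf(t), config.utr_min_len)
            if u is not None:
                utrs.append(u)
        mature_for_targets = [SeqRecord(disc.names[c.id], c.mature_seq)
                              for c, _, _ in disc.passers]
        sites = predict_targets(mature_for_targets, utrs, config.ddg_cutoff)
        pd.DataFrame([
            {"mirna": s.mirna_id, "transcript": s.transcript_id,
             "utr_start": s.utr_start, "utr_end": s.utr_end,
             "seed_class": f"{s.seed_len}mer",
             "dg_duplex": round(s.dg_duplex, 2),
             "open_cost": round(s.open_cost, 2), "ddg": round(s.ddg, 2),
             "retained": True}
            for s in sites
        ], columns=["mirna", "transcript", "utr_start", "utr_end", "seed_class",
                    "dg_duplex", "open_cost", "ddg", "retained"]
        ).to_csv(out / "targets/targets.tsv", sep="\t", index=False)
        register("targets", out / "targets/targets.tsv")
        logger.info("targets: %d UTRs >= %d bp, %d retained sites",
                    len(utrs), config.utr_min_len, len(sites))

        # -- enrichment --------------------------------------------------
        # transcripts are embedded in a larger annotated gene universe, as in
        # a real transcriptome where targeted genes are a small subset
        tx_ids = [t.id for t in transcripts]
        filler = [f"g{i:04d}" for i in
                  range(max(0, config.sim.n_background_genes - len(tx_ids)))]
        strong_tx = sorted({s.transcript_id for s in site_truth.sites
                            if s.klass == "strong"})
        dag, annotations, _, enriched_term = simulate_ontology(
            config.sim, genes=tx_ids + filler, study_genes=strong_tx)
        write_obo(dag, out / "go/go.obo")
        write_annotations(annotations, out / "go/annotations.tsv")
        closed = propagate(AnnotationSet({g: frozenset(t) for g, t in
                                          annotations.items()}), dag)
        study = {s.transcript_id for s in sites} & set(tx_ids)
        results = enrich(study or set(strong_tx), set(tx_ids) | set(filler),
                         closed, dag, alpha=config.alpha)
        pd.DataFrame([
            {"term": r.term, "name": r.name, "k": r.k, "n": r.n, "K": r.K,
             "N": r.N, "p_classic": r.p_classic, "p_elim": r.p_elim,
             "significant": r.significant}
            for r in results
        ]).to_csv(out / "go/enrichment.tsv", sep="\t", index=False)
        for f in ("go.obo", "annotations.tsv", "enrichment.tsv"):
            register("enrich", out / "go" / f)
        planted = next(r for r in results if r.term == enriched_term)
        logger.info("enrich: planted term %s p_elim=%.3g significant=%s",
                    enriched_term, planted.p_elim, planted.significant)

        manifest = pd.DataFrame(manifest_rows)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        return manifest
    finally:
        logger.removeHandler(fh)
        fh.close()
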