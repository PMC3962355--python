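#!/usr/bin/env python
"""Generate the synthetic study dataset with planted truth.

Writes a genome with 20 planted pre-miRNA hairpins (one carrying a 3-nt
overhang plus two known-miRNA matches, to exercise the conservation-rescue
path), the small-RNA library, transcripts with planted strong/weak target
sites, the mock contaminant set, the synthetic known-miRNA reference, and a
GO ontology whose one enriched term is planted on the strong-site
transcripts.  All downstream analysis steps read these files.
"""

import argparse
from collections import Counter
from pathlib import Path

from coralmir.formats import SeqRecord, write_records
from coralmir.pipeline import PipelineConfig
from coralmir.simulate import (
    make_contaminants,
    make_known_reference,
    simulate_genome,
    simulate_ontology,
    simulate_reads,
    simulate_transcripts,
    write_annotations,
    write_obo,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.outdir / "data"
    out.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(seed=args.seed)
    sim = cfg.sim
    genome, truth = simulate_genome(sim)
    reads, truth = simulate_reads(genome, truth, sim)
    known = make_known_reference(truth, sim)
    matures = [SeqRecord(h.mature_id, h.mature_seq) for h in truth.hairpins]
    transcripts, site_truth = simulate_transcripts(matures, sim)
    strong_tx = sorted({s.transcript_id for s in site_truth.sites
                        if s.klass == "strong"})
    # transcripts sit inside a larger annotated gene universe, as in a real
    # transcriptome where targeted genes are a small subset
    tx_ids = [t.id for t in transcripts]
    filler = [f"g{i:04d}" for i in
              range(max(0, sim.n_background_genes - len(tx_ids)))]
    dag, ann, _, term = simulate_ontology(sim, genes=tx_ids + filler,
                                          study_genes=strong_tx)

    write_records(genome, out / "genome.fa")
    write_records(reads, out / "reads.fastq", "fastq")
    write_records(known, out / "known_mirnas.fa")
    write_records(make_contaminants(sim), out / "contaminants.fa")
    write_records(transcripts, out / "transcripts.fa")
    write_obo(dag, out / "go.obo")
    write_annotations(ann, out / "annotations.tsv")
    truth.hairpin_frame().to_csv(out / "truth_hairpins.tsv", sep="\t", index=False)
    site_truth.site_frame().to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    truth.origin_frame().to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    (out / "truth_enriched_term.txt").write_text(term + "\n")

    origins = Counter(truth.read_origin.values())
    print(f"simulated {len(genome)} contigs, {len(reads)} reads, "
          f"{len(transcripts)} transcripts (seed {args.seed})")
    print(f"read origins: {dict(origins)}")
    print(f"planted: {len(truth.hairpins)} hairpins "
          f"({sum(h.overhang != sim.overhang for h in truth.hairpins)} with a "
          f"non-canonical overhang), {len(site_truth.sites)} target sites, "
          f"enriched GO term {term}")


if __name__ == "__main__":
    main()
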