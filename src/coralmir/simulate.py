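"""Synthetic genomes, reads, transcripts and ontologies with planted truth.

Every downstream stage of the pipeline is exercised against data generated
here, with a truth table recording what was planted, so recovery can be
measured without any external download.  The generator emulates the
hallmarks of a real small-RNA library:

* pre-miRNA hairpins (mature + loop + near-reverse-complement star) embedded
  in random flanks, on both strands, with designed Dicer-style 2-nt 3'
  duplex overhangs (one optional hairpin carries a 3-nt overhang and matches
  the known-miRNA reference, exercising the conservation-rescue path);
* read stacks concentrated on the mature and star arms with dominant 5'
  ends, 3' adapter read-through, and Phred-profile sequencing errors;
* a piRNA-like 26-31 nt fraction with a 5'-uridine bias;
* rRNA/tRNA-like contaminant fragments drawn from a mock contaminant FASTA;
* transcripts with a designed longest ORF and a >= 150 nt 3' UTR carrying
  planted high-accessibility (strong) and stem-occluded (weak) target sites;
* a small GO DAG with one truly enriched term.

Planted constructions are verified at generation time with the package's own
folder and energy functions (the stated post-conditions: planted windows
re-fold to the designed duplex geometry, strong sites score at or below the
strong ddG bound, weak sites at or above the weak bound); a draw that
violates its post-condition is redrawn.  All randomness flows from
``SimConfig.seed`` through per-stage streams, so identical configurations
give byte-identical outputs and stages can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .discover import PrecursorCandidate, _duplex_run
from .errors import ConfigError
from .fold import fold
from .formats import OntologyDAG, SeqRecord, SmallRead, revcomp
from .targets import EnergyModel, UTR3, duplex_dG, extract_utr3, longest_orf, open_cost

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_genome",
    "simulate_reads",
    "simulate_transcripts",
    "simulate_ontology",
    "simulate_decoys",
    "make_contaminants",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset (defaults = the conditions
    the pipeline's acceptance checks run under)."""

    seed: int = 42
    # genome / hairpins
    n_hairpins: int = 20
    mature_len: int = 22
    loop_len: int = 15
    flank_len: int = 200
    overhang: int = 2
    rescue_hairpins: int = 1      # planted with a 3-nt overhang + known match
    rescue_overhang: int = 3
    n_conserved: int = 5          # hairpins mirrored in the known reference
    n_weak_matures: int = 5       # hairpins whose seeds suit weak target sites
    # reads
    reads_per_hairpin_median: float = 200.0
    reads_per_hairpin_sigma: float = 0.4
    five_prime_purity: float = 0.9
    mature_frac: float = 0.72     # of a hairpin's reads; star/loop take the rest
    star_frac: float = 0.25
    noise_read_fraction: float = 0.2
    pirna_fraction: float = 0.15
    contaminant_read_fraction: float = 0.05
    pirna_u_prob: float = 0.9
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    read_len: int = 36
    phred_peak: int = 38          # 5'-end Phred; decays quadratically
    phred_tail: int = 18          # 3'-end Phred
    # transcripts / target sites
    n_transcripts: int = 120
    n_strong_sites: int = 25
    n_weak_sites: int = 25
    leader_len: int = 30
    orf_codons: int = 60
    utr_context: int = 75         # low-structure context on each side of a site
    planted_site_ddG_strong: float = -12.0
    planted_site_ddG_weak: float = -5.0
    # ontology
    n_go_terms: int = 40
    n_background_genes: int = 1000
    study_size: int = 50
    go_base_rate: float = 0.06
    enriched_term_effect: float = 5.0

    def __post_init__(self) -> None:
        for name in ("five_prime_purity", "noise_read_fraction", "pirna_fraction",
                     "contaminant_read_fraction", "pirna_u_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.mature_len < 18:
            raise ConfigError("mature_len must be >= 18")
        if self.loop_len < 3:
            raise ConfigError("loop_len must be >= 3 (minimum hairpin loop)")

    def rng(self, tag: str) -> np.random.Generator:
        """Independent stream per stage, derived from the master seed."""
        return np.random.default_rng(
            [int(self.seed) & 0x7FFFFFFF, zlib.crc32(tag.encode()) & 0x7FFFFFFF]
        )


@dataclass
class PlantedHairpin:
    index: int
    contig: str
    strand: str
    local_start: int        # hairpin start, strand-local coordinates
    genomic_start: int      # forward-genome window of the full hairpin
    genomic_end: int
    mature_seq: str
    star_seq: str
    loop_seq: str
    overhang: int
    conserved_ids: list[str] = field(default_factory=list)

    @property
    def mature_id(self) -> str:
        return f"mat-{self.index:02d}"


@dataclass
class PlantedSite:
    transcript_id: str
    mirna_id: str
    utr_start: int
    utr_end: int
    klass: str              # "strong" | "weak"
    designed_ddg: float


@dataclass
class TruthTable:
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)
    enriched_term: str | None = None
    read_origin: dict[str, str] = field(default_factory=dict)

    def hairpin_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"index": h.index, "contig": h.contig, "strand": h.strand,
             "genomic_start": h.genomic_start, "genomic_end": h.genomic_end,
             "mature_seq": h.mature_seq, "star_seq": h.star_seq,
             "overhang": h.overhang,
             "conserved_ids": ";".join(h.conserved_ids)}
            for h in self.hairpins
        ])

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"transcript_id": s.transcript_id, "mirna_id": s.mirna_id,
             "utr_start": s.utr_start, "utr_end": s.utr_end,
             "class": s.klass, "designed_ddg": s.designed_ddg}
            for s in self.sites
        ])

    def origin_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.read_origin.items()), columns=["read_id", "origin"]
        )


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _comp(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[b]


def _build_arms(rng: np.random.Generator, cfg: SimConfig, overhang: int,
                weak_seed: bool) -> tuple[str, str, str]:
    """Draw mature / loop / star with the designed duplex geometry.

    The mature tail (last 3 nt), the loop and the star's dangling 3' bases
    are drawn from {A, C} so that no base outside the designed helix can pair
    with the helix ends -- the folded window then shows exactly the designed
    3' overhangs.  Weak-seed matures additionally restrict positions 2-8 to
    {A, C}, which makes the stem-occluded target sites provably weak under
    the pair-energy model.
    """
    mlen = cfg.mature_len
    paired = mlen - overhang
    mature = list(_rand_seq(rng, mlen))
    # overhang bases from {A,C}: they cannot pair the poly-A loop, so the
    # designed 3' overhang survives folding
    for i in range(paired, mlen):
        mature[i] = rng.choice(["A", "C"])
    # loop-proximal helix pairs are G:C (weight 3): any competing structure
    # that opens the helix top to pair into the loop loses more than it gains
    for i in range(paired - 4, paired):
        mature[i] = rng.choice(["G", "C"])
    if weak_seed:
        for i in range(1, 8):
            mature[i] = rng.choice(["A", "C"])
    elif all(b in "GT" for b in mature[1:8]):
        # a pure-G/T seed would seed-match any {A,C} context; keep seeds mixed
        mature[4] = rng.choice(["A", "C"])
    mature = "".join(mature)
    loop = "A" * cfg.loop_len
    star = [""] * mlen
    for j in range(paired):
        star[j] = _comp(mature[paired - 1 - j])
    for j in range(paired, mlen):
        star[j] = rng.choice(["A", "C"])
    return mature, loop, "".join(star)


def _verify_hairpin_window(window: str, mlen: int, loop_len: int, overhang: int) -> bool:
    """Re-fold the planted window and check the designed duplex geometry."""
    fr = fold(window)
    duplex = _duplex_run(fr.pairs, 0, mlen)
    if len(duplex) != mlen - overhang:
        return False
    m_paired = [i for i, _ in duplex]
    s_paired = [p for _, p in duplex]
    star_start = mlen + loop_len
    return (min(m_paired) == 0 and max(m_paired) == mlen - overhang - 1
            and min(s_paired) == star_start
            and max(s_paired) == star_start + mlen - overhang - 1)


def simulate_genome(config: SimConfig) -> tuple[list[SeqRecord], TruthTable]:
    """Plant ``n_hairpins`` pre-miRNA hairpins, one per contig, both strands.

    Also emits one repeat contig carrying a 22-mer at six loci (food for the
    multi-locus mapping discard).  Deterministic given the seed.
    """
    if config.n_hairpins <= 0:
        raise ConfigError("n_hairpins must be positive")
    rng = config.rng("genome")
    truth = TruthTable()
    contigs: list[SeqRecord] = []
    flank_window = 70  # discovery window flank used for fold verification

    for i in range(config.n_hairpins):
        overhang = (config.rescue_overhang if i < config.rescue_hairpins
                    else config.overhang)
        weak_seed = (config.n_conserved <= i < config.n_conserved + config.n_weak_matures)
        flank_a = _rand_seq(rng, config.flank_len)
        flank_b = _rand_seq(rng, config.flank_len)
        strand = "+" if i % 2 == 0 else "-"
        for _attempt in range(80):
            mature, loop, star = _build_arms(rng, config, overhang, weak_seed)
            hairpin = mature + loop + star
            insert = hairpin if strand == "+" else revcomp(hairpin)
            contig_seq = flank_a + insert + flank_b
            # verify on the exact strand-local window discovery will excise
            local = contig_seq if strand == "+" else revcomp(contig_seq)
            window = local[config.flank_len : config.flank_len
                           + config.mature_len + flank_window]
            if _verify_hairpin_window(window, config.mature_len,
                                      config.loop_len, overhang):
                break
        else:
            raise ConfigError(f"could not construct hairpin {i}")
        cid = f"contig{i:03d}"
        contigs.append(SeqRecord(cid, contig_seq))
        truth.hairpins.append(PlantedHairpin(
            index=i, contig=cid, strand=strand,
            local_start=config.flank_len,
            genomic_start=config.flank_len,
            genomic_end=config.flank_len + len(hairpin),
            mature_seq=mature, star_seq=star, loop_seq=loop,
            overhang=overhang,
        ))

    # repeat contig: the same 22-mer at 6 loci
    unit = _rand_seq(rng, 22)
    parts = []
    for _ in range(6):
        parts.append(unit)
        parts.append(_rand_seq(rng, 60))
    contigs.append(SeqRecord("contig_repeat", "".join(parts)))
    truth.read_origin = {}
    return contigs, truth


def make_known_reference(truth: TruthTable, config: SimConfig) -> list[SeqRecord]:
    """Synthetic known-miRNA reference (miRBase-style ids).

    Conserved hairpins appear as <=2-mismatch variants of their matures; the
    rescue hairpin matches two reference entries of one family, mirroring a
    precursor rescued on the strength of two independent known matches.
    Plus two unrelated decoy entries.  All sequences are synthetic.
    """
    rng = config.rng("known")
    families = ["miR-2022", "miR-100", "miR-2023", "miR-2030", "miR-2036",
                "miR-9101", "miR-9102", "miR-9103"]
    out: list[SeqRecord] = []

    def mutate(seq: str, n: int) -> str:
        s = list(seq)
        for pos in rng.choice(len(s), size=n, replace=False):
            s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
        return "".join(s)

    for i, h in enumerate(truth.hairpins[: config.n_conserved]):
        fam = families[i % len(families)]
        if i < config.rescue_hairpins:
            ids = [f"nve-{fam}", f"hma-{fam}"]
        else:
            ids = [f"nve-{fam}"]
        for sid in ids:
            out.append(SeqRecord(sid, mutate(h.mature_seq, 2)))
        h.conserved_ids.extend(ids)
    out.append(SeqRecord("nve-miR-9001", _rand_seq(rng, 22)))
    out.append(SeqRecord("nve-miR-9002", _rand_seq(rng, 22)))
    return out


def make_contaminants(config: SimConfig) -> list[SeqRecord]:
    """Mock rRNA/tRNA contaminant set (~2 kb), deterministic from the seed."""
    rng = config.rng("contaminants")
    return [
        SeqRecord("mock_rRNA_LSU", _rand_seq(rng, 1200)),
        SeqRecord("mock_rRNA_SSU", _rand_seq(rng, 600)),
        SeqRecord("mock_tRNA_pool", _rand_seq(rng, 300)),
    ]


def _quality_profile(rng: np.random.Generator, n: int, cfg: SimConfig) -> list[int]:
    span = cfg.phred_peak - cfg.phred_tail
    qs = []
    for i in range(n):
        base = cfg.phred_peak - span * (i / max(1, cfg.read_len - 1)) ** 2
        q = int(round(base + rng.normal(0, 2.0)))
        qs.append(max(2, min(40, q)))
    return qs


def _sequence(rng: np.random.Generator, insert: str, cfg: SimConfig,
              rid: str) -> SmallRead:
    """Run an insert through the mock instrument: adapter read-through,
    Phred profile, Phred-driven base errors."""
    if len(insert) < cfg.read_len and not cfg.adapter3:
        raise ConfigError("adapter3 empty while inserts are shorter than the read length")
    full = (insert + cfg.adapter3 * 3)[: cfg.read_len]
    quals = _quality_profile(rng, len(full), cfg)
    bases = list(full)
    for i, q in enumerate(quals):
        if rng.random() < 10.0 ** (-q / 10.0):
            bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
    return SmallRead(rid, "".join(bases), quals)


def simulate_reads(genome: list[SeqRecord], truth: TruthTable,
                   config: SimConfig) -> tuple[list[SmallRead], TruthTable]:
    """Generate the small-RNA library over the planted genome.

    Mature/star-arm reads start at the designed 5' end with probability
    ``five_prime_purity`` (else shifted 1-2 nt); the piRNA-like fraction is
    26-31 nt with a 5'-U probability of ``pirna_u_prob``; noise reads are
    short random sequences; contaminant reads are fragments of the mock
    rRNA/tRNA set; the repeat contig contributes multi-locus reads.  Every
    read is labelled in the returned truth table.
    """
    rng = config.rng("reads")
    contig_seq = {c.id: c.seq for c in genome}
    inserts: list[tuple[str, str]] = []  # (origin label, insert sequence)

    for h in truth.hairpins:
        local = (contig_seq[h.contig] if h.strand == "+"
                 else revcomp(contig_seq[h.contig]))
        n = max(30, int(round(float(rng.lognormal(
            np.log(config.reads_per_hairpin_median),
            config.reads_per_hairpin_sigma)))))
        n_mat = int(round(n * config.mature_frac))
        n_star = int(round(n * config.star_frac))
        n_loop = max(0, n - n_mat - n_star)
        m5 = h.local_start
        s5 = h.local_start + config.mature_len + config.loop_len
        for arm_start, count, label in ((m5, n_mat, "mature"),
                                        (s5, n_star, "star")):
            for _ in range(count):
                p = arm_start
                if rng.random() > config.five_prime_purity:
                    p += int(rng.choice([-2, -1, 1, 2]))
                inserts.append((label, local[p : p + config.mature_len]))
        loop_lo = m5 + config.mature_len - 4
        loop_hi = max(loop_lo + 1, s5 - 14)
        for _ in range(n_loop):
            p = int(rng.integers(loop_lo, loop_hi))
            inserts.append(("loop", local[p : p + 18]))

    # repeat-derived reads (dropped later by the multi-locus rule)
    rep = contig_seq["contig_repeat"][:22]
    inserts.extend([("repeat", rep)] * 30)

    n_signal = len(inserts)
    f_extra = config.pirna_fraction + config.noise_read_fraction + config.contaminant_read_fraction
    n_total = int(round(n_signal / max(1e-9, 1.0 - f_extra)))
    n_pirna = int(round(n_total * config.pirna_fraction))
    n_noise = int(round(n_total * config.noise_read_fraction))
    n_contam = int(round(n_total * config.contaminant_read_fraction))

    for _ in range(n_pirna):
        L = int(rng.integers(26, 32))
        seq = _rand_seq(rng, L)
        if rng.random() < config.pirna_u_prob:
            seq = "T" + seq[1:]
        else:
            seq = str(rng.choice(["A", "C", "G"])) + seq[1:]
        inserts.append(("pirna", seq))
    for _ in range(n_noise):
        inserts.append(("noise", _rand_seq(rng, int(rng.integers(15, 25)))))
    contaminants = make_contaminants(config)
    for _ in range(n_contam):
        src = contaminants[int(rng.integers(len(contaminants)))]
        L = int(rng.integers(21, 31))
        p = int(rng.integers(0, len(src.seq) - L))
        frag = src.seq[p : p + L]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        inserts.append(("contaminant", frag))

    order = rng.permutation(len(inserts))
    reads: list[SmallRead] = []
    origin: dict[str, str] = {}
    for serial, idx in enumerate(order):
        label, insert = inserts[int(idx)]
        rid = f"r{serial:06d}"
        reads.append(_sequence(rng, insert, config, rid))
        origin[rid] = label
    truth = replace(truth, read_origin=origin)
    return reads, truth


# ---------------------------------------------------------------------------
# transcripts with planted target sites


def _non_pairing(base: str, rng: np.random.Generator) -> str:
    """A base from {A, C} that cannot pair (WC or GU) with ``base``."""
    if base == "G":
        return "A"
    if base == "T":
        return "C"
    return str(rng.choice(["A", "C"]))


def _orf_block(rng: np.random.Generator, codons: int) -> str:
    stops = {"TAA", "TAG", "TGA"}
    parts = ["ATG"]
    for _ in range(codons):
        while True:
            c = _rand_seq(rng, 3)
            if c not in stops:
                break
        parts.append(c)
    parts.append("TAA")
    return "".join(parts)


def _weak_compatible(mature: str) -> bool:
    return all(b in "AC" for b in mature[1:8])


def simulate_transcripts(matures: list[SeqRecord], config: SimConfig
                         ) -> tuple[list[SeqRecord], TruthTable]:
    """Transcripts = leader + designed longest ORF + 3' UTR with planted sites.

    Strong sites are full reverse complements of a mature placed in a
    low-structure {A,C} context (opening cost ~ 0, deep duplex energy); weak
    sites are seed-only matches locked inside a designed stem whose opposite
    strand is the seed itself, so the opening cost provably cancels the
    duplex energy.  Each transcript is verified against the package's own
    ORF finder, UTR extractor and energy functions before being emitted.
    """
    if not matures:
        raise ConfigError("at least one mature miRNA is required")
    if any(len(m.seq) < 9 for m in matures):
        raise ConfigError("mature shorter than the seed span")
    rng = config.rng("transcripts")
    model = EnergyModel()
    weak_pool = [m for m in matures if _weak_compatible(m.seq)]
    if config.n_weak_sites > 0 and not weak_pool:
        raise ConfigError("no weak-seed-compatible matures available")

    transcripts: list[SeqRecord] = []
    truth = TruthTable()
    kinds = (["strong"] * config.n_strong_sites + ["weak"] * config.n_weak_sites
             + ["none"] * max(0, config.n_transcripts - config.n_strong_sites
                              - config.n_weak_sites))

    for t_idx, kind in enumerate(kinds):
        tid = f"tx{t_idx:04d}"
        if kind == "strong":
            mat = matures[t_idx % len(matures)]
        elif kind == "weak":
            mat = weak_pool[t_idx % len(weak_pool)]
        else:
            mat = None

        for _attempt in range(60):
            ctx = config.utr_context
            if kind == "strong":
                site = revcomp(mat.seq)
                left = _rand_seq(rng, ctx, "AC")
                right = _rand_seq(rng, ctx + 1, "AC")
                utr = left + site + right
                # the predictor anchors on the seed match, which sits at the
                # 3' end of the reverse-complemented mature
                site_start = ctx + len(mat.seq) - 8
                site_end = site_start + 7
            elif kind == "weak":
                seed = mat.seq[1:8]
                site = revcomp(seed)                      # {G,T} letters only
                left = list(_rand_seq(rng, ctx, "AC"))
                left[-1] = _non_pairing(mat.seq[8], rng)  # block 3' extension
                loop = list(_rand_seq(rng, 5, "AC"))
                loop[0] = _non_pairing(mat.seq[0], rng)   # block 5' extension
                right = _rand_seq(rng, ctx + 1, "AC")
                utr = "".join(left) + site + "".join(loop) + seed + right
                site_start, site_end = ctx, ctx + len(site)
            else:
                utr = _rand_seq(rng, 2 * config.utr_context + 20)
                site_start = site_end = -1

            leader = _rand_seq(rng, config.leader_len)
            seq = leader + _orf_block(rng, config.orf_codons) + utr
            rec = SeqRecord(tid, seq)
            orf = longest_orf(rec)
            if orf is None or orf.end != len(seq) - len(utr):
                continue  # a chance ORF outgrew the designed one; redraw
            utr3 = extract_utr3(rec, orf)
            if utr3 is None or utr3.seq != utr:
                continue
            if kind != "none" and mat is not None:
                dg = duplex_dG(mat.seq, utr3, site_start, model)
                oc = open_cost(utr3, site_start, site_start + 7, model=model)
                ddg = dg + oc
                if kind == "strong" and ddg > config.planted_site_ddG_strong:
                    continue
                if kind == "weak" and ddg < config.planted_site_ddG_weak:
                    continue
                truth.sites.append(PlantedSite(tid, mat.id, site_start,
                                               site_end, kind, ddg))
            transcripts.append(rec)
            break
        else:
            raise ConfigError(f"could not construct transcript {tid} ({kind})")
    return transcripts, truth


# ---------------------------------------------------------------------------
# ontology


def simulate_ontology(config: SimConfig, genes: list[str] | None = None,
                      study_genes: list[str] | None = None
                      ) -> tuple[OntologyDAG, dict[str, set[str]], set[str], str]:
    """Random is_a DAG + gene annotations with one truly enriched term.

    Returns (dag, direct annotations, study set, enriched term id).  When
    ``genes``/``study_genes`` are not given, a background of
    ``n_background_genes`` with the first ``study_size`` as the study set is
    generated.  Study genes carry the enriched term at ``go_base_rate *
    enriched_term_effect``; background genes at ``go_base_rate``.
    """
    if config.n_go_terms < 3:
        raise ConfigError("n_go_terms must be >= 3")
    if config.enriched_term_effect <= 1:
        raise ConfigError("enriched_term_effect must exceed 1")
    rng = config.rng("ontology")

    term_ids = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    names = {t: f"synthetic process {i + 1}" for i, t in enumerate(term_ids)}
    edges: list[tuple[str, str]] = []
    for i in range(1, config.n_go_terms):
        n_par = 1 if (i < 3 or rng.random() < 0.7) else 2
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in parents:
            edges.append((term_ids[i], term_ids[int(p)]))
    dag = OntologyDAG(names, edges)

    leaves = sorted(t for t in dag.terms if not dag.children(t))
    enriched = max(leaves, key=lambda t: (dag.depth(t), t))
    annotatable = sorted(dag.terms - dag.roots)

    if genes is None:
        genes = [f"g{i:04d}" for i in range(config.n_background_genes)]
    if study_genes is None:
        study_genes = genes[: config.study_size]
    study = set(study_genes)

    annotations: dict[str, set[str]] = {}
    q_bg = config.go_base_rate
    q_study = min(1.0, q_bg * config.enriched_term_effect)
    for g in genes:
        k = int(rng.integers(1, 4))
        terms = set(str(t) for t in rng.choice(annotatable, size=k, replace=False))
        terms.discard(enriched)
        if rng.random() < (q_study if g in study else q_bg):
            terms.add(enriched)
        annotations[g] = terms
    return dag, annotations, study, enriched


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialise a DAG back to the OBO subset the parser reads."""
    with open(str(path), "w") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {dag.names[t]}\n")
            for p in sorted(dag.parents(t)):
                fh.write(f"is_a: {p} ! {dag.names[p]}\n")


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("gene\tgo_id\n")
        for g in sorted(annotations):
            for t in sorted(annotations[g]):
                fh.write(f"{g}\t{t}\n")


# ---------------------------------------------------------------------------
# decoys for the specificity check


def simulate_decoys(config: SimConfig, n_decoys: int = 200
                    ) -> list[tuple[PrecursorCandidate, list[tuple[int, int]]]]:
    """Structure-free decoy windows with planted-like read stacks.

    Each decoy is a random window the size of a discovery excision, carrying
    a read stack whose count distribution and 5' purity mirror the planted
    hairpins -- only the hairpin structure is missing.  The classifier's
    false-positive rate is measured on these.
    """
    rng = config.rng("decoys")
    win_len = config.mature_len + 70
    out = []
    for i in range(n_decoys):
        seq = _rand_seq(rng, win_len)
        n = max(30, int(round(float(rng.lognormal(
            np.log(config.reads_per_hairpin_median),
            config.reads_per_hairpin_sigma)))))
        reads = []
        for _ in range(n):
            p = 0
            if rng.random() > config.five_prime_purity:
                p += int(rng.choice([1, 2]))
            reads.append((p, config.mature_len))
        cand = PrecursorCandidate(
            id=f"decoy-{i:03d}", contig=f"decoy-{i:03d}", strand="+",
            local_start=0, local_end=win_len, seq=seq,
            mature_offset=0, mature_len=config.mature_len,
        )
        out.append((cand, reads))
    return out
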