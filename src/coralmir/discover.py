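"""Hairpin-based miRNA discovery.

Cleaned reads are mapped exactly to the genome (both strands, discarding
reads at more than five genomic loci), read stacks with homogeneous 5' ends
are called, candidate precursor windows are excised around each stack and
folded, and the duplex statistics used to separate genuine Dicer products
from fold noise are computed: length of the 3' overhang of the mature:star
duplex, proportion of reads sharing the modal 5' end, number of mismatched
(unpaired) bases in the stem, and read support on each arm.  A candidate
passes when all criteria hold; a candidate failing *only* the overhang
criterion, with an overhang of at most 3 nt and at least one match to a
known miRNA, is rescued into the set on conservation evidence.

Coordinates are 0-based half-open.  Stacks and windows are handled in
strand-local coordinates (minus-strand contigs are reverse-complemented), so
the excision and duplex geometry is strand-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigError, DegenerateCandidateError
from .fold import FoldResult, fold_hairpin
from .formats import SeqRecord, SmallRead, revcomp

__all__ = [
    "GenomeIndex",
    "Alignment",
    "ReadStack",
    "PrecursorCandidate",
    "HairpinMetrics",
    "BonaFideVerdict",
    "ClassifyThresholds",
    "map_reads",
    "call_stacks",
    "excise_precursors",
    "duplex_metrics",
    "score_candidate",
    "classify",
]


class GenomeIndex:
    """Exact-match k-mer seed index over the forward strand of each contig.

    A query is located by looking up its first k-mer and verifying the full
    match by slice comparison; minus-strand hits are found by querying the
    reverse complement.  Lookups return every exact occurrence (verified
    against a naive substring scan in the test suite).
    """

    def __init__(self, contigs: list[SeqRecord], k: int = 12):
        if not contigs:
            raise ConfigError("empty genome")
        self.k = k
        self.contigs = {c.id: c.seq for c in contigs}
        self.rc = {cid: revcomp(seq) for cid, seq in self.contigs.items()}
        self._idx: dict[str, list[tuple[str, int]]] = {}
        for cid, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                self._idx.setdefault(seq[i : i + k], []).append((cid, i))

    def find(self, query: str) -> list[tuple[str, int]]:
        """All forward-strand occurrences of ``query`` as (contig, start)."""
        if len(query) < self.k:
            # fall back to direct scan for sub-seed queries
            out = []
            for cid, seq in self.contigs.items():
                p = seq.find(query)
                while p != -1:
                    out.append((cid, p))
                    p = seq.find(query, p + 1)
            return out
        hits = []
        for cid, pos in self._idx.get(query[: self.k], ()):
            if self.contigs[cid][pos : pos + len(query)] == query:
                hits.append((cid, pos))
        return hits


@dataclass
class Alignment:
    """An exact, full-length placement of a read on the genome."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str          # "+" or "-"
    copies: int          # genomic loci for this read sequence (both strands)

    @property
    def length(self) -> int:
        return self.end - self.start


def map_reads(reads: list[SmallRead], genome: GenomeIndex,
              min_len: int = 18, max_loci: int = 5) -> list[Alignment]:
    """Exact mapping of reads >= ``min_len`` nt, both strands.

    A read sequence occurring at more than ``max_loci`` genomic loci (summed
    over strands) produces no alignments at all, keeping repeat-derived reads
    out of precursor calling.
    """
    # group reads by sequence so each distinct sequence is located once
    by_seq: dict[str, list[str]] = {}
    for r in reads:
        if len(r) >= min_len:
            by_seq.setdefault(r.seq, []).append(r.id)

    out: list[Alignment] = []
    for seq, ids in by_seq.items():
        fwd = genome.find(seq)
        rev = genome.find(revcomp(seq))
        copies = len(fwd) + len(rev)
        if copies == 0 or copies > max_loci:
            continue
        for rid in ids:
            for cid, pos in fwd:
                out.append(Alignment(rid, cid, pos, pos + len(seq), "+", copies))
            for cid, pos in rev:
                out.append(Alignment(rid, cid, pos, pos + len(seq), "-", copies))
    return out


@dataclass
class ReadStack:
    """Reads sharing (up to ``merge_gap``) one 5' position on one strand.

    Positions are strand-local: on the minus strand, local coordinate 0 is
    the last base of the contig, so a read's local start is always its 5'
    end.
    """

    contig: str
    strand: str
    histogram: dict[int, int]            # local 5' position -> read count
    reads: list[tuple[int, int]]         # (local 5' position, read length)
    modal: int = 0
    total: int = 0
    modal_len: int = 0

    def finalise(self) -> None:
        self.total = sum(self.histogram.values())
        # modal 5' position; ties resolved toward the smaller coordinate
        self.modal = min(
            (p for p in self.histogram
             if self.histogram[p] == max(self.histogram.values()))
        )
        lens = [ln for p, ln in self.reads if p == self.modal]
        self.modal_len = max(set(lens), key=lambda x: (lens.count(x), -x))


def _local_start(aln: Alignment, contig_len: int) -> int:
    if aln.strand == "+":
        return aln.start
    return contig_len - aln.end


def call_stacks(alignments: list[Alignment], genome: GenomeIndex,
                min_count: int = 10, merge_gap: int = 2) -> list[ReadStack]:
    """Cluster alignments into 5'-position stacks per contig and strand.

    5' positions within ``merge_gap`` of each other merge into one stack;
    stacks supported by fewer than ``min_count`` reads are dropped.
    """
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for a in alignments:
        L = len(genome.contigs[a.contig])
        grouped.setdefault((a.contig, a.strand), []).append(
            (_local_start(a, L), a.length)
        )
    stacks: list[ReadStack] = []
    for (cid, strand), items in grouped.items():
        items.sort()
        cluster: list[tuple[int, int]] = []
        last = None
        for pos, ln in items + [(None, None)]:
            if last is not None and (pos is None or pos - last > merge_gap):
                hist: dict[int, int] = {}
                for p, _ in cluster:
                    hist[p] = hist.get(p, 0) + 1
                st = ReadStack(cid, strand, hist, cluster)
                st.finalise()
                if st.total >= min_count:
                    stacks.append(st)
                cluster = []
            if pos is None:
                break
            cluster.append((pos, ln))
            last = pos
    stacks.sort(key=lambda s: (s.contig, s.strand, s.modal))
    return stacks


@dataclass
class PrecursorCandidate:
    """An excised genomic window holding a putative pre-miRNA."""

    id: str
    contig: str
    strand: str
    local_start: int        # window span, strand-local coordinates
    local_end: int
    seq: str
    mature_offset: int      # mature arm start within the window
    mature_len: int
    clipped: bool = False   # window truncated at a contig end
    fold: FoldResult | None = None

    @property
    def mature_seq(self) -> str:
        return self.seq[self.mature_offset : self.mature_offset + self.mature_len]

    def genomic_span(self, contig_len: int) -> tuple[int, int]:
        """Window span in forward-genome coordinates."""
        if self.strand == "+":
            return self.local_start, self.local_end
        return contig_len - self.local_end, contig_len - self.local_start


def excise_precursors(stack: ReadStack, genome: GenomeIndex, flank: int = 70,
                      min_extra: int = 18) -> list[PrecursorCandidate]:
    """Excise the two candidate windows around a stack's modal read.

    Window A runs downstream from the modal 5' end (mature on the 5' arm of
    a putative hairpin); window B runs upstream ending at the modal 3' end
    (mature on the 3' arm).  Windows are clipped at contig ends and skipped
    when shorter than mature + minimal loop and counter-arm (``min_extra``).
    """
    seq = genome.contigs[stack.contig] if stack.strand == "+" else genome.rc[stack.contig]
    L = len(seq)
    m5, mlen = stack.modal, stack.modal_len
    m3 = m5 + mlen
    out = []
    for tag, (a, b) in (("dn", (m5, m5 + mlen + flank)),
                        ("up", (m3 - mlen - flank, m3))):
        ca, cb = max(0, a), min(L, b)
        clipped = (ca, cb) != (a, b)
        if cb - ca < mlen + min_extra:
            continue
        mature_offset = m5 - ca
        if mature_offset < 0 or mature_offset + mlen > cb - ca:
            continue
        out.append(PrecursorCandidate(
            id=f"{stack.contig}:{stack.strand}:{m5}:{tag}",
            contig=stack.contig, strand=stack.strand,
            local_start=ca, local_end=cb, seq=seq[ca:cb],
            mature_offset=mature_offset, mature_len=mlen, clipped=clipped,
        ))
    return out


@dataclass
class HairpinMetrics:
    """The filter statistics judged for each candidate."""

    overhang3: int | None               # max 3' protrusion of the duplex strands
    overhang3_mature: int | None
    overhang3_star: int | None
    five_prime_consistency: float
    stem_mismatches: int
    mature_count: int
    star_count: int
    loop_count: int
    mature_paired_fraction: float
    duplex_pairs: int


def _duplex_run(pairs: dict[int, int], m_start: int, m_end: int,
                max_jump: int = 6) -> list[tuple[int, int]]:
    """Longest helix anchored in the mature arm.

    The mature:star duplex of a genuine precursor is one quasi-contiguous
    helix; scattered pairings of a random fold are not.  Paired mature
    positions are chained while the partner coordinate keeps descending and
    the combined bulge on the two strands stays small (<= ``max_jump`` - 2
    unpaired bases between consecutive pairs); the chain with the most pairs
    is the duplex.
    """
    anchored = [
        (i, pairs[i]) for i in range(m_start, m_end)
        if i in pairs and not (m_start <= pairs[i] < m_end)
    ]
    if not anchored:
        return []
    best: list[tuple[int, int]] = []
    run: list[tuple[int, int]] = []
    for i, p in anchored:
        if run:
            di = i - run[-1][0]
            dp = run[-1][1] - p
            if dp > 0 and di + dp <= max_jump:
                run.append((i, p))
            else:
                if len(run) > len(best):
                    best = run
                run = [(i, p)]
        else:
            run = [(i, p)]
    if len(run) > len(best):
        best = run
    return best


def duplex_metrics(candidate: PrecursorCandidate, fold_result: FoldResult,
                   window_reads: list[tuple[int, int]],
                   five_prime_tol: int = 3) -> HairpinMetrics:
    """Compute the duplex statistics for a folded candidate.

    ``window_reads`` are (local 5' position, length) for every aligned read
    on the candidate's contig/strand that overlaps the window, in window
    coordinates handled by the caller being contig-local (they are shifted
    here).  Reads are assigned to the mature arm (5' end within
    ``five_prime_tol`` of the mature start), the star arm (>= half the read
    overlapping the star span), or the loop.

    The 3' overhang is measured for both duplex strands -- the number of
    3'-terminal bases of each strand extending past the partner of the other
    strand's 5'-most paired base -- and reported as the maximum of the two.
    Stem mismatches are mature bases with no partner inside the duplex
    interval.
    """
    w0 = candidate.local_start
    m_start = candidate.mature_offset
    m_end = m_start + candidate.mature_len
    duplex = _duplex_run(fold_result.pairs, m_start, m_end)
    if not duplex:
        raise DegenerateCandidateError(
            f"candidate {candidate.id}: mature arm forms no duplex"
        )
    m_paired = [i for i, _ in duplex]
    s_paired = [p for _, p in duplex]
    s_lo_pair, s_hi_pair = min(s_paired), max(s_paired)

    # read assignment (positions shifted into window coordinates)
    reads_w = [(p - w0, ln) for p, ln in window_reads
               if p - w0 + ln > 0 and p - w0 < len(candidate.seq)]
    mature_reads = [(p, ln) for p, ln in reads_w if abs(p - m_start) <= five_prime_tol]
    star_reads = []
    loop_reads = []
    star_span = (s_lo_pair, s_hi_pair + 1)
    for p, ln in reads_w:
        if abs(p - m_start) <= five_prime_tol:
            continue
        ov = min(p + ln, star_span[1]) - max(p, star_span[0])
        if ov >= ln / 2:
            star_reads.append((p, ln))
        else:
            loop_reads.append((p, ln))

    # star arm extent: modal observed star read when present (the modal 5'/3'
    # ends are the Dicer cut positions; stray +/-1-2 nt reads must not widen
    # the arm), else the paired span
    if star_reads:
        def _modal(values: list[int]) -> int:
            counts: dict[int, int] = {}
            for v in values:
                counts[v] = counts.get(v, 0) + 1
            top = max(counts.values())
            return min(v for v, c in counts.items() if c == top)

        s_lo = _modal([p for p, _ in star_reads])
        s_hi = _modal([p + ln - 1 for p, ln in star_reads])
    else:
        s_lo, s_hi = s_lo_pair, s_hi_pair

    # mature 3' overhang: distance from the mature 3' end to the partner of
    # the star arm's 5'-most paired base, less any star 5' dangle -- and
    # symmetrically for the star strand.  The same expressions hold whether
    # the mature arm is the 5' or the 3' arm of the hairpin.
    ov_m = ((m_end - 1) - max(m_paired)) - (s_lo_pair - s_lo)
    ov_s = (s_hi - max(s_paired)) - (min(m_paired) - m_start)

    hist: dict[int, int] = {}
    for p, _ in mature_reads:
        hist[p] = hist.get(p, 0) + 1
    if hist:
        modal_n = max(hist.values())
        consistency = modal_n / sum(hist.values())
    else:
        consistency = 0.0

    mismatches = sum(
        1 for i in range(min(m_paired), max(m_paired) + 1) if i not in dict(duplex)
    )
    return HairpinMetrics(
        overhang3=max(ov_m, ov_s),
        overhang3_mature=ov_m,
        overhang3_star=ov_s,
        five_prime_consistency=consistency,
        stem_mismatches=mismatches,
        mature_count=len(mature_reads),
        star_count=len(star_reads),
        loop_count=len(loop_reads),
        mature_paired_fraction=len(duplex) / candidate.mature_len,
        duplex_pairs=len(duplex),
    )


def score_candidate(metrics: HairpinMetrics) -> float:
    """Plausibility score: read support, star evidence, stem pairing.

    score = log2(1 + mature reads) + 3*[star reads >= 1]
          + 5 * mature_paired_fraction
    """
    return (
        math.log2(1 + metrics.mature_count)
        + (3.0 if metrics.star_count >= 1 else 0.0)
        + 5.0 * metrics.mature_paired_fraction
    )


@dataclass
class ClassifyThresholds:
    """Pass criteria for the *bona fide* call (all CLI-overridable)."""

    min_score: float = 10.0
    overhang: int = 2
    overhang_tol: int = 0
    min_five_prime_consistency: float = 0.8
    max_stem_mismatches: int = 4
    min_paired_fraction: float = 0.6
    rescue_max_overhang: int = 3


@dataclass
class BonaFideVerdict:
    candidate_id: str
    passed: bool
    failed: list[str] = field(default_factory=list)
    rescued_by_conservation: bool = False
    score: float = 0.0


def classify(entries: list[tuple[PrecursorCandidate, HairpinMetrics]],
             conservation_hits: dict[str, int] | None = None,
             thresholds: ClassifyThresholds | None = None) -> list[BonaFideVerdict]:
    """Apply the pass criteria; rescue overhang-only failures with
    conservation support (at most a 3-nt overhang and >= 1 known-miRNA hit).

    ``conservation_hits`` maps candidate id -> number of known-miRNA matches.
    """
    th = thresholds or ClassifyThresholds()
    hits = conservation_hits or {}
    verdicts = []
    for cand, m in entries:
        sc = score_candidate(m)
        failed = []
        if sc < th.min_score:
            failed.append("score")
        if m.overhang3 is None or abs(m.overhang3 - th.overhang) > th.overhang_tol:
            failed.append("overhang")
        if m.five_prime_consistency < th.min_five_prime_consistency:
            failed.append("five_prime_consistency")
        if m.stem_mismatches > th.max_stem_mismatches:
            failed.append("stem_mismatches")
        if m.mature_paired_fraction < th.min_paired_fraction:
            failed.append("paired_fraction")
        rescued = False
        passed = not failed
        if (failed == ["overhang"] and m.overhang3 is not None
                and m.overhang3 <= th.rescue_max_overhang
                and hits.get(cand.id, 0) >= 1):
            passed, rescued = True, True
        verdicts.append(BonaFideVerdict(cand.id, passed, failed, rescued, sc))
    return verdicts
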