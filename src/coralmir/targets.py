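"""Accessibility-energy (ddG) miRNA target prediction on 3' UTRs.

The 3' UTR of each transcript is the sequence downstream of its longest
forward-frame ORF; UTRs under 100 bp are discarded.  For every seed match of
a mature miRNA in a UTR the site's score is

    ddG = dG_duplex + open_cost

where dG_duplex (<= 0) is the pairing energy of the miRNA:target duplex
under a per-pair energy model (GC -3, AU -2, GU -1 kcal/mol) extended
outward from the seed while pairs form, and open_cost (>= 0) is the energy
needed to free the site from local secondary structure: the fold score of
the +/-70 nt context minus the fold score with the site bases forced
unpaired, in the same per-pair units.  Sites with ddG at or below the cutoff
(default -10 kcal/mol) are retained.

Sign convention: open_cost is defined positive, so ddG = dG_duplex +
open_cost; this equals the usual "duplex energy minus opening energy" with
the opening energy taken as negative.  ddG is never below dG_duplex.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fold import fold, pair_weight
from .formats import SeqRecord, from_rna, revcomp

__all__ = [
    "OpenReadingFrame",
    "UTR3",
    "EnergyModel",
    "TargetSite",
    "longest_orf",
    "extract_utr3",
    "seed_matches",
    "duplex_dG",
    "open_cost",
    "predict_targets",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OpenReadingFrame:
    transcript_id: str
    frame: int
    start: int      # 0-based half-open, forward strand
    end: int
    stop_terminated: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UTR3:
    transcript_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class EnergyModel:
    """Per-pair energies in kcal/mol; loop and overhang penalties are zero."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0

    def pair_energy(self, a: str, b: str) -> float:
        w = pair_weight(a, b)
        return {3: self.gc, 2: self.au, 1: self.gu, 0: 0.0}[w]

    def score_to_energy(self, score: int) -> float:
        """Convert an integer fold score to kcal/mol (1 unit = 1 kcal/mol
        when the default -3/-2/-1 table is in use)."""
        unit = abs(self.gc) / 3.0
        return unit * score


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    utr_start: int
    utr_end: int
    seed_len: int
    dg_duplex: float
    open_cost: float

    @property
    def ddg(self) -> float:
        return self.dg_duplex + self.open_cost


def longest_orf(transcript: SeqRecord) -> OpenReadingFrame | None:
    """Longest ATG-initiated ORF over the three forward frames.

    ORFs end at the first in-frame stop (stop included) or at the transcript
    end (truncated).  Ties break toward the smaller start coordinate.  No
    ATG anywhere -> None.
    """
    seq = transcript.seq
    best: OpenReadingFrame | None = None
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                j = i
                stop = False
                while j + 3 <= len(seq):
                    codon = seq[j : j + 3]
                    if codon in _STOPS:
                        stop = True
                        j += 3
                        break
                    j += 3
                end = j if stop else len(seq) - (len(seq) - frame) % 3
                orf = OpenReadingFrame(transcript.id, frame, i, end, stop)
                if best is None or orf.length > best.length or (
                        orf.length == best.length and orf.start < best.start):
                    best = orf
                # next ATG after this ORF in the same frame
                i = end if stop else len(seq)
                continue
            i += 3
    return best


def extract_utr3(transcript: SeqRecord, orf: OpenReadingFrame | None,
                 min_len: int = 100) -> UTR3 | None:
    """Transcript suffix after the ORF; kept only at ``min_len`` or longer."""
    if orf is None:
        return None
    utr = transcript.seq[orf.end :]
    if len(utr) < min_len:
        return None
    return UTR3(transcript.id, utr)


def seed_matches(mature: str, utr: UTR3, seed_len: int = 7,
                 seed_start: int = 2, allow_gu: bool = False) -> list[int]:
    """UTR start positions of matches to the miRNA seed.

    The seed is mature positions ``seed_start`` .. ``seed_start+seed_len-1``
    in 1-based miRNA numbering (default 2-8); a match is the exact reverse
    complement in the UTR (Watson-Crick only unless ``allow_gu``).
    """
    m = from_rna(mature)
    if len(m) < seed_start - 1 + seed_len:
        return []
    seed = m[seed_start - 1 : seed_start - 1 + seed_len]
    positions = []
    if not allow_gu:
        target = revcomp(seed)
        p = utr.seq.find(target)
        while p != -1:
            positions.append(p)
            p = utr.seq.find(target, p + 1)
    else:
        n = len(utr.seq)
        for p in range(n - seed_len + 1):
            window = utr.seq[p : p + seed_len]
            # antiparallel: seed base k pairs window base seed_len-1-k
            if all(pair_weight(seed[k], window[seed_len - 1 - k]) > 0
                   for k in range(seed_len)):
                positions.append(p)
    return positions


def duplex_dG(mature: str, utr: UTR3, site: int, model: EnergyModel | None = None,
              seed_len: int = 7, seed_start: int = 2) -> float:
    """Pairing energy of the miRNA:site duplex (kcal/mol, <= 0).

    The seed duplex is extended outward base by base while pairs (WC or GU)
    keep forming; the first mismatch on each side terminates extension.
    """
    model = model or EnergyModel()
    m = from_rna(mature)
    s0 = seed_start - 1            # 0-based seed start on the miRNA
    # mature position s0+k pairs UTR position site+seed_len-1-k
    energy = 0.0
    for k in range(seed_len):
        energy += model.pair_energy(m[s0 + k], utr.seq[site + seed_len - 1 - k])
    # extend 3' on the miRNA (5' on the UTR)
    mp, up = s0 + seed_len, site - 1
    while mp < len(m) and up >= 0:
        e = model.pair_energy(m[mp], utr.seq[up])
        if e == 0.0:
            break
        energy += e
        mp += 1
        up -= 1
    # extend 5' on the miRNA (3' on the UTR)
    mp, up = s0 - 1, site + seed_len
    while mp >= 0 and up < len(utr.seq):
        e = model.pair_energy(m[mp], utr.seq[up])
        if e == 0.0:
            break
        energy += e
        mp -= 1
        up += 1
    return energy


def open_cost(utr: UTR3, site_start: int, site_end: int, window: int = 70,
              model: EnergyModel | None = None) -> float:
    """Energy to free the site from local structure (kcal/mol, >= 0).

    The +/-``window`` context around the site is folded unconstrained and
    with the site bases forced unpaired; the cost is the energy difference.
    The window is clipped at the UTR ends.
    """
    model = model or EnergyModel()
    lo = max(0, site_start - window)
    hi = min(len(utr.seq), site_end + window)
    ctx = utr.seq[lo:hi]
    blocked = frozenset(range(site_start - lo, site_end - lo))
    free = fold(ctx)
    constrained = fold(ctx, blocked=blocked)
    return model.score_to_energy(free.score - constrained.score)


def predict_targets(matures: list[SeqRecord], utrs: list[UTR3],
                    cutoff: float = -10.0, model: EnergyModel | None = None,
                    seed_len: int = 7, seed_start: int = 2,
                    allow_gu: bool = False, window: int = 70,
                    keep_all: bool = False) -> list[TargetSite]:
    """Score every seed match of every miRNA in every UTR; retain by ddG.

    Returns retained sites (all sites when ``keep_all``), ordered by ddG
    ascending then coordinates, deterministic.
    """
    model = model or EnergyModel()
    out: list[TargetSite] = []
    for mat in matures:
        for utr in utrs:
            for pos in seed_matches(mat.seq, utr, seed_len, seed_start, allow_gu):
                dg = duplex_dG(mat.seq, utr, pos, model, seed_len, seed_start)
                oc = open_cost(utr, pos, pos + seed_len, window, model)
                site = TargetSite(mat.id, utr.transcript_id, pos,
                                  pos + seed_len, seed_len, dg, oc)
                if keep_all or site.ddg <= cutoff:
                    out.append(site)
    out.sort(key=lambda s: (s.ddg, s.mirna_id, s.transcript_id, s.utr_start))
    return out
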