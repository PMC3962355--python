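"""Small-RNA read cleaning: 3' quality trimming, mean-quality and
expected-error filters, adapter trimming, contaminant removal and the
length/first-nucleotide composition report.

Stage order follows the sequencing protocol the statistics were designed
around: trim low-quality 3' ends, drop reads whose mean Phred is not above
20 or whose mean per-base error probability exceeds 2%, trim library
adapters, remove rRNA/tRNA/mRNA fragments by exact k-mer matching against a
contaminant set, and finally keep reads of at least 10 bp.  The ">20"
thresholds are strict: a terminal base at Phred 20 is trimmed, a read whose
mean is exactly 20 fails.

Reads containing N are discarded at the error-rate stage: the per-base error
probability of a no-call base is undefined, so the error statistic cannot be
computed for such reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, CoralmirError
from .formats import SeqRecord, SmallRead, revcomp

__all__ = [
    "QCParams",
    "QCReport",
    "quality_trim",
    "expected_error_rate",
    "trim_adapters",
    "contaminant_filter",
    "run_qc",
    "composition_table",
]


@dataclass
class QCParams:
    """Thresholds of the cleaning stages (defaults = the study's settings)."""

    min_tail_phred: int = 20          # trailing bases at or below this go
    min_mean_phred: float = 20.0      # mean Phred must be strictly above
    max_error_rate: float = 0.02      # mean per-base error probability
    adapter3: str = ""
    adapter5: str = ""
    adapter_min_overlap: int = 3
    adapter_max_error: float = 0.1    # mismatch fraction within the overlap
    min_len: int = 10
    contaminant_k: int = 21

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ConfigError("min_len must be >= 1")
        if self.max_error_rate <= 0 or self.min_tail_phred <= 0:
            raise ConfigError("QC thresholds must be positive")


@dataclass
class QCReport:
    """Read counts through the cleaning funnel plus the composition table.

    ``counts`` is monotonically non-increasing stage to stage.  Because the
    source protocol does not state whether reads emptied by quality trimming
    count as "kept", both conventions are exposed: ``counts['post_quality']``
    counts non-empty reads only, while ``n_emptied_by_trim`` holds the reads
    whose every base was trimmed (kept under the permissive convention:
    post_quality + n_emptied_by_trim).
    """

    counts: dict[str, int] = field(default_factory=dict)
    n_emptied_by_trim: int = 0
    composition: pd.DataFrame | None = None

    STAGES = ("raw", "post_quality", "post_error", "post_adapter",
              "post_contaminant", "post_length")

    def as_frame(self) -> pd.DataFrame:
        rows = [(s, self.counts.get(s, 0)) for s in self.STAGES]
        df = pd.DataFrame(rows, columns=["stage", "reads"])
        return df


def quality_trim(read: SmallRead, min_tail_phred: int = 20) -> SmallRead:
    """Trim trailing bases while the terminal base's Phred is <= threshold.

    May return an empty read (later removed by the length filter)."""
    end = len(read.quals)
    while end > 0 and read.quals[end - 1] <= min_tail_phred:
        end -= 1
    if end == len(read.quals):
        return read
    return SmallRead(read.id, read.seq[:end], read.quals[:end])


def expected_error_rate(read: SmallRead) -> float:
    """Mean per-base error probability, from the Phred scores.

    Returns (sum_i 10^(-Q_i/10)) / len(read).  Undefined (error) on an empty
    read."""
    if len(read) == 0:
        raise CoralmirError("expected_error_rate is undefined for an empty read")
    return sum(10.0 ** (-q / 10.0) for q in read.quals) / len(read)


def _match_len_3p(seq: str, adapter: str, min_overlap: int, max_err: float) -> int:
    """Longest suffix of ``seq`` matching a prefix of ``adapter``."""
    for L in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        window = seq[-L:]
        prefix = adapter[:L]
        mm = sum(1 for a, b in zip(window, prefix) if a != b)
        if mm <= max_err * L:
            return L
    return 0


def _match_len_5p(seq: str, adapter: str, min_overlap: int, max_err: float) -> int:
    """Longest prefix of ``seq`` matching a suffix of ``adapter``."""
    for L in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        window = seq[:L]
        suffix = adapter[-L:]
        mm = sum(1 for a, b in zip(window, suffix) if a != b)
        if mm <= max_err * L:
            return L
    return 0


def trim_adapters(read: SmallRead, adapter3: str = "", adapter5: str = "",
                  min_overlap: int = 3, max_error: float = 0.1) -> SmallRead:
    """Remove 3' (then 5') adapter remnants; qualities are trimmed in step.

    The best match is the longest suffix (prefix) of the read equal to a
    prefix (suffix) of the adapter with mismatch fraction <= ``max_error``
    over at least ``min_overlap`` bases.  Matching repeats until no adapter
    remains, so the operation is idempotent and never lengthens a read.
    """
    seq, quals = read.seq, read.quals
    changed = True
    while changed and seq:
        changed = False
        if adapter3:
            L = _match_len_3p(seq, adapter3, min_overlap, max_error)
            if L:
                seq, quals = seq[:-L], quals[:-L]
                changed = True
        if adapter5 and seq:
            L = _match_len_5p(seq, adapter5, min_overlap, max_error)
            if L:
                seq, quals = seq[L:], quals[L:]
                changed = True
    if seq is read.seq:
        return read
    return SmallRead(read.id, seq, quals)


def _kmer_set(seqs: Iterable[str], k: int) -> set[str]:
    out: set[str] = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            out.add(s[i : i + k])
    return out


def contaminant_filter(reads: Sequence[SmallRead], contaminants: Sequence[SeqRecord],
                       k: int = 21) -> list[SmallRead]:
    """Drop reads sharing any exact k-mer (either strand) with a contaminant.

    Survivor order is preserved.  ``k`` larger than the shortest contaminant
    is a configuration error (the filter would be vacuous for it)."""
    if not contaminants:
        raise ConfigError("contaminant set is empty")
    shortest = min(len(c.seq) for c in contaminants)
    if k > shortest:
        raise ConfigError(
            f"k={k} exceeds shortest contaminant length {shortest}"
        )
    bank = _kmer_set((c.seq for c in contaminants), k)
    bank |= _kmer_set((revcomp(c.seq) for c in contaminants), k)
    kept = []
    for r in reads:
        hit = any(r.seq[i : i + k] in bank for i in range(len(r.seq) - k + 1))
        if not hit:
            kept.append(r)
    return kept


def passes_all_predicates(read: SmallRead, params: QCParams,
                          contaminant_kmers: set[str] | None = None) -> bool:
    """Re-check every QC predicate independently (used as a global invariant)."""
    if len(read) < params.min_len:
        return False
    if read.quals and read.quals[-1] <= params.min_tail_phred:
        return False
    if "N" in read.seq:
        return False
    if sum(read.quals) / len(read) <= params.min_mean_phred:
        return False
    if expected_error_rate(read) > params.max_error_rate:
        return False
    if contaminant_kmers:
        k = params.contaminant_k
        for i in range(len(read.seq) - k + 1):
            if read.seq[i : i + k] in contaminant_kmers:
                return False
    return True


def run_qc(reads: Iterable[SmallRead], params: QCParams,
           contaminants: Sequence[SeqRecord] | None = None) -> tuple[list[SmallRead], QCReport]:
    """Run the full cleaning cascade and produce the funnel report."""
    report = QCReport()
    reads = list(reads)
    report.counts["raw"] = len(reads)

    trimmed = [quality_trim(r, params.min_tail_phred) for r in reads]
    report.n_emptied_by_trim = sum(1 for r in trimmed if len(r) == 0)
    trimmed = [r for r in trimmed if len(r) > 0]
    report.counts["post_quality"] = len(trimmed)

    ok = []
    for r in trimmed:
        if "N" in r.seq:
            continue
        if sum(r.quals) / len(r) <= params.min_mean_phred:
            continue
        if expected_error_rate(r) > params.max_error_rate:
            continue
        ok.append(r)
    report.counts["post_error"] = len(ok)

    ok = [
        trim_adapters(r, params.adapter3, params.adapter5,
                      params.adapter_min_overlap, params.adapter_max_error)
        for r in ok
    ]
    # adapter removal can expose a low-quality 3' base; re-trim so the tail
    # guarantee holds for the emitted reads (mean/error can only improve)
    ok = [quality_trim(r, params.min_tail_phred) for r in ok]
    ok = [r for r in ok if len(r) > 0]
    report.counts["post_adapter"] = len(ok)

    if contaminants:
        ok = contaminant_filter(ok, contaminants, params.contaminant_k)
    report.counts["post_contaminant"] = len(ok)

    ok = [r for r in ok if len(r) >= params.min_len]
    report.counts["post_length"] = len(ok)

    report.composition = composition_table(ok)
    return ok, report


def composition_table(reads: Sequence[SmallRead],
                      min_len: int = 10, max_len: int = 39) -> pd.DataFrame:
    """Length x first-nucleotide count table over cleaned reads.

    One row per observed length within [min_len, max_len]; columns A/C/G/T
    hold counts of the first base, plus per-row fractions.  Mirrors the
    standard small-RNA library composition plot in which a 5'-U bias in the
    26-31 nt band flags a piRNA population.
    """
    counts: dict[int, dict[str, int]] = {}
    for r in reads:
        L = len(r)
        if L < min_len or L > max_len or not r.seq:
            continue
        row = counts.setdefault(L, {"A": 0, "C": 0, "G": 0, "T": 0})
        first = r.seq[0]
        if first in row:
            row[first] += 1
    rows = []
    for L in sorted(counts):
        row = counts[L]
        total = sum(row.values())
        rec = {"length": L, **row, "total": total}
        for b in "ACGT":
            rec[f"frac_{b}"] = row[b] / total if total else 0.0
        rows.append(rec)
    cols = ["length", "A", "C", "G", "T", "total",
            "frac_A", "frac_C", "frac_G", "frac_T"]
    return pd.DataFrame(rows, columns=cols)
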