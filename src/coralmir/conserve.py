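"""Matching predicted mature miRNAs against a known-miRNA reference.

Queries are ~22 nt, so an exhaustive end-gap-free offset scan is exact and
replaces heuristic seeded alignment: the query is slid along each subject
over every placement leaving at most ``max_offset`` query bases overhanging
the subject ends, mismatches are counted over the overlap (overhanging bases
are reported as offset, not as mismatches), and placements with at most
``max_mismatch`` mismatches become hits.  No gaps are allowed.  Subjects may
be mature-length or full pre-miRNA hairpins; against a hairpin the query
simply slides along the longer sequence.

Family names are parsed from miRBase-style ids (``nve-miR-2023`` ->
``miR-2023``), and passing candidates are named ``<prefix>-miR-<family>``
when conserved or ``<prefix>-miR-temp-<rank>`` (descending plausibility
score) when novel.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import SeqRecord, from_rna

__all__ = ["ConservationHit", "match_known", "family_name", "assign_names"]


@dataclass
class ConservationHit:
    query_id: str
    subject_id: str
    offset: int          # query start relative to subject start
    overlap: int         # aligned (overlapping) length
    mismatches: int
    end_overhang: int    # query bases hanging past the subject ends
    family: str


def family_name(subject_id: str) -> str:
    """``nve-miR-2023`` -> ``miR-2023``; ids without a dash pass through."""
    parts = subject_id.split("-", 1)
    return parts[1] if len(parts) == 2 else subject_id


def match_known(query_id: str, query_seq: str, reference: list[SeqRecord],
                max_mismatch: int = 3, max_offset: int = 3) -> list[ConservationHit]:
    """Best end-gap-free placement of the query on each reference sequence.

    Returns hits sorted by (mismatches, end overhang, subject id).  An empty
    reference yields an empty result.
    """
    q = from_rna(query_seq)
    hits: list[ConservationHit] = []
    for subj in reference:
        s = from_rna(subj.seq)
        best: tuple | None = None
        for off in range(-max_offset, len(s) - len(q) + max_offset + 1):
            lo = max(0, off)
            hi = min(len(s), off + len(q))
            overlap = hi - lo
            if overlap <= 0:
                continue
            overhang = len(q) - overlap
            if overhang > max_offset:
                continue
            mm = sum(1 for i in range(lo, hi) if s[i] != q[i - off])
            key = (mm, overhang, off)
            if best is None or key < best[:3]:
                best = (mm, overhang, off, overlap)
        if best is not None and best[0] <= max_mismatch:
            mm, overhang, off, overlap = best
            hits.append(ConservationHit(
                query_id, subj.id, off, overlap, mm, overhang,
                family_name(subj.id),
            ))
    hits.sort(key=lambda h: (h.mismatches, h.end_overhang, h.subject_id))
    return hits


def assign_names(passers: list[tuple[str, float]],
                 hits_by_query: dict[str, list[ConservationHit]],
                 prefix: str = "spi") -> dict[str, str]:
    """Name the passing miRNAs.

    ``passers`` are (candidate id, plausibility score).  Conserved passers
    take their best hit's family (``spi-miR-100``); novel passers are
    numbered ``spi-miR-temp-<rank>`` by descending score.  Duplicate family
    assignments to distinct candidates are disambiguated with -1/-2 suffixes.
    Returns candidate id -> name.
    """
    names: dict[str, str] = {}
    used: dict[str, int] = {}
    novel: list[tuple[float, str]] = []
    for cid, score in passers:
        hs = hits_by_query.get(cid, [])
        if hs:
            fam = hs[0].family
            base = f"{prefix}-{fam}"
            n = used.get(base, 0)
            used[base] = n + 1
            names[cid] = base if n == 0 else f"{base}-{n + 1}"
            if n == 1:  # retroactively suffix the first holder
                first = next(k for k, v in names.items() if v == base)
                names[first] = f"{base}-1"
        else:
            novel.append((score, cid))
    novel.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, cid) in enumerate(novel, 1):
        names[cid] = f"{prefix}-miR-temp-{rank}"
    return names
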