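"""Readers and writers for the on-disk formats the pipeline touches.

Parsing is deliberately strict: every reader validates its input and raises
:class:`~coralmir.errors.FormatError` with a line number where possible, so
that malformed files fail at the boundary instead of corrupting a downstream
stage.  Sequences are normalised to upper-case DNA internally; mature miRNAs
are printed in the lower-case RNA dialect (``u`` for ``T``) only at output
time (:func:`to_rna_lower`).

Quality scores are Phred+33 (Illumina >= 1.8).  Phred+64 input is not
supported and fails loudly: any quality character below ``!`` is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .errors import CycleError, FormatError

__all__ = [
    "SeqRecord",
    "SmallRead",
    "OntologyDAG",
    "read_fasta",
    "read_fastq",
    "iter_fastq",
    "write_records",
    "parse_obo",
    "revcomp",
    "to_rna_lower",
    "from_rna",
]

_DNA_OK = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna_lower(seq: str) -> str:
    """DNA to the lower-case RNA output dialect (``ACGT`` -> ``acgu``)."""
    return seq.lower().replace("t", "u")


def from_rna(seq: str) -> str:
    """Normalise an RNA or DNA string (either case) to upper-case DNA."""
    return seq.upper().replace("U", "T")


@dataclass
class SeqRecord:
    """A named sequence (genome contig, transcript, reference miRNA...)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id {self.id!r}")
        if not self.seq:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SmallRead:
    """One sequencing read with per-base Phred quality scores."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        if any(q < 0 or q > 93 for q in self.quals):
            raise FormatError(f"read {self.id!r}: Phred score out of range 0-93")

    def __len__(self) -> int:
        return len(self.seq)


def _check_alphabet(seq: str, path: str, lineno: int) -> None:
    bad = set(seq) - _DNA_OK
    if bad:
        raise FormatError(
            f"{path}:{lineno}: illegal sequence character(s) {sorted(bad)!r}"
        )


def read_fasta(path) -> list[SeqRecord]:
    """Parse a FASTA file into a list of :class:`SeqRecord`.

    Multi-line sequences are concatenated; sequences are upper-cased.
    Raises :class:`FormatError` on an empty file, on sequence data before the
    first header, and on illegal characters (naming the line number).
    """
    path = str(path)
    records: list[SeqRecord] = []
    header: tuple[str, str] | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is not None:
            seq = "".join(chunks)
            if not seq:
                raise FormatError(f"{path}:{header_line}: record with no sequence")
            records.append(SeqRecord(header[0], seq, header[1]))

    with open(path) as fh:
        seen_any = False
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            seen_any = True
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header = (parts[0], parts[1] if len(parts) > 1 else "")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence line before first header"
                    )
                # accept the RNA dialect (u for T) and normalise to DNA
                seq = line.upper().replace("U", "T")
                _check_alphabet(seq, path, lineno)
                chunks.append(seq)
        flush()
    if not seen_any:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def iter_fastq(path) -> Iterator[SmallRead]:
    """Stream a Phred+33 FASTQ file as :class:`SmallRead` objects."""
    path = str(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"{path}: line count {len(lines)} is not divisible by 4"
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"{path}:{lineno}: expected '@' header")
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{lineno + 2}: expected '+' separator")
        rid = head[1:].split(None, 1)[0] if head[1:] else ""
        if not rid:
            raise FormatError(f"{path}:{lineno}: empty read id")
        seq = seq.upper()
        _check_alphabet(seq, path, lineno + 1)
        if len(qual) != len(seq):
            raise FormatError(
                f"{path}:{lineno + 3}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        quals = []
        for c in qual:
            q = ord(c) - 33
            if q < 0:
                raise FormatError(
                    f"{path}:{lineno + 3}: quality character {c!r} below '!' "
                    "(Phred+64 input is not supported)"
                )
            if q > 93:
                raise FormatError(f"{path}:{lineno + 3}: quality character {c!r} above '~'")
            quals.append(q)
        yield SmallRead(rid, seq, quals)


def read_fastq(path) -> list[SmallRead]:
    """Eager version of :func:`iter_fastq`."""
    return list(iter_fastq(path))


def write_records(records: Iterable[SeqRecord | SmallRead], path, dialect: str = "fasta") -> None:
    """Write records as FASTA or FASTQ (Phred+33).

    Round-trips: ``read_fasta(write_records(x))`` (resp. fastq) reproduces
    every id/description/sequence/quality field.  Writing a record without
    qualities in the fastq dialect is an error.
    """
    if dialect not in ("fasta", "fastq"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(str(path), "w") as fh:
        for rec in records:
            if dialect == "fasta":
                desc = getattr(rec, "description", "")
                head = f">{rec.id} {desc}" if desc else f">{rec.id}"
                fh.write(head + "\n")
                seq = rec.seq
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
            else:
                quals = getattr(rec, "quals", None)
                if quals is None:
                    raise FormatError(
                        f"record {rec.id!r} has no quality scores; cannot write fastq"
                    )
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n")
                fh.write("".join(chr(q + 33) for q in quals) + "\n")


class OntologyDAG:
    """An is_a ontology: acyclic graph of terms with ancestor closure.

    Edges run child -> parent.  ``ancestors(t)`` is the transitive closure of
    is_a parents, excluding ``t`` itself.
    """

    def __init__(self, names: dict[str, str], edges: Iterable[tuple[str, str]]):
        self.names = dict(names)
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for child, parent in edges:
            for t in (child, parent):
                if t not in self.names:
                    raise FormatError(f"is_a edge references unknown term {t!r}")
            g.add_edge(child, parent)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            chain = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
            raise CycleError(f"cyclic is_a chain: {chain}")
        self._g = g
        self._anc: dict[str, frozenset[str]] = {}
        self._depth: dict[str, int] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.names)

    def parents(self, term: str) -> set[str]:
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._g.predecessors(term))

    @property
    def roots(self) -> set[str]:
        return {t for t in self._g.nodes if self._g.out_degree(t) == 0}

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term`` (term itself excluded)."""
        if term not in self._anc:
            self._anc[term] = frozenset(nx.descendants(self._g, term))
        return self._anc[term]

    def depth(self, term: str) -> int:
        """Longest is_a path length from ``term`` up to a root."""
        if term not in self._depth:
            parents = self.parents(term)
            self._depth[term] = (
                0 if not parents else 1 + max(self.depth(p) for p in parents)
            )
        return self._depth[term]

    def __contains__(self, term: str) -> bool:
        return term in self.names

    def __len__(self) -> int:
        return len(self.names)


def parse_obo(path) -> OntologyDAG:
    """Parse an OBO subset (``[Term]`` stanzas: id/name/is_a/is_obsolete).

    Obsolete terms are dropped together with any edge that references them
    only if the referencing side is obsolete too; a live term whose is_a
    target is unknown (or obsolete) is an error.  A cyclic is_a chain raises
    :class:`CycleError` listing one cycle.
    """
    path = str(path)
    stanzas: list[dict] = []
    current: dict | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line == "[Term]":
                current = {"lineno": lineno, "is_a": []}
                stanzas.append(current)
                continue
            if line.startswith("[") and line.endswith("]"):
                current = None  # [Typedef] etc.
                continue
            if current is None or not line or ":" not in line:
                continue
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            key = key.strip()
            if key == "id":
                current["id"] = value
            elif key == "name":
                current["name"] = value
            elif key == "is_a":
                current["is_a"].append(value)
            elif key == "is_obsolete":
                current["obsolete"] = value.lower() == "true"

    names: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    for st in stanzas:
        if "id" not in st:
            raise FormatError(f"{path}:{st['lineno']}: [Term] stanza missing id")
        if st.get("obsolete"):
            continue
        names[st["id"]] = st.get("name", st["id"])
    for st in stanzas:
        if st.get("obsolete") or "id" not in st:
            continue
        for parent in st["is_a"]:
            edges.append((st["id"], parent))
    return OntologyDAG(names, edges)
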