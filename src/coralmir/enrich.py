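"""GO term enrichment with DAG decorrelation.

Annotations are first propagated to all is_a ancestors (annotating a term
implies its parents).  Each term is then tested for over-representation in
the study set with the one-sided Fisher/hypergeometric upper tail.  Two
scorings are produced:

* ``classic`` -- the plain per-term test;
* ``elim`` -- terms are processed level by level from the leaves upward, and
  whenever a term comes out significant (p < ``elim_cut``) its annotated
  study and background genes are removed from all of its ancestors before
  those are tested.  This decorrelates parent terms whose apparent signal is
  driven entirely by a significant child.

P values are deliberately *not* corrected for multiple testing: the tests on
a GO DAG are strongly non-independent and the decorrelation already absorbs
the local dependence, so a plain threshold (default P < 0.01) is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .errors import ConfigError, CoralmirError
from .formats import OntologyDAG

__all__ = ["AnnotationSet", "EnrichmentResult", "propagate", "fisher_p", "enrich"]


@dataclass
class AnnotationSet:
    """gene -> set of GO term ids; ``closed`` marks ancestor closure."""

    genes: dict[str, frozenset[str]]
    closed: bool = False

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.genes.values():
            out |= ts
        return out


def propagate(annotations: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Replace each gene's term set by its ancestor closure (idempotent)."""
    closed: dict[str, frozenset[str]] = {}
    for gene, terms in annotations.genes.items():
        acc: set[str] = set()
        for t in terms:
            if t not in dag:
                raise CoralmirError(
                    f"gene {gene!r} annotated to unknown term {t!r}"
                )
            acc.add(t)
            acc |= dag.ancestors(t)
        closed[gene] = frozenset(acc)
    return AnnotationSet(closed, closed=True)


def fisher_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p value, P(X >= k).

    X counts annotated genes in a draw of ``n`` from ``N`` genes of which
    ``K`` are annotated.  Computed with exact integer arithmetic and
    converted to float at the end.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ConfigError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return float(Fraction(total, denom))


@dataclass
class EnrichmentResult:
    term: str
    name: str
    k: int          # study genes annotated (classic counting)
    n: int          # study size
    K: int          # background genes annotated
    N: int          # background size
    p_classic: float
    p_elim: float
    significant: bool


def enrich(study: set[str], background: set[str], annotations: AnnotationSet,
           dag: OntologyDAG, alpha: float = 0.01, elim_cut: float | None = None,
           min_term_size: int = 1) -> list[EnrichmentResult]:
    """Test every DAG term for enrichment in the study set.

    ``annotations`` must be ancestor-closed (run :func:`propagate` first) and
    the study set must be a subset of the background.  Terms with no study
    annotation are reported with p = 1 rather than omitted, so the output is
    a total function of the DAG.  ``significant`` flags p_elim < alpha.
    """
    if not study:
        raise CoralmirError("empty study set")
    if not study <= background:
        raise CoralmirError("study set is not a subset of the background")
    if not annotations.closed:
        raise CoralmirError("annotations must be ancestor-closed; run propagate()")
    if elim_cut is None:
        elim_cut = alpha

    term_bg: dict[str, set[str]] = {t: set() for t in dag.terms}
    for gene, terms in annotations.genes.items():
        if gene not in background:
            continue
        for t in terms:
            if t in term_bg:
                term_bg[t].add(gene)
    term_study = {t: gs & study for t, gs in term_bg.items()}

    N, n = len(background), len(study)
    classic: dict[str, float] = {}
    for t in dag.terms:
        K, k = len(term_bg[t]), len(term_study[t])
        classic[t] = fisher_p(k, n, K, N) if K >= min_term_size else 1.0

    # elim: deepest levels first; significant terms strip their genes from
    # every ancestor before the ancestors are tested
    depth = {t: dag.depth(t) for t in dag.terms}
    elim_bg = {t: set(gs) for t, gs in term_bg.items()}
    elim_study = {t: set(gs) for t, gs in term_study.items()}
    p_elim: dict[str, float] = {}
    for level in sorted(set(depth.values()), reverse=True):
        level_terms = sorted(t for t, d in depth.items() if d == level)
        newly_significant = []
        for t in level_terms:
            K, k = len(elim_bg[t]), len(elim_study[t])
            k = min(k, K)
            p = fisher_p(k, n, K, N) if K >= min_term_size else 1.0
            p_elim[t] = p
            if p < elim_cut:
                newly_significant.append(t)
        for t in newly_significant:
            for anc in dag.ancestors(t):
                elim_bg[anc] -= elim_bg[t]
                elim_study[anc] -= elim_study[t]

    results = []
    for t in sorted(dag.terms):
        results.append(EnrichmentResult(
            term=t, name=dag.names[t],
            k=len(term_study[t]), n=n, K=len(term_bg[t]), N=N,
            p_classic=classic[t], p_elim=p_elim[t],
            significant=p_elim[t] < alpha,
        ))
    results.sort(key=lambda r: (r.p_elim, r.term))
    return results
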