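"""Biological Process ontology parsing and best-match semantic divergence.

The divergence score between two genes ("GO divergence") is one minus the
highest information-content similarity over all cross pairs of their directly
annotated terms.  Term-term similarity follows Lin's normalization:

    T(m, n) = 2 * ln p(x*) / (ln p(m) + ln p(n))

where ``x*`` is the shared ancestor of ``m`` and ``n`` with the smallest
annotation probability ``p`` (the most informative common ancestor), and
``p(x)`` is the probability of drawing term ``x`` or any of its descendants
from the annotation corpus.  Two terms that meet only at the root score 0;
a term scores 1 against itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from typing import IO, Iterable, Iterator

BP_NAMESPACE = "biological_process"

#: metadata recorded alongside batch scores (similarity formula is a
#: configuration choice, so outputs carry it explicitly)
SIMILARITY_METADATA = {
    "lin": "T = 2*ln p(MICA) / (ln p(m) + ln p(n))",
    "icmax": "T = ln p(MICA) / ln min(p(m), p(n))",
}


class OntologyError(ValueError):
    """Base class for ontology/annotation failures."""


class CycleError(OntologyError):
    """The parsed edge set contains a cycle."""


class OntologyFormatError(OntologyError):
    """Structurally invalid OBO/GAF content."""


class UnannotatedTermError(OntologyError):
    """p(x) requested for a term with zero annotations."""


def _as_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        if "\n" in stream:
            return iter(StringIO(stream))
        return iter(open(stream, "rt", encoding="utf-8"))
    return iter(stream)


# ---------------------------------------------------------------------------
# DAG
# ---------------------------------------------------------------------------

@dataclass
class OntologyDAG:
    """Biological Process DAG with ``is_a``/``part_of`` parent edges."""

    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]
    root: str
    alt_ids: dict[str, str] = field(default_factory=dict)
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _descendants: dict[str, frozenset[str]] | None = field(default=None, repr=False)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def canonical(self, term: str) -> str:
        """Map an alt_id to its canonical term id (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.canonical(term) in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive ancestor closure (the term itself plus all ancestors)."""
        term = self.canonical(term)
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(f"unknown term: {term}")
        closure: set[str] = {term}
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in closure:
                closure.add(t)
                stack.extend(self.parents[t])
        result = frozenset(closure)
        self._ancestors[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """Reflexive descendant closure."""
        if self._descendants is None:
            children: dict[str, set[str]] = {t: set() for t in self.parents}
            for child, ps in self.parents.items():
                for p in ps:
                    children[p].add(child)
            closures: dict[str, frozenset[str]] = {}

            def close(t: str) -> frozenset[str]:
                if t in closures:
                    return closures[t]
                acc: set[str] = {t}
                for c in children[t]:
                    acc |= close(c)
                closures[t] = frozenset(acc)
                return closures[t]

            for t in self.parents:
                close(t)
            self._descendants = closures
        return self._descendants[term]


def _check_acyclic(parents: dict[str, frozenset[str]]) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = dict.fromkeys(parents, WHITE)
    for start in parents:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, Iterator[str]]] = [(start, iter(parents[start]))]
        color[start] = GREY
        path = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in parents:
                    continue
                if color[nxt] == GREY:
                    cycle = path[path.index(nxt):] + [nxt]
                    raise CycleError("cycle in ontology: " + " -> ".join(cycle))
                if color[nxt] == WHITE:
                    color[nxt] = GREY
                    stack.append((nxt, iter(parents[nxt])))
                    path.append(nxt)
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()
                path.pop()


def parse_obo(stream: str | IO[str] | Iterable[str]) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into a BP-restricted :class:`OntologyDAG`.

    Obsolete terms are dropped, ``alt_id`` entries are mapped to canonical
    ids, and both ``is_a`` and ``relationship: part_of`` edges populate the
    parents map.  Raises :class:`OntologyFormatError` if no unique BP root
    (a BP term without parents) exists, :class:`CycleError` on cycles.
    """
    terms: dict[str, dict] = {}
    current: dict | None = None
    in_term = False
    for raw in _as_lines(stream):
        line = raw.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
            current = {"parents": set(), "alt_ids": [], "obsolete": False} if in_term else None
            continue
        if not in_term or current is None or not line or line.startswith("!"):
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        # trailing comments after '!' are permitted by the format
        value = value.split(" ! ")[0].strip()
        if key == "id":
            current["id"] = value
            terms[value] = current
        elif key == "namespace":
            current["namespace"] = value
        elif key == "is_a":
            current["parents"].add(value)
        elif key == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                current["parents"].add(parts[1])
        elif key == "alt_id":
            current["alt_ids"].append(value)
        elif key == "is_obsolete":
            current["obsolete"] = value.lower() == "true"

    bp = {
        tid: t for tid, t in terms.items()
        if not t["obsolete"] and t.get("namespace", BP_NAMESPACE) == BP_NAMESPACE
    }
    if not bp:
        raise OntologyFormatError("no biological_process terms found")
    parents = {
        tid: frozenset(p for p in t["parents"] if p in bp)
        for tid, t in bp.items()
    }
    _check_acyclic(parents)
    roots = [tid for tid, ps in parents.items() if not ps]
    if len(roots) != 1:
        raise OntologyFormatError(
            f"expected exactly one parentless BP root, found {len(roots)}: {sorted(roots)[:5]}"
        )
    alt_ids = {alt: tid for tid, t in bp.items() for alt in t["alt_ids"]}
    namespace = {tid: BP_NAMESPACE for tid in bp}
    return OntologyDAG(parents=parents, namespace=namespace, root=roots[0], alt_ids=alt_ids)


# ---------------------------------------------------------------------------
# Annotation corpus
# ---------------------------------------------------------------------------

@dataclass
class AnnotationCorpus:
    """Gene -> BP-term annotations with propagated per-term counts.

    ``term_count[t]`` is the number of annotations made to ``t`` or any
    descendant of ``t``; with row-level counting (the default) ``total``
    equals the number of deduplicated (gene, term) annotation rows, so
    ``p(root) == 1`` always holds.
    """

    gene_terms: dict[str, frozenset[str]]
    term_count: dict[str, int]
    total: int
    gene_level: bool = False
    n_skipped_terms: int = 0
    n_skipped_rows: int = 0

    @classmethod
    def from_gene_terms(
        cls,
        dag: OntologyDAG,
        gene_terms: dict[str, Iterable[str]],
        gene_level: bool = False,
        n_skipped_terms: int = 0,
        n_skipped_rows: int = 0,
    ) -> "AnnotationCorpus":
        clean = {
            g: frozenset(dag.canonical(t) for t in ts if t in dag)
            for g, ts in gene_terms.items()
        }
        clean = {g: ts for g, ts in clean.items() if ts}
        if not clean:
            raise OntologyFormatError("empty annotation corpus")
        count: dict[str, int] = {}
        if gene_level:
            for ts in clean.values():
                covered: set[str] = set()
                for t in ts:
                    covered |= dag.ancestors(t)
                for anc in covered:
                    count[anc] = count.get(anc, 0) + 1
        else:
            for ts in clean.values():
                for t in ts:
                    for anc in dag.ancestors(t):
                        count[anc] = count.get(anc, 0) + 1
        total = count[dag.root]
        return cls(
            gene_terms=clean,
            term_count=count,
            total=total,
            gene_level=gene_level,
            n_skipped_terms=n_skipped_terms,
            n_skipped_rows=n_skipped_rows,
        )


def parse_gaf(
    stream: str | IO[str] | Iterable[str],
    dag: OntologyDAG,
    gene_level: bool = False,
) -> AnnotationCorpus:
    """Parse GAF 2.x annotations restricted to aspect P, evidence != IEA.

    Rows whose term id is absent from the DAG (after alt_id mapping), and
    NOT-qualified rows, are skipped and counted.  Duplicate (gene, term)
    rows count once.  Raises :class:`OntologyFormatError` when nothing
    qualifying remains.
    """
    gene_terms: dict[str, set[str]] = {}
    n_skipped_terms = 0
    n_skipped_rows = 0
    for raw in _as_lines(stream):
        if not raw.strip() or raw.startswith("!"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 9:
            n_skipped_rows += 1
            continue
        gene, qualifier, term, evidence, aspect = cols[1], cols[3], cols[4], cols[6], cols[8]
        if aspect != "P" or evidence == "IEA":
            n_skipped_rows += 1
            continue
        if "NOT" in qualifier.split("|"):
            n_skipped_rows += 1
            continue
        if term not in dag:
            n_skipped_terms += 1
            continue
        gene_terms.setdefault(gene, set()).add(dag.canonical(term))
    if not gene_terms:
        raise OntologyFormatError("no qualifying (aspect P, non-IEA) annotations")
    return AnnotationCorpus.from_gene_terms(
        dag, gene_terms, gene_level=gene_level,
        n_skipped_terms=n_skipped_terms, n_skipped_rows=n_skipped_rows,
    )


def term_probability(corpus: AnnotationCorpus, term: str) -> float:
    """p(term) = count of annotations to the term or any descendant / total."""
    count = corpus.term_count.get(term, 0)
    if count < 1:
        raise UnannotatedTermError(f"term {term} has no annotations; p undefined")
    return count / corpus.total


# ---------------------------------------------------------------------------
# Similarity and divergence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermPairScore:
    term_a: str
    term_b: str
    similarity: float
    mica: str


def term_similarity(
    dag: OntologyDAG,
    corpus: AnnotationCorpus,
    m: str,
    n: str,
    method: str = "lin",
) -> TermPairScore:
    """Information-content similarity between two annotated BP terms.

    The shared-ancestor set is reflexive: when one term subsumes the other,
    the subsumed term itself is a candidate MICA.  ``method`` selects the
    normalization (``"lin"`` default, ``"icmax"`` alternative); both give 0
    at the root and 1 for a term against itself.
    """
    if method not in SIMILARITY_METADATA:
        raise ValueError(f"unknown similarity method: {method}")
    m, n = dag.canonical(m), dag.canonical(n)
    for t in (m, n):
        if t not in dag:
            raise KeyError(f"unknown term: {t}")
    if dag.namespace[m] != dag.namespace[n]:
        raise OntologyError(f"terms {m}, {n} are from different namespaces")
    p_m = term_probability(corpus, m)
    p_n = term_probability(corpus, n)
    shared = dag.ancestors(m) & dag.ancestors(n)
    # every shared ancestor of annotated terms carries annotations
    mica = min(shared, key=lambda t: (corpus.term_count[t], t))
    p_star = term_probability(corpus, mica)
    if p_star >= 1.0:
        return TermPairScore(m, n, 0.0, mica)
    if method == "lin":
        sim = 2.0 * math.log(p_star) / (math.log(p_m) + math.log(p_n))
    else:  # icmax
        sim = math.log(p_star) / math.log(min(p_m, p_n))
    sim = min(1.0, max(0.0, sim))
    return TermPairScore(m, n, sim, mica)


@dataclass(frozen=True)
class GoDivResult:
    gene_a: str
    gene_b: str
    score: float | None
    status: str  # "ok" or "unannotated"
    best_term_a: str | None = None
    best_term_b: str | None = None
    mica: str | None = None


def go_div(
    dag: OntologyDAG,
    corpus: AnnotationCorpus,
    gene_a: str,
    gene_b: str,
    method: str = "lin",
) -> GoDivResult:
    """Best-match divergence: 1 - max term-term similarity over cross pairs.

    Genes lacking a qualifying BP annotation yield ``status="unannotated"``
    with ``score=None`` rather than a silent 0 or 1.
    """
    terms_a = corpus.gene_terms.get(gene_a, frozenset())
    terms_b = corpus.gene_terms.get(gene_b, frozenset())
    if not terms_a or not terms_b:
        return GoDivResult(gene_a, gene_b, None, "unannotated")
    best: TermPairScore | None = None
    for ta in sorted(terms_a):
        for tb in sorted(terms_b):
            s = term_similarity(dag, corpus, ta, tb, method=method)
            if best is None or s.similarity > best.similarity:
                best = s
    assert best is not None
    return GoDivResult(
        gene_a, gene_b, 1.0 - best.similarity, "ok",
        best_term_a=best.term_a, best_term_b=best.term_b, mica=best.mica,
    )
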