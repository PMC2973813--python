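"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from parabuffer import ontology as onto

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: mid
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
is_a: GO:0000002
"""

# root <- A, B ; C is_a A and part_of B ; D is_a C
FIVE_TERM_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: B
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: C
namespace: biological_process
is_a: GO:0000002
relationship: part_of GO:0000003

[Term]
id: GO:0000005
name: D
namespace: biological_process
is_a: GO:0000004
"""


def gaf_row(gene: str, term: str, evidence: str = "IDA", aspect: str = "P",
            qualifier: str = "involved_in") -> str:
    cols = ["DB", gene, gene, qualifier, term, "PMID:1", evidence, "", aspect,
            gene, "", "protein", "taxon:4932", "20090101", "DB", "", ""]
    return "\t".join(cols)


def make_gaf(rows: list[str]) -> str:
    return "!gaf-version: 2.2\n" + "\n".join(rows) + "\n"


@pytest.fixture
def chain_dag():
    return onto.parse_obo(CHAIN_OBO)


@pytest.fixture
def five_term_dag():
    return onto.parse_obo(FIVE_TERM_OBO)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately avoid the implementation's code paths)
# ---------------------------------------------------------------------------

def oracle_descendants(dag, term) -> set[str]:
    """Reflexive descendant closure by BFS over reversed parent edges."""
    children: dict[str, set[str]] = {t: set() for t in dag.parents}
    for child, ps in dag.parents.items():
        for p in ps:
            children[p].add(child)
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for c in children[t]:
            if c not in out:
                out.add(c)
                frontier.append(c)
    return out


def oracle_ancestors(dag, term) -> set[str]:
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in dag.parents[t]:
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def oracle_term_counts(dag, gene_terms) -> tuple[dict[str, int], int]:
    """Per-term annotation-row counts by exhaustive descendant enumeration."""
    rows = {(g, t) for g, ts in gene_terms.items() for t in ts}
    counts = {}
    for t in dag.parents:
        desc = oracle_descendants(dag, t)
        counts[t] = sum(1 for (_, tt) in rows if tt in desc)
    return counts, len(rows)


def oracle_lin_similarity(dag, gene_terms, m, n) -> float:
    """Lin similarity from first principles: shared reflexive ancestors,
    probabilities from the row-count oracle, max-IC ancestor."""
    import math

    counts, total = oracle_term_counts(dag, gene_terms)
    shared = oracle_ancestors(dag, m) & oracle_ancestors(dag, n)
    p_star = min(counts[t] / total for t in shared)
    if p_star >= 1.0:
        return 0.0
    p_m, p_n = counts[m] / total, counts[n] / total
    return 2 * math.log(p_star) / (math.log(p_m) + math.log(p_n))


def oracle_go_div(dag, gene_terms, gene_a, gene_b) -> float:
    sims = [
        oracle_lin_similarity(dag, gene_terms, ta, tb)
        for ta in gene_terms[gene_a]
        for tb in gene_terms[gene_b]
    ]
    return 1.0 - max(sims)


def oracle_auc(scores, labels) -> float:
    """Exhaustive positive/negative pair counting with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def oracle_partial_correlation(x, y, z) -> float:
    """Correlate the residuals of least-squares fits of x~z and y~z."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    A = np.column_stack([np.ones_like(z), z])
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_chi2_2x2(a1, n1, a2, n2) -> float:
    """Textbook sum((O-E)^2/E) over the 2x2 table."""
    obs = np.array([[a1, n1 - a1], [a2, n2 - a2]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    exp = rows * cols / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())
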