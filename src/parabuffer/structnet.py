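"""Structure and network properties of buffering pairs.

Secondary-structure strings over {H, E, C} become 9-entry transition
probability vectors; dissimilarity between two vectors is the Jensen-Shannon
divergence of their pseudocounted, renormalized flattenings (bounded,
symmetric, zero iff equal).  PPI and complex comparisons count shared
interaction partners and complex co-membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import IO, Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

SS_STATES = ("H", "E", "C")
#: extra PSIPRED/DSSP codes folded into the 3-state alphabet
SS_CODE_MAP = {"G": "H", "I": "H", "B": "E", "T": "C", "S": "C", "-": "C"}
PSEUDOCOUNT = 1e-6


class StructNetError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

@dataclass
class SsTransitionVector:
    """3x3 transition probabilities over (H, E, C) x (H, E, C).

    Rows for source states with at least one outgoing transition sum to 1;
    unvisited source states are zero rows flagged in ``visited``.
    """

    probs: np.ndarray  # shape (3, 3)
    counts: np.ndarray  # raw bigram counts
    visited: np.ndarray  # bool per source state

    def flat(self) -> np.ndarray:
        return self.probs.reshape(9)


def _normalize_ss(ss: str) -> str:
    out = []
    n_mapped = 0
    for ch in ss.upper():
        if ch in SS_STATES:
            out.append(ch)
        elif ch in SS_CODE_MAP:
            out.append(SS_CODE_MAP[ch])
            n_mapped += 1
        else:
            raise StructNetError(f"unknown secondary-structure code: {ch!r}")
    if n_mapped:
        logger.info("mapped %d non-canonical structure codes", n_mapped)
    return "".join(out)


def ss_transition_vector(ss: str) -> SsTransitionVector:
    """Estimate bigram transition probabilities from a structure string."""
    ss = _normalize_ss(ss)
    if len(ss) < 2:
        raise StructNetError("structure string shorter than 2 states")
    index = {s: i for i, s in enumerate(SS_STATES)}
    counts = np.zeros((3, 3))
    for a, b in zip(ss, ss[1:]):
        counts[index[a], index[b]] += 1
    row_sums = counts.sum(axis=1)
    visited = row_sums > 0
    probs = np.zeros((3, 3))
    probs[visited] = counts[visited] / row_sums[visited, None]
    return SsTransitionVector(probs=probs, counts=counts, visited=visited)


def structure_discrepancy(a: SsTransitionVector, b: SsTransitionVector) -> float:
    """Jensen-Shannon divergence (natural log) between the two 9-entry
    vectors after pseudocount renormalization; 0 iff equal, symmetric."""
    p = a.flat() + PSEUDOCOUNT
    q = b.flat() + PSEUDOCOUNT
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    kl_pm = float(np.sum(p * np.log(p / m)))
    kl_qm = float(np.sum(q * np.log(q / m)))
    return max(0.0, 0.5 * kl_pm + 0.5 * kl_qm)


def read_ss(stream: str | IO[str] | Iterable[str]) -> dict[str, str]:
    """Read structure strings: fasta-like 2-line records (``>id`` then the
    string, possibly wrapped) or horizontal PSIPRED ``Pred:`` lines."""
    if isinstance(stream, str):
        lines = StringIO(stream) if "\n" in stream else open(stream, "rt", encoding="utf-8")
    else:
        lines = stream
    out: dict[str, str] = {}
    current: str | None = None
    pred_chunks: list[str] = []
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            out[current] = ""
        elif line.startswith("Pred:"):
            pred_chunks.append(line.split(":", 1)[1].strip())
        elif current is not None:
            out[current] += line
    if pred_chunks and not out:
        out["psipred"] = "".join(pred_chunks)
    if not out:
        raise StructNetError("no secondary-structure records found")
    return out


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

class PpiNetwork:
    """Undirected protein-interaction adjacency; self-loops dropped."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        self._adj: dict[str, set[str]] = {}
        for a, b in edges:
            self.add_edge(a, b)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            return
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def n_edges(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def neighbors(self, gene: str) -> set[str]:
        return set(self._adj.get(gene, set()))


def read_ppi(stream: str | IO[str] | Iterable[str]) -> PpiNetwork:
    """Read a 2-column TSV edge list (header optional)."""
    if isinstance(stream, str):
        lines = StringIO(stream) if "\n" in stream else open(stream, "rt", encoding="utf-8")
    else:
        lines = stream
    net = PpiNetwork()
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise StructNetError(f"malformed PPI line: {line!r}")
        if cols[0] in ("gene_a", "protein_a"):
            continue
        net.add_edge(cols[0], cols[1])
    if len(net) == 0:
        raise StructNetError("empty PPI network")
    return net


def has_shared_partner(gene_a: str, gene_b: str, ppi: PpiNetwork) -> bool:
    """True when a third protein interacts with both genes; the pair's own
    A-B edge does not count."""
    shared = (ppi.neighbors(gene_a) - {gene_a, gene_b}) & (
        ppi.neighbors(gene_b) - {gene_a, gene_b}
    )
    return bool(shared)


def chi2_2x2(a1: int, n1: int, a2: int, n2: int, correction: bool = False) -> tuple[float, float]:
    """Chi-square test of independence on the 2x2 table
    [[a1, n1-a1], [a2, n2-a2]]; df = 1, no continuity correction by default."""
    table = np.array([[a1, n1 - a1], [a2, n2 - a2]])
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def shared_partner_comparison(
    group1: Sequence[tuple[str, str]],
    group2: Sequence[tuple[str, str]],
    ppi: PpiNetwork,
    correction: bool = False,
) -> dict:
    """Compare the shared-partner fractions of two pair groups.

    Pairs whose genes are not both in the network are excluded and counted.
    Returns fractions, the chi-square statistic/p (df=1), and exclusions.
    """

    def resolve(group):
        shared = 0
        used = 0
        excluded = 0
        for a, b in group:
            if a not in ppi or b not in ppi:
                excluded += 1
                continue
            used += 1
            if has_shared_partner(a, b, ppi):
                shared += 1
        return shared, used, excluded

    s1, n1, e1 = resolve(group1)
    s2, n2, e2 = resolve(group2)
    if n1 == 0 or n2 == 0:
        raise StructNetError("a group is empty after network resolution")
    chi2, p = chi2_2x2(s1, n1, s2, n2, correction=correction)
    return {
        "frac1": s1 / n1, "frac2": s2 / n2,
        "n1": n1, "n2": n2,
        "shared1": s1, "shared2": s2,
        "excluded1": e1, "excluded2": e2,
        "chi2": chi2, "p": p,
    }


# ---------------------------------------------------------------------------
# Protein complexes
# ---------------------------------------------------------------------------

class ComplexCatalog:
    """Named gene sets; each complex needs at least 2 members."""

    def __init__(self, complexes: dict[str, Iterable[str]]):
        self.complexes = {name: frozenset(members) for name, members in complexes.items()}
        for name, members in self.complexes.items():
            if len(members) < 2:
                raise StructNetError(f"complex {name} has fewer than 2 members")
        if not self.complexes:
            raise StructNetError("empty complex catalog")
        self._membership: dict[str, set[str]] = {}
        for name, members in self.complexes.items():
            for g in members:
                self._membership.setdefault(g, set()).add(name)

    def memberships(self, gene: str) -> set[str]:
        return set(self._membership.get(gene, set()))


def read_complexes(stream: str | IO[str] | Iterable[str]) -> ComplexCatalog:
    """Read a TSV of (complex_id, gene) rows (header optional)."""
    if isinstance(stream, str):
        lines = StringIO(stream) if "\n" in stream else open(stream, "rt", encoding="utf-8")
    else:
        lines = stream
    complexes: dict[str, set[str]] = {}
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("complex_id"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise StructNetError(f"malformed complex line: {line!r}")
        complexes.setdefault(cols[0], set()).add(cols[1])
    return ComplexCatalog(complexes)


def complex_cocluster_fraction(
    pairs: Sequence[tuple[str, str]], catalog: ComplexCatalog
) -> float:
    """Fraction of pairs whose genes share at least one complex."""
    if not pairs:
        raise StructNetError("no pairs supplied")
    n_co = sum(
        1 for a, b in pairs if catalog.memberships(a) & catalog.memberships(b)
    )
    return n_co / len(pairs)
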