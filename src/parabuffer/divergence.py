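"""Sequence and expression divergence between paralogs.

Ka/Ks uses the Nei-Gojobori (1986) pathway-counting estimator with the
Jukes-Cantor multiple-hit correction; this is a transparent stand-in for a
likelihood codon model, and a reader for precomputed Ka/Ks tables takes
precedence when such a table is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from itertools import permutations
from typing import IO, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = "ACGT"

# standard genetic code, stops as '*'
_BASES = "TCAG"
GENETIC_CODE: dict[str, str] = {}
_aa = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _c1 in enumerate(_BASES):
    for _j, _c2 in enumerate(_BASES):
        for _k, _c3 in enumerate(_BASES):
            GENETIC_CODE[_c1 + _c2 + _c3] = _aa[16 * _i + 4 * _j + _k]
STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")

SATURATION_KS = 2.0  # Ks above this is treated as saturated downstream


class DivergenceError(ValueError):
    pass


class UndefinedDivergenceError(DivergenceError):
    """Raised when a divergence statistic is undefined (e.g. zero variance)."""


def translate(codon: str) -> str:
    return GENETIC_CODE[codon.upper()]


@dataclass
class CodonAlignment:
    """Pair of aligned coding sequences; gaps allowed in matched columns."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise DivergenceError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise DivergenceError("alignment length not divisible by 3")

    def comparable_codons(self) -> list[tuple[str, str]]:
        """Codon columns with no gap in either sequence and no stop codon."""
        out = []
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i:i + 3], self.seq_b[i:i + 3]
            if "-" in ca or "-" in cb:
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                raise DivergenceError(f"in-frame stop codon at position {i}")
            out.append((ca, cb))
        return out


@dataclass
class DivergenceEstimate:
    ka: float | None
    ks: float | None
    identity: float | None = None
    saturated: bool = False
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0


_syn_fraction_cache: dict[str, float] = {}


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3); mutations to stop
    codons count as nonsynonymous."""
    cached = _syn_fraction_cache.get(codon)
    if cached is not None:
        return cached
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    _syn_fraction_cache[codon] = s
    return s


_path_cache: dict[tuple[str, str], tuple[float, float]] = {}


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts between two codons,
    enumerating all mutational pathways; pathways passing through a stop
    codon are excluded (all pathways used as fallback)."""
    key = (ca, cb) if ca <= cb else (cb, ca)
    cached = _path_cache.get(key)
    if cached is not None:
        return cached
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        _path_cache[key] = (0.0, 0.0)
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = ca
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != cb:
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o) for o in permutations(diff_pos)) if r is not None]
    if not results:
        results = []
        for order in permutations(diff_pos):
            cur = ca
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    _path_cache[key] = (sd, nd)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when the proportion is at/beyond saturation."""
    if p < 0:
        raise DivergenceError("negative difference proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ka_ks_ng86(aln: CodonAlignment) -> DivergenceEstimate:
    """NG86 Ka/Ks with Jukes-Cantor correction.

    Gap-containing codon columns are dropped.  Proportions at or beyond the
    JC limit (p >= 3/4), or corrected Ks above 2, set the saturated flag;
    an unestimable rate is reported as None, never clamped.
    """
    codons = aln.comparable_codons()
    if not codons:
        raise DivergenceError("no comparable (gap-free) codons")
    s_sites_a = sum(_syn_fraction(ca) for ca, _ in codons)
    s_sites_b = sum(_syn_fraction(cb) for _, cb in codons)
    S = 0.5 * (s_sites_a + s_sites_b)
    N = 3.0 * len(codons) - S
    sd = nd = 0.0
    for ca, cb in codons:
        d = _pathway_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    if S <= 0 or N <= 0:
        raise DivergenceError("degenerate site counts")
    ks = jukes_cantor(sd / S)
    ka = jukes_cantor(nd / N)
    saturated = ks is None or ks > SATURATION_KS
    return DivergenceEstimate(
        ka=ka, ks=ks, saturated=saturated,
        syn_sites=S, nonsyn_sites=N, syn_diffs=sd, nonsyn_diffs=nd,
    )


def protein_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical non-gap matched positions over aligned columns
    carrying at least one residue."""
    if len(seq_a) != len(seq_b):
        raise DivergenceError("aligned protein sequences differ in length")
    n_cols = 0
    n_match = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == "-" and b == "-":
            continue
        n_cols += 1
        if a == b and a != "-":
            n_match += 1
    if n_cols == 0:
        raise DivergenceError("empty alignment")
    return n_match / n_cols


def expression_divergence(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """1 - Pearson correlation of expression profiles; in [0, 2].

    Raises :class:`UndefinedDivergenceError` for zero-variance profiles.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise DivergenceError("profiles differ in length")
    if len(a) < 3:
        raise DivergenceError("need at least 3 shared conditions")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DivergenceError("non-finite expression values")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedDivergenceError("zero-variance expression profile")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def read_kaks_table(stream: str | IO[str]) -> dict[str, tuple[float, float]]:
    """Read a precomputed Ka/Ks table (pair_id, ka, ks); takes precedence
    over the NG86 estimator when supplied."""
    if isinstance(stream, str) and "\n" in stream:
        stream = StringIO(stream)
    df = pd.read_csv(stream, sep="\t")
    missing = {"pair_id", "ka", "ks"} - set(df.columns)
    if missing:
        raise DivergenceError(f"missing columns: {sorted(missing)}")
    return {str(r.pair_id): (float(r.ka), float(r.ks)) for r in df.itertuples(index=False)}
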