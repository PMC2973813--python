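"""Synthetic inputs for every pipeline stage.

The generator plants the statistical structure the downstream analysis is
designed to detect: a background fraction of random assayed pairs with
negative interaction scores, duplicate pairs with an excess of significant
negative scores whose magnitude decays linearly with Ks, annotation sets
whose best-match specificity tracks buffering, codon sequences mutated to
planted Ka/Ks, correlated expression profiles, and PPI/complex fixtures
with planted sharing among buffering pairs.  Everything is deterministic
under the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import asdict, dataclass, field
import numpy as np

from .divergence import GENETIC_CODE, NUCLEOTIDES, STOP_CODONS, _syn_fraction
from .interactions import InteractionRecord, InteractionTable
from .ontology import AnnotationCorpus, OntologyDAG
from .records import PairRecord

_NON_STOP_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Knobs for the synthetic universe; defaults mirror the analyzed study
    population (pair counts, buffering rates, background negative rates,
    neutral slope, Ks mixture, condition count)."""

    seed: int = 0
    # ontology
    n_ontology_terms: int = 60
    dag_branching: int = 3
    n_genes: int = 150  # background annotated genes
    # pair universe
    n_wgd_pairs: int = 266
    n_ssd_pairs: int = 228
    buffering_rate_wgd: float = 105 / 266
    buffering_rate_ssd: float = 42 / 228
    # interaction background
    background_negative_rate: float = 0.07
    duplicate_background_negative_rate: float = 0.066
    n_background_pairs: int = 6000
    n_duplicate_cross_pairs: int = 4000
    background_score_scale: float = 0.0877  # E|score| ~ 0.07
    # neutral decay of buffering strength with Ks
    neutral_slope: float = 0.41
    neutral_intercept: float = 0.8
    neutral_noise_sd: float = 0.05
    # Ks structure
    ssd_recent_fraction: float = 10 / 42  # buffering SSD with Ks <= 2
    ks_left_mode: float = 0.18
    ks_left_sd: float = 0.05
    ks_right_low: float = 2.2
    ks_right_high: float = 4.0
    ks_recent_uniform: bool = False  # U(0.05, 1.6) instead of the left mode
    nonbuffering_ssd_ancient_fraction: float = 163 / 186
    # strengths for selection-stabilized (ancient) buffering pairs
    wgd_strength_mean: float = -0.42
    wgd_strength_sd: float = 0.15
    ssd_ancient_strength_mean: float = -0.20
    ssd_ancient_strength_sd: float = 0.12
    # feature artifacts
    n_expression_conditions: int = 549
    n_codons: int = 300
    ss_length: int = 120
    # planted network/complex rates (buffering vs non-buffering pairs)
    shared_partner_rate_buffering: float = 0.62
    shared_partner_rate_nonbuffering: float = 0.40
    cocluster_rate_buffering: float = 0.18
    cocluster_rate_nonbuffering: float = 0.065
    # artifact toggles (heavier stages can be skipped)
    with_sequences: bool = True
    with_expression: bool = True
    with_structures: bool = True
    with_network: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise SynthConfigError("seed is mandatory")
        rates = {
            "buffering_rate_wgd": self.buffering_rate_wgd,
            "buffering_rate_ssd": self.buffering_rate_ssd,
            "background_negative_rate": self.background_negative_rate,
            "duplicate_background_negative_rate": self.duplicate_background_negative_rate,
            "ssd_recent_fraction": self.ssd_recent_fraction,
            "nonbuffering_ssd_ancient_fraction": self.nonbuffering_ssd_ancient_fraction,
            "shared_partner_rate_buffering": self.shared_partner_rate_buffering,
            "shared_partner_rate_nonbuffering": self.shared_partner_rate_nonbuffering,
            "cocluster_rate_buffering": self.cocluster_rate_buffering,
            "cocluster_rate_nonbuffering": self.cocluster_rate_nonbuffering,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise SynthConfigError(f"{name}={value} outside [0, 1]")
        if self.ks_left_mode <= 0 or self.ks_right_low <= 0:
            raise SynthConfigError("Ks modes must be positive")
        if self.n_ontology_terms < 10:
            raise SynthConfigError("need at least 10 ontology terms")


def neutral_recovery_config(seed: int = 0) -> SynthConfig:
    """Config for slope/partial-correlation recovery: 50 buffering SSD
    pairs, all with Ks <= 2 spread uniformly, strength following the
    planted neutral line with sd-0.05 noise."""
    return SynthConfig(
        seed=seed,
        n_wgd_pairs=0,
        n_ssd_pairs=50,
        buffering_rate_ssd=1.0,
        ssd_recent_fraction=1.0,
        ks_recent_uniform=True,
        n_background_pairs=0,
        n_duplicate_cross_pairs=0,
        with_sequences=False,
        with_expression=False,
        with_structures=False,
        with_network=False,
    )


# ---------------------------------------------------------------------------
# Ontology + annotations
# ---------------------------------------------------------------------------

def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate_ontology(config: SynthConfig) -> tuple[OntologyDAG, dict[str, set[str]]]:
    """Random rooted DAG plus depth-weighted background-gene annotations.

    Each non-root term gets 1-2 parents drawn from shallower levels, so the
    graph is acyclic with every term reaching the root.  Returns the DAG and
    the background gene->terms map (build a corpus after adding pair genes).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_ontology_terms
    levels: list[list[str]] = [[_term_id(1)]]
    parents: dict[str, set[str]] = {_term_id(1): set()}
    next_id = 2
    while sum(len(lv) for lv in levels) < n:
        prev = levels[-1]
        size = min(
            max(2, len(prev) * config.dag_branching),
            n - sum(len(lv) for lv in levels),
        )
        level: list[str] = []
        shallower = [t for lv in levels for t in lv]
        for _ in range(size):
            tid = _term_id(next_id)
            next_id += 1
            n_parents = 1 + int(rng.random() < 0.3)
            # primary parent from the immediately shallower level keeps the
            # hierarchy deep; an occasional extra parent makes it a DAG
            chosen = {prev[int(rng.integers(len(prev)))]}
            if n_parents == 2 and len(shallower) > 1:
                chosen.add(shallower[int(rng.integers(len(shallower)))])
            chosen.discard(tid)
            parents[tid] = chosen
            level.append(tid)
        levels.append(level)
    dag = OntologyDAG(
        parents={t: frozenset(ps) for t, ps in parents.items()},
        namespace={t: "biological_process" for t in parents},
        root=_term_id(1),
    )
    # depth-weighted annotation of background genes
    all_terms = [t for lv in levels for t in lv]
    depth = {t: d for d, lv in enumerate(levels) for t in lv}
    weights = np.array([1.0 + depth[t] for t in all_terms])
    weights /= weights.sum()
    gene_terms: dict[str, set[str]] = {}
    for g in range(config.n_genes):
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(all_terms), size=k, replace=False, p=weights)
        gene_terms[f"BG{g:04d}"] = {all_terms[i] for i in picks}
    return dag, gene_terms


def _dag_levels(dag: OntologyDAG) -> dict[str, int]:
    levels = {dag.root: 0}
    pending = [t for t in dag.terms if t != dag.root]
    while pending:
        progressed = False
        rest = []
        for t in pending:
            ps = dag.parents[t]
            if all(p in levels for p in ps):
                levels[t] = 1 + max(levels[p] for p in ps)
                progressed = True
            else:
                rest.append(t)
        pending = rest
        if not progressed:
            raise SynthConfigError("unreachable terms in generated DAG")
    return levels


# ---------------------------------------------------------------------------
# Interaction backgrounds
# ---------------------------------------------------------------------------

def _background_scores(rng, n: int, negative_rate: float, scale: float) -> np.ndarray:
    """Scores with an exact planted count of negatives."""
    n_neg = round(n * negative_rate)
    mags = np.abs(rng.normal(0.0, scale, size=n)) + 1e-6
    signs = np.ones(n)
    signs[:n_neg] = -1.0
    rng.shuffle(signs)
    return signs * mags


def generate_background_table(
    n_pairs: int,
    negative_rate: float,
    seed: int = 0,
    scale: float = 0.0877,
) -> InteractionTable:
    """Genome-scale background: random pairs, an exact ``negative_rate``
    fraction carrying negative scores."""
    rng = np.random.default_rng(seed)
    scores = _background_scores(rng, n_pairs, negative_rate, scale)
    records = [
        InteractionRecord(f"RA{i:06d}", f"RB{i:06d}", float(scores[i]), float(rng.uniform()))
        for i in range(n_pairs)
    ]
    return InteractionTable(records)


def generate_duplicate_shuffle_fixture(
    n_genes: int,
    negative_rate: float,
    seed: int = 0,
    scale: float = 0.0877,
) -> tuple[list[str], InteractionTable]:
    """All-pairs table over a duplicate-gene universe with an exact planted
    negative fraction, for exercising the re-pairing null."""
    rng = np.random.default_rng(seed)
    genes = [f"DG{i:04d}" for i in range(n_genes)]
    pairs = [(genes[i], genes[j]) for i in range(n_genes) for j in range(i + 1, n_genes)]
    scores = _background_scores(rng, len(pairs), negative_rate, scale)
    records = [
        InteractionRecord(a, b, float(s), float(rng.uniform()))
        for (a, b), s in zip(pairs, scores)
    ]
    return genes, InteractionTable(records)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def random_cds(rng, n_codons: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _single_nt_changes(codon: str, synonymous: bool) -> list[str]:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            if (GENETIC_CODE[mut] == aa) == synonymous:
                out.append(mut)
    return out


def mutate_cds(rng, seq: str, ks: float, ka: float) -> str:
    """Apply planted synonymous/nonsynonymous substitution loads.

    Event counts are Ks x (synonymous sites) and Ka x (nonsynonymous sites)
    of the starting sequence; each event rewrites one codon via a random
    qualifying single-nucleotide change.  Multiple hits arise naturally and
    are what the Jukes-Cantor correction later unwinds.
    """
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    S = sum(_syn_fraction(c) for c in codons)
    N = 3.0 * len(codons) - S
    events = ["s"] * round(ks * S) + ["n"] * round(ka * N)
    rng.shuffle(events)
    # a codon only ever accumulates events of one kind: mixed hits would be
    # misattributed by downstream pathway averaging and are not needed for
    # the planted loads
    kind_mark: dict[int, str] = {}
    for kind in events:
        for _ in range(100):
            i = int(rng.integers(len(codons)))
            if kind_mark.get(i, kind) != kind:
                continue
            options = _single_nt_changes(codons[i], synonymous=(kind == "s"))
            if not options:
                continue
            codons[i] = options[int(rng.integers(len(options)))]
            kind_mark[i] = kind
            break
    return "".join(codons)


# ---------------------------------------------------------------------------
# Classification fixture
# ---------------------------------------------------------------------------

def generate_classification_fixture(n: int, seed: int = 0, shuffle_labels: bool = False):
    """Feature vectors whose buffering probability declines logistically
    with the GO divergence; the other features are noisy correlates of it
    carrying no independent signal."""
    from .predict import FeatureVector

    rng = np.random.default_rng(seed)
    go = rng.uniform(0.0, 1.0, size=n)
    prob = 1.0 / (1.0 + np.exp(6.0 * (go - 0.45)))
    labels = rng.uniform(size=n) < prob
    if labels.all() or not labels.any():  # pragma: no cover - vanishingly rare
        labels[0] = not labels[0]
    ka = np.clip(0.05 + 0.2 * go + rng.normal(0, 0.1, n), 1e-3, None)
    identity = np.clip(0.85 - 0.4 * go + rng.normal(0, 0.15, n), 0.0, 1.0)
    expr = np.clip(0.3 + 0.8 * go + rng.normal(0, 0.3, n), 0.0, 2.0)
    if shuffle_labels:
        labels = rng.permutation(labels)
    return [
        FeatureVector(
            f"CF{i:04d}",
            np.array([ka[i], identity[i], expr[i], go[i]]),
            bool(labels[i]),
        )
        for i in range(n)
    ]


def generate_ks_mixture(
    n: int,
    seed: int = 0,
    left: tuple[float, float] = (0.18, 0.05),
    right: tuple[float, float] = (3.0, 0.5),
    weight_left: float = 0.5,
) -> np.ndarray:
    """Two-component Ks mixture for density/bimodality checks."""
    rng = np.random.default_rng(seed)
    n_left = round(n * weight_left)
    vals = np.concatenate([
        rng.normal(left[0], left[1], size=n_left),
        rng.normal(right[0], right[1], size=n - n_left),
    ])
    return np.abs(vals)


# ---------------------------------------------------------------------------
# The full bundle
# ---------------------------------------------------------------------------

@dataclass
class SynthBundle:
    config: SynthConfig
    dag: OntologyDAG
    corpus: AnnotationCorpus
    gene_terms: dict[str, set[str]]
    pairs: list[PairRecord]
    interactions: InteractionTable
    duplicate_genes: list[str]
    sequences: dict[str, str] = field(default_factory=dict)  # gene -> aligned CDS
    expression: dict[str, np.ndarray] = field(default_factory=dict)
    ss: dict[str, str] = field(default_factory=dict)
    ppi_edges: list[tuple[str, str]] = field(default_factory=list)
    complexes: dict[str, set[str]] = field(default_factory=dict)

    def pairs_by_class(self, pair_class: str) -> list[PairRecord]:
        return [p for p in self.pairs if p.pair_class == pair_class]


def _exact_flags(rng, n: int, rate: float) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[: round(n * rate)] = True
    rng.shuffle(flags)
    return flags


def generate_pairs(
    config: SynthConfig,
    dag: OntologyDAG,
    gene_terms: dict[str, set[str]],
) -> SynthBundle:
    """Generate the duplicate-pair universe and all per-pair artifacts."""
    rng = np.random.default_rng(config.seed + 1)
    levels = _dag_levels(dag)
    children: dict[str, list[str]] = {t: [] for t in dag.terms}
    for child, ps in dag.parents.items():
        for p in ps:
            children[p].append(child)
    max_level = max(levels.values())
    deep_anchors = sorted(
        t for t in dag.terms if len(children[t]) >= 2 and levels[t] >= max(1, max_level - 2)
    )
    shallow_anchors = sorted(
        t for t in dag.terms if len(children[t]) >= 2 and levels[t] <= 1
    )
    if not deep_anchors:
        deep_anchors = sorted(t for t in dag.terms if len(children[t]) >= 2)
    if not shallow_anchors:
        shallow_anchors = [dag.root]
    all_terms = sorted(dag.terms)

    pairs: list[PairRecord] = []
    gene_terms = {g: set(ts) for g, ts in gene_terms.items()}

    def make_class(prefix: str, n_pairs: int, buffering_rate: float, is_ssd: bool):
        flags = _exact_flags(rng, n_pairs, buffering_rate)
        buf_idx = np.where(flags)[0]
        nonbuf_idx = np.where(~flags)[0]
        # which buffering pairs are "recent" (Ks <= 2)
        recent = np.zeros(n_pairs, dtype=bool)
        if is_ssd and len(buf_idx):
            r = _exact_flags(rng, len(buf_idx), config.ssd_recent_fraction)
            recent[buf_idx[r]] = True
        # which non-buffering pairs are ancient
        ancient_nonbuf = np.zeros(n_pairs, dtype=bool)
        if len(nonbuf_idx):
            frac = config.nonbuffering_ssd_ancient_fraction if is_ssd else 1.0
            a = _exact_flags(rng, len(nonbuf_idx), frac)
            ancient_nonbuf[nonbuf_idx[a]] = True
        for i in range(n_pairs):
            pid = f"{prefix}{i:04d}"
            ga, gb = f"{prefix}{i:04d}a", f"{prefix}{i:04d}b"
            buffering = bool(flags[i])
            # --- Ks ---
            if buffering and recent[i]:
                if config.ks_recent_uniform:
                    ks = float(rng.uniform(0.05, 1.6))
                else:
                    ks = float(abs(rng.normal(config.ks_left_mode, config.ks_left_sd)))
                    ks = min(max(ks, 0.01), 1.95)
            elif buffering:
                ks = float(rng.uniform(config.ks_right_low, config.ks_right_high))
            elif ancient_nonbuf[i]:
                ks = float(rng.uniform(config.ks_right_low, config.ks_right_high))
            else:
                ks = float(rng.uniform(0.2, 1.95))
            ka = float(np.clip(0.02 + 0.08 * min(ks, 2.5) + rng.normal(0, 0.02), 1e-3, 0.6))
            # --- score / p ---
            if buffering:
                if is_ssd and recent[i]:
                    score = -(config.neutral_intercept - config.neutral_slope * ks)
                    score += float(rng.normal(0, config.neutral_noise_sd))
                elif is_ssd:
                    score = float(
                        rng.normal(config.ssd_ancient_strength_mean, config.ssd_ancient_strength_sd)
                    )
                else:
                    score = float(rng.normal(config.wgd_strength_mean, config.wgd_strength_sd))
                score = min(score, -1e-3)
                p_value = float(rng.uniform(0.0, 0.05))
            else:
                magnitude = float(abs(rng.normal(0.05, 0.05))) + 1e-6
                if rng.random() < 0.5:
                    score, p_value = magnitude, float(rng.uniform(0.0, 1.0))
                else:
                    score, p_value = -magnitude, float(rng.uniform(0.051, 1.0))
            # --- annotations: share two children of an anchor term ---
            anchors = deep_anchors if buffering else shallow_anchors
            anchor = anchors[int(rng.integers(len(anchors)))]
            kids = children[anchor]
            if len(kids) >= 2:
                ca, cb = rng.choice(len(kids), size=2, replace=False)
                terms_a, terms_b = {kids[ca]}, {kids[cb]}
            else:
                terms_a, terms_b = {anchor}, {anchor}
            for terms in (terms_a, terms_b):
                if rng.random() < 0.6:
                    terms.add(all_terms[int(rng.integers(len(all_terms)))])
            gene_terms[ga] = terms_a
            gene_terms[gb] = terms_b
            pairs.append(PairRecord(
                pair_id=pid, gene_a=ga, gene_b=gb,
                pair_class="SSD" if is_ssd else "WGD",
                score=score, p_value=p_value, ka=ka, ks=ks,
                buffering=buffering,
                meta={"recent": bool(recent[i])},
            ))

    make_class("W", config.n_wgd_pairs, config.buffering_rate_wgd, is_ssd=False)
    make_class("S", config.n_ssd_pairs, config.buffering_rate_ssd, is_ssd=True)
    if not pairs:
        raise SynthConfigError("no pairs configured")

    corpus = AnnotationCorpus.from_gene_terms(dag, gene_terms)

    # --- interaction table: true pairs + duplicate cross pairs + background
    records = [
        InteractionRecord(p.gene_a, p.gene_b, p.score, p.p_value) for p in pairs
    ]
    duplicate_genes = [g for p in pairs for g in p.genes]
    if config.n_duplicate_cross_pairs and len(duplicate_genes) >= 4:
        seen = {InteractionRecord(p.gene_a, p.gene_b, 0, 0).key for p in pairs}
        scores = _background_scores(
            rng, config.n_duplicate_cross_pairs,
            config.duplicate_background_negative_rate, config.background_score_scale,
        )
        made = 0
        while made < config.n_duplicate_cross_pairs:
            i, j = rng.integers(len(duplicate_genes), size=2)
            a, b = duplicate_genes[int(i)], duplicate_genes[int(j)]
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            records.append(InteractionRecord(a, b, float(scores[made]), float(rng.uniform())))
            made += 1
    if config.n_background_pairs:
        scores = _background_scores(
            rng, config.n_background_pairs,
            config.background_negative_rate, config.background_score_scale,
        )
        for i in range(config.n_background_pairs):
            records.append(InteractionRecord(
                f"RA{i:06d}", f"RB{i:06d}", float(scores[i]), float(rng.uniform())
            ))
    table = InteractionTable(records)

    bundle = SynthBundle(
        config=config, dag=dag, corpus=corpus, gene_terms=gene_terms,
        pairs=pairs, interactions=table, duplicate_genes=duplicate_genes,
    )

    # --- codon sequences ---
    if config.with_sequences:
        for p in pairs:
            ancestor = random_cds(rng, config.n_codons)
            bundle.sequences[p.gene_a] = ancestor
            bundle.sequences[p.gene_b] = mutate_cds(rng, ancestor, p.ks, p.ka)

    # --- expression profiles ---
    if config.with_expression:
        nc = config.n_expression_conditions
        for p in pairs:
            target_r = 0.7 if p.buffering else 0.1
            r = float(np.clip(target_r + rng.normal(0, 0.15), -0.3, 0.95))
            a = rng.normal(size=nc)
            b = r * a + math.sqrt(max(1e-9, 1 - r * r)) * rng.normal(size=nc)
            bundle.expression[p.gene_a] = a
            bundle.expression[p.gene_b] = b

    # --- secondary structures ---
    if config.with_structures:
        trans = np.array([[0.85, 0.05, 0.10], [0.05, 0.85, 0.10], [0.15, 0.15, 0.70]])
        states = "HEC"
        for p in pairs:
            s = [int(rng.integers(3))]
            for _ in range(config.ss_length - 1):
                s.append(int(rng.choice(3, p=trans[s[-1]])))
            base = "".join(states[i] for i in s)
            flip = 0.05 if p.buffering else 0.30
            partner = "".join(
                states[int(rng.integers(3))] if rng.random() < flip else ch for ch in base
            )
            bundle.ss[p.gene_a] = base
            bundle.ss[p.gene_b] = partner

    # --- PPI + complexes, exact planted rates per buffering group ---
    if config.with_network:
        buf = [p for p in pairs if p.buffering]
        nonbuf = [p for p in pairs if not p.buffering]
        shared_flags = {}
        co_flags = {}
        for group, share_rate, co_rate in (
            (buf, config.shared_partner_rate_buffering, config.cocluster_rate_buffering),
            (nonbuf, config.shared_partner_rate_nonbuffering, config.cocluster_rate_nonbuffering),
        ):
            if not group:
                continue
            sf = _exact_flags(rng, len(group), share_rate)
            cf = _exact_flags(rng, len(group), co_rate)
            for p, s, c in zip(group, sf, cf):
                shared_flags[p.pair_id] = bool(s)
                co_flags[p.pair_id] = bool(c)
        hub = 0
        cplx = 0
        filler = 0
        for p in pairs:
            if shared_flags.get(p.pair_id):
                partner = f"HUB{hub:05d}"
                hub += 1
                bundle.ppi_edges += [(p.gene_a, partner), (p.gene_b, partner)]
            else:
                pa, pb = f"HUB{hub:05d}", f"HUB{hub + 1:05d}"
                hub += 2
                bundle.ppi_edges += [(p.gene_a, pa), (p.gene_b, pb)]
            if co_flags.get(p.pair_id):
                name = f"CPX{cplx:04d}"
                cplx += 1
                bundle.complexes[name] = {p.gene_a, p.gene_b, f"FIL{filler:05d}"}
                filler += 1
            else:
                na, nb = f"CPX{cplx:04d}", f"CPX{cplx + 1:04d}"
                cplx += 2
                bundle.complexes[na] = {p.gene_a, f"FIL{filler:05d}"}
                bundle.complexes[nb] = {p.gene_b, f"FIL{filler + 1:05d}"}
                filler += 2

    return bundle


def generate_bundle(config: SynthConfig) -> SynthBundle:
    dag, gene_terms = generate_ontology(config)
    return generate_pairs(config, dag, gene_terms)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _write_obo(path: str, dag: OntologyDAG) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic process {term}\n")
            fh.write("namespace: biological_process\n")
            for parent in sorted(dag.parents[term]):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def _write_gaf(path: str, gene_terms: dict[str, set[str]]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(gene_terms):
            for term in sorted(gene_terms[gene]):
                cols = [
                    "SYNTH", gene, gene, "involved_in", term, "PMID:0000000",
                    "IDA", "", "P", gene, "", "protein", "taxon:4932",
                    "20090101", "SYNTH", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def write_fixture_bundle(out_dir: str, config: SynthConfig) -> tuple[SynthBundle, dict]:
    """Generate a bundle and write every pipeline input as plain text,
    plus a manifest recording the config and per-file checksums."""
    bundle = generate_bundle(config)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def register(name: str) -> str:
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    _write_obo(register("ontology.obo"), bundle.dag)
    _write_gaf(register("annotations.gaf"), bundle.gene_terms)
    with open(register("pairs.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("pair_id\tgene_a\tgene_b\tpair_class\n")
        for p in bundle.pairs:
            fh.write(f"{p.pair_id}\t{p.gene_a}\t{p.gene_b}\t{p.pair_class}\n")
    with open(register("interactions.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tscore\tp_value\n")
        for r in bundle.interactions.records:
            fh.write(f"{r.gene_a}\t{r.gene_b}\t{r.score:.6g}\t{r.p_value:.6g}\n")
    with open(register("kaks.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("pair_id\tka\tks\n")
        for p in bundle.pairs:
            fh.write(f"{p.pair_id}\t{p.ka:.6g}\t{p.ks:.6g}\n")
    if bundle.sequences:
        with open(register("cds.fasta"), "wt", encoding="utf-8") as fh:
            for gene in sorted(bundle.sequences):
                fh.write(f">{gene}\n{bundle.sequences[gene]}\n")
    if bundle.expression:
        with open(register("expression.tsv"), "wt", encoding="utf-8") as fh:
            nc = config.n_expression_conditions
            fh.write("gene\t" + "\t".join(f"c{i}" for i in range(nc)) + "\n")
            for gene in sorted(bundle.expression):
                vals = "\t".join(f"{v:.5g}" for v in bundle.expression[gene])
                fh.write(f"{gene}\t{vals}\n")
    if bundle.ss:
        with open(register("ss.txt"), "wt", encoding="utf-8") as fh:
            for gene in sorted(bundle.ss):
                fh.write(f">{gene}\n{bundle.ss[gene]}\n")
    if bundle.ppi_edges:
        with open(register("ppi.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\n")
            for a, b in bundle.ppi_edges:
                fh.write(f"{a}\t{b}\n")
    if bundle.complexes:
        with open(register("complexes.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("complex_id\tgene\n")
            for name in sorted(bundle.complexes):
                for gene in sorted(bundle.complexes[name]):
                    fh.write(f"{name}\t{gene}\n")

    manifest = {
        "config": asdict(config),
        "checksums": {
            name: hashlib.sha256(open(p, "rb").read()).hexdigest()
            for name, p in paths.items()
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle, manifest
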