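"""Genetic-interaction tables, buffering calls, and randomization nulls.

A pair buffers when its quantitative interaction score is negative and its
per-pair P-value falls below the significance threshold (default 0.05).
Two null protocols calibrate observed buffering rates: uniform sampling of
assayed pairs, and random re-pairing of the duplicate genes themselves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class InteractionError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionRecord:
    gene_a: str
    gene_b: str
    score: float
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise InteractionError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b) if self.gene_a <= self.gene_b else (self.gene_b, self.gene_a)


class InteractionTable:
    """Unordered-pair index over interaction records."""

    def __init__(self, records: Iterable[InteractionRecord]):
        self._index: dict[tuple[str, str], InteractionRecord] = {}
        n_collapsed = 0
        for rec in records:
            prev = self._index.get(rec.key)
            if prev is not None:
                n_collapsed += 1
                if rec.p_value < prev.p_value:
                    self._index[rec.key] = rec
            else:
                self._index[rec.key] = rec
        if not self._index:
            raise InteractionError("empty interaction table")
        self.n_collapsed = n_collapsed
        if n_collapsed:
            logger.info("collapsed %d duplicate unordered pairs", n_collapsed)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self._index

    def get(self, gene_a: str, gene_b: str) -> InteractionRecord | None:
        key = (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)
        return self._index.get(key)

    @property
    def records(self) -> list[InteractionRecord]:
        return list(self._index.values())

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._index:
            out.add(a)
            out.add(b)
        return out

    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self._index.values()])


def read_interaction_table(stream: str | IO[str]) -> InteractionTable:
    """Read a TSV with columns gene_a, gene_b, score, p_value.

    Out-of-range p-values reject the row (logged); non-numeric fields raise
    with the offending line number; duplicate unordered pairs collapse to the
    more significant record.
    """
    if isinstance(stream, str) and "\n" in stream:
        stream = StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype={"gene_a": str, "gene_b": str})
    required = {"gene_a", "gene_b", "score", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise InteractionError(f"missing columns: {sorted(missing)}")
    records: list[InteractionRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            score = float(row.score)
            p = float(row.p_value)
        except (TypeError, ValueError) as exc:
            raise InteractionError(f"non-numeric score/p_value at line {i}") from exc
        if math.isnan(score) or math.isnan(p):
            raise InteractionError(f"non-numeric score/p_value at line {i}")
        if not 0.0 <= p <= 1.0:
            n_rejected += 1
            logger.warning("rejected line %d: p_value %s outside [0, 1]", i, p)
            continue
        records.append(InteractionRecord(str(row.gene_a), str(row.gene_b), score, p))
    if not records:
        raise InteractionError("no valid interaction rows")
    table = InteractionTable(records)
    table.n_rejected = n_rejected
    return table


def classify_buffering(record, alpha: float = DEFAULT_ALPHA) -> bool:
    """True iff score < 0 and p_value < alpha."""
    return record.score < 0 and record.p_value < alpha


@dataclass
class BufferingSummary:
    n_buffering: int
    n_total: int
    fraction: float
    mean_strength: float | None  # mean score over buffering pairs; None if none

    @property
    def percentage(self) -> float:
        return 100.0 * self.fraction


def buffering_summary(pairs: Sequence, alpha: float = DEFAULT_ALPHA) -> BufferingSummary:
    """Buffering fraction and mean strength over a pair collection.

    Each element needs ``score`` and ``p_value`` attributes.  Mean strength
    is computed over buffering pairs only and is ``None`` (undefined, never
    0) when no pair buffers.
    """
    pairs = list(pairs)
    if not pairs:
        raise InteractionError("no pairs supplied")
    flags = [classify_buffering(p, alpha) for p in pairs]
    n_buf = sum(flags)
    mean_strength = (
        float(np.mean([p.score for p, f in zip(pairs, flags) if f])) if n_buf else None
    )
    return BufferingSummary(n_buf, len(pairs), n_buf / len(pairs), mean_strength)


@dataclass
class NullDistribution:
    """Ensemble of randomized controls.

    ``control_percentages``: per control, % of sampled pairs with a negative
    score.  ``control_mean_scores``: per control, mean score among the
    negative pairs (NaN when a control drew none).
    """

    control_percentages: np.ndarray
    control_mean_scores: np.ndarray
    n_controls: int
    pairs_per_control: int
    seed: int
    n_dropped: int = 0

    def __post_init__(self):
        if len(self.control_percentages) != self.n_controls - self.n_dropped:
            raise InteractionError("percentage vector length mismatch")
        if np.any((self.control_percentages < 0) | (self.control_percentages > 100)):
            raise InteractionError("control percentage outside [0, 100]")


def randomization_null(
    table: InteractionTable,
    n_controls: int = 1000,
    pairs_per_control: int = 1000,
    seed: int = 0,
    replace: bool = False,
) -> NullDistribution:
    """Control protocol 1: sample assayed pairs uniformly per control."""
    scores = table.scores()
    if len(scores) < pairs_per_control and not replace:
        raise InteractionError(
            f"table has {len(scores)} pairs < pairs_per_control={pairs_per_control}; "
            "pass replace=True to sample with replacement"
        )
    rng = np.random.default_rng(seed)
    percentages = np.empty(n_controls)
    means = np.empty(n_controls)
    for i in range(n_controls):
        sample = rng.choice(scores, size=pairs_per_control, replace=replace)
        neg = sample[sample < 0]
        percentages[i] = 100.0 * len(neg) / pairs_per_control
        means[i] = neg.mean() if len(neg) else np.nan
    return NullDistribution(percentages, means, n_controls, pairs_per_control, seed)


def duplicate_shuffle_null(
    duplicate_genes: Sequence[str],
    table: InteractionTable,
    n_controls: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Control protocol 2: randomly re-pair the duplicate genes themselves.

    Per control the gene list is permuted and split into disjoint pairs; only
    pairings present in the table are scored.  A shuffled pairing that
    happens to recreate a true duplicate pair is allowed and counted.
    Controls with no assayed pairing are dropped with a warning.
    """
    genes = list(dict.fromkeys(duplicate_genes))
    if len(genes) < 4:
        raise InteractionError("need at least 4 duplicate genes to shuffle")
    rng = np.random.default_rng(seed)
    percentages: list[float] = []
    means: list[float] = []
    n_dropped = 0
    for _ in range(n_controls):
        order = rng.permutation(len(genes))
        scores = []
        for j in range(0, len(genes) - 1, 2):
            rec = table.get(genes[order[j]], genes[order[j + 1]])
            if rec is not None:
                scores.append(rec.score)
        if not scores:
            n_dropped += 1
            continue
        arr = np.array(scores)
        neg = arr[arr < 0]
        percentages.append(100.0 * len(neg) / len(arr))
        means.append(neg.mean() if len(neg) else np.nan)
    if not percentages:
        raise InteractionError("every shuffle control was unassayed")
    if n_dropped:
        logger.warning("dropped %d/%d shuffle controls with no assayed pairing", n_dropped, n_controls)
    return NullDistribution(
        np.array(percentages), np.array(means), n_controls, len(genes) // 2, seed,
        n_dropped=n_dropped,
    )


def empirical_p(observed: float, null, side: str, stat: str = "percentage") -> float:
    """Add-one empirical p-value of ``observed`` against a null ensemble.

    ``null`` may be a :class:`NullDistribution` (``stat`` selects the
    percentage or mean-score ensemble) or any array of null values.
    """
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    if isinstance(null, NullDistribution):
        values = null.control_percentages if stat == "percentage" else null.control_mean_scores
    else:
        values = np.asarray(null, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise InteractionError("null distribution is empty")
    if side == "greater":
        extreme = int(np.sum(values >= observed))
    else:
        extreme = int(np.sum(values <= observed))
    return (extreme + 1) / (len(values) + 1)


def strength_vs_background(
    buffering_scores: Sequence[float],
    background_scores: Sequence[float],
) -> dict:
    """Two-sample rank test that buffering scores are more negative than
    background negative-pair scores (one-sided Mann-Whitney)."""
    u = stats.mannwhitneyu(buffering_scores, background_scores, alternative="less")
    return {"statistic": float(u.statistic), "p_value": float(u.pvalue)}
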