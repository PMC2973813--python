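"""Shared record types used across analysis stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class PairRecord:
    """One duplicate gene pair and the quantities measured for it.

    ``score``/``p_value`` come from the genetic-interaction table; the
    divergence metrics are filled in by the corresponding stages and may be
    NaN when undefined (e.g. saturated Ks, zero-variance expression).
    """

    pair_id: str
    gene_a: str
    gene_b: str
    pair_class: str = ""  # "WGD" or "SSD"
    score: float = math.nan
    p_value: float = math.nan
    ka: float = math.nan
    ks: float = math.nan
    identity: float = math.nan
    expression_divergence: float = math.nan
    go_div: float = math.nan
    buffering: bool | None = None
    meta: dict = field(default_factory=dict)

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)
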