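"""Population-level aggregation of repair-event calls.

Rates are percentages with half-up rounding (so 1/106 prints as 0.9 and
13/106 as 12, matching how such counts are conventionally reported). Because
the NCO screen removes plants from the denominator, every summary carries
both denominators — plants sequenced and plants eligible after the
homozygosity screen — side by side, with the raw counts, so no rate is ever
ambiguous about what it divides by.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .markers import DsbTarget
from .tracts import ConversionTract


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_rate(count: int, denominator: int, decimals: int = 1) -> float:
    """100 * count / denominator, rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return round_half_up(100.0 * count / denominator, decimals)


@dataclass
class PlantCall:
    """Per-plant outcome at one target, as produced by the HMM + tract stages."""

    plant_id: str
    eligible: bool  # passed the homozygosity screen
    tract: Optional[ConversionTract] = None
    co_at_target: bool = False


@dataclass
class PopulationSummary:
    target_id: str
    n_plants_sequenced: int
    n_eligible: int
    n_nco: int
    n_co: int
    nco_rate_pct_sequenced: float  # 0 decimals, denominator = sequenced
    nco_rate_pct_eligible: float  # 0 decimals, denominator = eligible
    co_rate_pct: float  # 1 decimal, denominator = sequenced
    min_tract_bp: Optional[int]
    max_tract_bp: Optional[int]
    n_simple: int
    n_complex: int

    def __post_init__(self) -> None:
        if not self.n_nco <= self.n_eligible <= self.n_plants_sequenced:
            raise ValueError("require n_nco <= n_eligible <= n_plants_sequenced")


def summarize_population(calls: Sequence[PlantCall], target: DsbTarget) -> PopulationSummary:
    """Counts, rates and tract statistics for one target's F2 population."""
    if not calls:
        raise ValueError("empty population")
    n = len(calls)
    eligible = [c for c in calls if c.eligible]
    tracts = [c.tract for c in eligible if c.tract is not None]
    n_nco = len(tracts)
    n_co = sum(c.co_at_target for c in calls)
    n_elig = len(eligible)
    return PopulationSummary(
        target_id=target.id,
        n_plants_sequenced=n,
        n_eligible=n_elig,
        n_nco=n_nco,
        n_co=n_co,
        nco_rate_pct_sequenced=compute_rate(n_nco, n, 0),
        nco_rate_pct_eligible=compute_rate(n_nco, n_elig, 0) if n_elig else 0.0,
        co_rate_pct=compute_rate(n_co, n, 1),
        min_tract_bp=min((t.min_length for t in tracts), default=None),
        max_tract_bp=max((t.min_length for t in tracts), default=None),
        n_simple=sum(t.complexity == "simple" for t in tracts),
        n_complex=sum(t.complexity == "complex" for t in tracts),
    )


_SUMMARY_COLUMNS = [
    "target_id",
    "n_plants_sequenced",
    "n_eligible",
    "n_nco",
    "n_co",
    "nco_rate_pct_sequenced",
    "nco_rate_pct_eligible",
    "co_rate_pct",
    "min_tract_bp",
    "max_tract_bp",
    "n_simple",
    "n_complex",
]


def write_summary_tsv(summaries: Sequence[PopulationSummary], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in summaries])[_SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_tsv(path: str | Path) -> list[PopulationSummary]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.to_dict("records"):
        for key in ("min_tract_bp", "max_tract_bp"):
            r[key] = None if pd.isna(r[key]) else int(r[key])
        for key in ("n_plants_sequenced", "n_eligible", "n_nco", "n_co", "n_simple", "n_complex"):
            r[key] = int(r[key])
        out.append(PopulationSummary(**r))
    return out
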