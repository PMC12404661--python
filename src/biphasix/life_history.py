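"""Genome-trait-based life-history prediction.

Two layers:

* the fast/slow growth dichotomy — maximal growth rate r_max (per hour,
  codon-usage predicted) converts to a doubling time ln(2)/r_max, with 5 h
  doubling time (rate ≈ 0.14/h) separating slow from fast growers;

* Grime's CSR classification — each species is scored by how many
  strategy-congruent traits fall in the extreme quartiles of the community
  distribution.  Competitor traits: high genome size, antibiotic pathways,
  siderophore pathways and catabolic pathways.  Stress-tolerator traits:
  slow growth, few rRNA copies, many biofilm genes and auxotrophies.
  Ruderal traits: few catabolic pathways, fast growth, many rRNA copies and
  high codon usage bias.  The strategy with the most contributing traits
  wins; ties (including all-zero scores) are called intermediate.  Ternary
  coordinates (scores normalized to sum 1, centroid when all zero) position
  each species in the CSR triangle.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .datamodel import TableSchemaError, TraitTable

__all__ = [
    "Strategy",
    "CSRScore",
    "STRATEGY_TRAITS",
    "growth_rate_to_doubling_time",
    "doubling_time_to_growth_rate",
    "classify_growth",
    "quantile_thresholds",
    "csr_scores",
    "assign_strategy",
    "classify_community",
]

#: doubling time (hours) separating fast from slow growers
DEFAULT_GROWTH_THRESHOLD_H = 5.0


class Strategy(str, enum.Enum):
    competitor = "competitor"
    stress_tolerator = "stress_tolerator"
    ruderal = "ruderal"
    intermediate = "intermediate"


#: strategy -> [(trait column, "high"|"low"), ...]; "high" contributes when the
#: species' value lies strictly above the community Q75, "low" strictly below Q25
STRATEGY_TRAITS: Dict[Strategy, List[Tuple[str, str]]] = {
    Strategy.competitor: [
        ("genome_size_mb", "high"),
        ("n_antibiotic_pathways", "high"),
        ("n_siderophore_pathways", "high"),
        ("n_catabolic_pathways", "high"),
    ],
    Strategy.stress_tolerator: [
        ("max_growth_rate", "low"),
        ("n_rrna_copies", "low"),
        ("n_biofilm_genes", "high"),
        ("n_auxotrophies", "high"),
    ],
    Strategy.ruderal: [
        ("n_catabolic_pathways", "low"),
        ("max_growth_rate", "high"),
        ("n_rrna_copies", "high"),
        ("codon_usage_bias", "high"),
    ],
}

#: every trait column the scorer touches
SCORED_TRAITS = sorted(
    {trait for traits in STRATEGY_TRAITS.values() for trait, _ in traits}
)


@dataclasses.dataclass
class CSRScore:
    species_id: str
    score_C: int
    score_S: int
    score_R: int
    ternary: Tuple[float, float, float]
    assignment: Strategy

    def as_row(self) -> dict:
        return {
            "species_id": self.species_id,
            "score_C": self.score_C,
            "score_S": self.score_S,
            "score_R": self.score_R,
            "ternary_C": self.ternary[0],
            "ternary_S": self.ternary[1],
            "ternary_R": self.ternary[2],
            "assignment": self.assignment.value,
        }


def growth_rate_to_doubling_time(r_max: float) -> float:
    """Doubling time in hours for an exponential rate r_max (per hour)."""
    if r_max <= 0:
        raise ValueError("r_max must be > 0")
    return math.log(2) / r_max


def doubling_time_to_growth_rate(doubling_time_h: float) -> float:
    if doubling_time_h <= 0:
        raise ValueError("doubling time must be > 0")
    return math.log(2) / doubling_time_h


def classify_growth(
    doubling_time_h: float, threshold_h: float = DEFAULT_GROWTH_THRESHOLD_H
) -> str:
    """"fast" iff the doubling time is strictly below the threshold.

    A species exactly at the threshold is called slow (the threshold is
    quoted as separating the groups, so a boundary convention is needed).
    """
    if doubling_time_h <= 0:
        raise ValueError("doubling time must be > 0")
    return "fast" if doubling_time_h < threshold_h else "slow"


def quantile_thresholds(
    table: TraitTable, method: str = "linear"
) -> pd.DataFrame:
    """Empirical Q25 and Q75 per scored trait across the community.

    Linear interpolation of order statistics (numpy's default, R type 7)
    unless another numpy quantile ``method`` is named.  Requires at least 4
    species for the quartiles to be meaningful.
    """
    if len(table) < 4:
        raise ValueError("quantile thresholds need at least 4 species")
    data = table.frame[SCORED_TRAITS]
    q = np.quantile(data.to_numpy(), [0.25, 0.75], axis=0, method=method)
    return pd.DataFrame(q, index=["q25", "q75"], columns=SCORED_TRAITS)


def _contributes(value: float, direction: str, q25: float, q75: float) -> bool:
    # strict inequalities: degenerate all-equal traits contribute nothing
    return value > q75 if direction == "high" else value < q25


def assign_strategy(score_c: int, score_s: int, score_r: int) -> CSRScore:
    """Final call from the three trait counts (species label left blank).

    Unique argmax wins; any tie for the maximum — including all-zero
    scores — is intermediate.  Ternary coordinates are the scores
    normalized by their sum, with the centroid for all-zero scores.
    """
    scores = (score_c, score_s, score_r)
    if any(s < 0 for s in scores):
        raise ValueError("scores must be >= 0")
    total = sum(scores)
    if total == 0:
        ternary = (1 / 3, 1 / 3, 1 / 3)
    else:
        ternary = tuple(s / total for s in scores)
    best = max(scores)
    winners = [i for i, s in enumerate(scores) if s == best]
    if len(winners) > 1:
        assignment = Strategy.intermediate
    else:
        assignment = [Strategy.competitor, Strategy.stress_tolerator, Strategy.ruderal][
            winners[0]
        ]
    return CSRScore(
        species_id="",
        score_C=score_c,
        score_S=score_s,
        score_R=score_r,
        ternary=ternary,
        assignment=assignment,
    )


def csr_scores(
    table: TraitTable,
    quantile_method: str = "linear",
    binary_antibiotics: bool = False,
) -> List[CSRScore]:
    """Score and classify every species in the community.

    ``binary_antibiotics`` switches the antibiotic-pathway criterion from the
    quantile rule to simple presence (count > 0).
    """
    missing = [c for c in SCORED_TRAITS if c not in table.frame.columns]
    if missing:
        raise TableSchemaError(f"missing trait column(s): {', '.join(missing)}")
    thresholds = quantile_thresholds(table, method=quantile_method)
    results = []
    for species, row in table.frame.iterrows():
        per_strategy = {}
        for strategy, traits in STRATEGY_TRAITS.items():
            n = 0
            for trait, direction in traits:
                if binary_antibiotics and trait == "n_antibiotic_pathways":
                    n += int(row[trait] > 0)
                    continue
                n += int(
                    _contributes(
                        row[trait],
                        direction,
                        thresholds.loc["q25", trait],
                        thresholds.loc["q75", trait],
                    )
                )
            per_strategy[strategy] = n
        score = assign_strategy(
            per_strategy[Strategy.competitor],
            per_strategy[Strategy.stress_tolerator],
            per_strategy[Strategy.ruderal],
        )
        score.species_id = str(species)
        results.append(score)
    return results


def classify_community(
    table: TraitTable,
    quantile_method: str = "linear",
    binary_antibiotics: bool = False,
    growth_threshold_h: float = DEFAULT_GROWTH_THRESHOLD_H,
) -> pd.DataFrame:
    """CSR scores plus the fast/slow growth class, one row per species."""
    rows = []
    scores = csr_scores(
        table, quantile_method=quantile_method, binary_antibiotics=binary_antibiotics
    )
    for score in scores:
        row = score.as_row()
        dt = table.frame.loc[score.species_id, "doubling_time_h"]
        row["growth_class"] = classify_growth(dt, threshold_h=growth_threshold_h)
        rows.append(row)
    return pd.DataFrame(rows)
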