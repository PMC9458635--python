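"""Herbicide-injury phenotype binning and resistance tabulation.

Plants are scored for visible injury after herbicide application on a 0-100%
scale (0 = no injury, 100 = dead). Mean injury bins a sample as highly
resistant (0-32%), moderately resistant (33-67%) or susceptible (68-100%).
A sample whose individual plants fall in both a resistant bin and the
susceptible bin is called Segregating — the signature of an herbicide-
resistance allele still heterozygous (or otherwise unfixed) in the maternal
line's offspring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

HIGH = "High"
MODERATE = "Moderate"
SUSCEPTIBLE = "Susceptible"
SEGREGATING = "Segregating"
CATEGORIES = (HIGH, MODERATE, SUSCEPTIBLE, SEGREGATING)
RESISTANT_BINS = frozenset({HIGH, MODERATE})

FIELD_TYPES = ("CHY", "HYB", "CLF")


@dataclass(frozen=True)
class InjuryRecord:
    """Per-plant injury scores for one field-collected sample."""

    sample_id: str
    field_type: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("at least one plant score required")
        for s in self.scores:
            if not (0.0 <= s <= 100.0):
                raise ValueError(f"injury score {s} outside [0, 100]")


def bin_injury(mean_injury: float, floor_means: bool = True) -> str:
    """Bin a mean injury percentage into a resistance category.

    Boundaries are inclusive integer ranges (<=32 High, 33-67 Moderate,
    >=68 Susceptible); non-integer means are floored before comparison by
    default so the printed integer ranges partition [0, 100].
    """
    if not (0.0 <= mean_injury <= 100.0):
        raise ValueError(f"mean injury {mean_injury} outside [0, 100]")
    x = math.floor(mean_injury) if floor_means else mean_injury
    if x <= 32:
        return HIGH
    if x <= 67:
        return MODERATE
    return SUSCEPTIBLE


def classify_sample(rec: InjuryRecord, floor_means: bool = True) -> str:
    """Resistance category of one sample from its per-plant scores.

    Segregating when plants co-occur in the susceptible bin and a resistant
    bin; otherwise the bin of the across-plant mean. Invariant to plant
    order.
    """
    bins = {bin_injury(s, floor_means) for s in rec.scores}
    if SUSCEPTIBLE in bins and bins & RESISTANT_BINS:
        return SEGREGATING
    return bin_injury(sum(rec.scores) / len(rec.scores), floor_means)


def _pct(count: int, total: int) -> float:
    if total == 0:
        return float("nan")
    return float(
        Decimal(100 * count / total).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def tabulate_resistance(
    records: Iterable[InjuryRecord],
    field_types: Sequence[str] = FIELD_TYPES,
    floor_means: bool = True,
) -> pd.DataFrame:
    """Counts and column percentages of resistance categories by field type.

    Rows are the four categories; columns are each field type plus a Total
    column. Cells hold ``count`` and ``pct`` (percent of the field type's
    column total; the Total column is percent of all samples), rounded
    half-up to 1 decimal. Exact fractions are recoverable from the counts.
    """
    records = list(records)
    if not records:
        raise ValueError("no injury records")
    known = set(field_types)
    for rec in records:
        if rec.field_type not in known:
            raise KeyError(f"unknown field type {rec.field_type!r}")
    counts = {(c, f): 0 for c in CATEGORIES for f in field_types}
    for rec in records:
        counts[(classify_sample(rec, floor_means), rec.field_type)] += 1
    col_totals = {f: sum(counts[(c, f)] for c in CATEGORIES) for f in field_types}
    n_all = len(records)
    rows = []
    for c in CATEGORIES:
        row: dict[str, object] = {"category": c}
        for f in field_types:
            row[f"{f}_count"] = counts[(c, f)]
            row[f"{f}_pct"] = _pct(counts[(c, f)], col_totals[f])
        total = sum(counts[(c, f)] for f in field_types)
        row["Total_count"] = total
        row["Total_pct"] = _pct(total, n_all)
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def any_resistance_fraction(records: Iterable[InjuryRecord],
                            floor_means: bool = True) -> float:
    """Fraction of samples showing any resistance (High, Moderate or
    Segregating)."""
    records = list(records)
    hits = sum(
        classify_sample(r, floor_means) != SUSCEPTIBLE for r in records
    )
    return hits / len(records)


def read_injury_tsv(path: str | Path) -> list[InjuryRecord]:
    """Read per-plant injury scores from TSV
    (sample_id, field_type, plant_index, injury)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for (sid, ftype), grp in df.groupby(["sample_id", "field_type"], sort=False):
        ordered = grp.sort_values("plant_index")
        records.append(
            InjuryRecord(str(sid), str(ftype), tuple(float(x) for x in ordered["injury"]))
        )
    return records


def write_resistance_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
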