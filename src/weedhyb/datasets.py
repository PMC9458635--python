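"""Small bundled example datasets for demonstrations and arithmetic checks.

These are desk-scale inputs: a published-style per-chromosome weed-ancestry
bias table for two hybrid weed groups, a membership (Q) matrix with the
category composition of a 48-accession contemporary weedy-rice collection,
and an injury-score table matching a three-field-type resistance trial.
They exercise the table arithmetic (averaging, classification, tabulation)
without any genome-scale computation.
"""

from __future__ import annotations

import pandas as pd

from .resistance import InjuryRecord

#: Per-chromosome proportions of the contemporary genome assigned to the
#: weedy ancestor, for BHA-like and SH-like hybrid weed groups, across the
#: 12 rice chromosomes.
EXAMPLE_BIAS_ROWS = {
    "chrom": [f"chr{i}" for i in range(1, 13)],
    "BHA-like": [0.652, 0.796, 0.793, 0.775, 0.773, 0.609,
                 0.796, 0.704, 0.767, 0.766, 0.649, 0.810],
    "SH-like": [0.682, 0.658, 0.658, 0.696, 0.733, 0.770,
                0.652, 0.737, 0.545, 0.791, 0.656, 0.728],
}


def example_bias_table() -> pd.DataFrame:
    """Per-chromosome weed-ancestry bias rows (no average row)."""
    df = pd.DataFrame(EXAMPLE_BIAS_ROWS).set_index("chrom")
    df.index.name = None
    return df


# Composition of the example 48-accession collection:
# 28 BHA-like admixed, 6 SH-like admixed, 1 complex, 9 beta,
# 4 non-admixed SH.
_Q_ARCHETYPES: list[tuple[int, dict[str, float]]] = [
    (28, {"BHA": 0.60, "TRJ": 0.40}),
    (6, {"SH": 0.40, "TRJ": 0.60}),
    (1, {"SH": 0.25, "BHA": 0.25, "TRJ": 0.50}),
    (9, {"BETA": 0.90, "BHA": 0.06, "TRJ": 0.04}),
    (4, {"SH": 0.97, "TRJ": 0.03}),
]

Q_POPULATIONS = ("TRJ", "TMJ", "ARO", "IND", "AUS", "SH", "BHA", "BETA")


def example_q_matrix() -> pd.DataFrame:
    """Membership (Q) matrix of the example 48-accession collection."""
    rows = []
    ids = []
    i = 0
    for n, arch in _Q_ARCHETYPES:
        for _ in range(n):
            i += 1
            ids.append(f"cw{i:03d}")
            rows.append({p: arch.get(p, 0.0) for p in Q_POPULATIONS})
    q = pd.DataFrame(rows, index=ids)
    return q


# Resistance-category counts per field cropping history in the example
# trial: (field_type, category) -> number of samples.
_INJURY_COUNTS: dict[tuple[str, str], int] = {
    ("CHY", "High"): 14, ("CHY", "Segregating"): 1,
    ("HYB", "High"): 12, ("HYB", "Moderate"): 2,
    ("HYB", "Susceptible"): 2, ("HYB", "Segregating"): 3,
    ("CLF", "High"): 8, ("CLF", "Moderate"): 2,
    ("CLF", "Segregating"): 4,
}

_CATEGORY_SCORES = {
    "High": (5.0, 10.0, 8.0),
    "Moderate": (50.0, 55.0, 60.0),
    "Susceptible": (95.0, 90.0, 92.0),
    "Segregating": (5.0, 95.0, 10.0),
}


def example_injury_records() -> list[InjuryRecord]:
    """Per-plant injury scores reproducing the example trial's composition."""
    records = []
    i = 0
    for (ftype, category), n in _INJURY_COUNTS.items():
        for _ in range(n):
            i += 1
            records.append(
                InjuryRecord(f"cw{i:03d}", ftype, _CATEGORY_SCORES[category])
            )
    return records
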