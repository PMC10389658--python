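"""Genealogical relatedness on a 1-10 scale and pairwise difference tables.

Each unordered pair of languages carries an integer distance:

* 1 — varieties some would call dialects of one language;
* 2-8 — increasingly distant relationship within an accepted family;
* 9 — strongly divided expert opinion on a highest-level grouping;
* 10 — no widely accepted family relationship at all (isolates score 10
  against everything).

Pairwise trait/environment difference tables exclude d = 10 pairs, since
those carry no genealogical signal, and summarise |x_i - x_j| by distance
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


def label_distance_class(d: int) -> str:
    """Human-readable label for a 1-9 relatedness distance.

    1 is "Dialect", 2 "Close", 8 "Distant", 9 "Divided Opinions"; the
    intermediate values 3-7 get ordinal "Level k" labels.
    """
    if d == 1:
        return "Dialect"
    if d == 2:
        return "Close"
    if d == 8:
        return "Distant"
    if d == 9:
        return "Divided Opinions"
    if 3 <= d <= 7:
        return f"Level {d}"
    raise ValidationError(f"distance {d} has no class label (must be 1..9)")


#: Orders class labels by the underlying distance for plotting/trend tests.
CLASS_ORDER = [label_distance_class(d) for d in range(1, 10)]


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class RelatednessTable:
    """Symmetric pairwise distances on the 1-10 scale.

    Distances are stored sparsely on unordered pairs.  A missing pair is
    read as 10 only when *both* languages are flagged as belonging to no
    shared family (``no_family``); otherwise a missing pair is an error,
    which prevents silent misclassification of unscored pairs.
    """

    language_ids: list[str]
    distances: dict[tuple[str, str], int] = field(default_factory=dict)
    #: Languages (isolates or members of singleton families in this sample)
    #: for which every unstored cross pair is distance 10.
    no_family: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.language_ids)) != len(self.language_ids):
            raise ValidationError("duplicate language ids in relatedness table")
        self.distances = {_key(a, b): int(v) for (a, b), v in self.distances.items()}

    def get(self, a: str, b: str) -> int:
        if a == b:
            raise ValidationError("no self-distance is defined")
        try:
            return self.distances[_key(a, b)]
        except KeyError:
            if a in self.no_family and b in self.no_family:
                return 10
            raise ValidationError(f"no distance stored for pair ({a}, {b})") from None

    def pairs(self):
        """Yield every unordered pair (a, b, d) over ``language_ids``."""
        ids = self.language_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                yield a, b, self.get(a, b)


def validate_relatedness(table: RelatednessTable) -> list[str]:
    """Check scale semantics; returns a list of problems (empty iff valid)."""
    report: list[str] = []
    known = set(table.language_ids)
    for (a, b), d in table.distances.items():
        if a == b:
            report.append(f"self-distance stored for {a}")
        if not (1 <= d <= 10):
            report.append(f"({a}, {b}): value {d} outside 1..10")
        for lang in (a, b):
            if lang not in known:
                report.append(f"({a}, {b}): unknown language {lang}")
        if d != 10 and (a in table.no_family or b in table.no_family):
            report.append(
                f"({a}, {b}): distance {d} contradicts a no-shared-family flag"
            )
    return report


def validate_long_table(df: pd.DataFrame) -> list[str]:
    """Validate a long-format ``id_i, id_j, d`` table, including symmetry.

    Both orientations of a pair may be present; they must agree.
    """
    report: list[str] = []
    seen: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        a, b, d = str(row["id_i"]), str(row["id_j"]), int(row["d"])
        if a == b:
            report.append(f"self-distance stored for {a}")
            continue
        if not (1 <= d <= 10):
            report.append(f"({a}, {b}): value {d} outside 1..10")
        k = _key(a, b)
        if k in seen and seen[k] != d:
            report.append(f"asymmetric pair ({a}, {b}): {seen[k]} vs {d}")
        seen[k] = d
    return report


def read_relatedness_csv(path, language_ids=None, no_family=()) -> RelatednessTable:
    """Read a long-format CSV ``id_i,id_j,d``; asymmetries are fatal."""
    df = pd.read_csv(path, dtype={"id_i": str, "id_j": str})
    problems = validate_long_table(df)
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    distances = {
        _key(str(r["id_i"]), str(r["id_j"])): int(r["d"]) for _, r in df.iterrows()
    }
    if language_ids is None:
        language_ids = sorted({i for pair in distances for i in pair})
    return RelatednessTable(list(language_ids), distances, set(no_family))


def write_relatedness_csv(table: RelatednessTable, path) -> None:
    rows = [{"id_i": a, "id_j": b, "d": d} for (a, b), d in sorted(table.distances.items())]
    pd.DataFrame(rows, columns=["id_i", "id_j", "d"]).to_csv(path, index=False)


def pairwise_differences(
    values: Mapping[str, float],
    table: RelatednessTable,
    max_distance: int = 9,
    min_distance: int = 1,
) -> pd.DataFrame:
    """Absolute per-pair differences of a variable for related pairs.

    Pairs at distance 10 (no accepted relationship) are always excluded;
    ``min_distance`` allows additionally dropping distance-1 "dialect"
    pairs.  Pairs with a missing value on either side are dropped and
    counted in the ``n_dropped_missing`` DataFrame attribute.

    Returns a table with columns ``id_i, id_j, d, class_label, diff``.
    """
    defined = {
        k: float(v) for k, v in values.items()
        if v is not None and np.isfinite(v)
    }
    if not defined:
        raise ValidationError("variable has no defined values")
    rows = []
    n_missing = 0
    for a, b, d in table.pairs():
        if d > max_distance or d < min_distance:
            continue
        if a not in defined or b not in defined:
            n_missing += 1
            continue
        i, j = _key(a, b)  # canonical orientation: output independent of id order
        rows.append(
            {
                "id_i": i,
                "id_j": j,
                "d": d,
                "class_label": label_distance_class(d),
                "diff": abs(defined[a] - defined[b]),
            }
        )
    out = pd.DataFrame(rows, columns=["id_i", "id_j", "d", "class_label", "diff"])
    out.attrs["n_dropped_missing"] = n_missing
    return out


def summarize_by_class(pairs: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-style summaries of ``diff`` per occupied distance class.

    Quartiles use linear interpolation between order statistics (the
    "type 7" rule, shared package-wide); whiskers extend to the most
    extreme values within 1.5 IQR of the quartiles.
    """
    if pairs.empty:
        raise ValidationError("empty pair table")
    rows = []
    for d, grp in pairs.groupby("d"):
        x = grp["diff"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        rows.append(
            {
                "d": int(d),
                "class_label": label_distance_class(int(d)),
                "n": len(x),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_lo": inside.min(),
                "whisker_hi": inside.max(),
            }
        )
    return pd.DataFrame(rows).sort_values("d", ignore_index=True)
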