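"""Overlap of significant variants with published QTL intervals.

A user-supplied interval table (BED or 1-based CSV) with trait-category
labels is intersected with significant variant positions; a QTL counts
once per component column (All, additive/dominance x CW/WtW) when it
contains at least one significant variant for that component, and
percentages are column-wise over counted QTL.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["QTLInterval", "load_qtl_table", "overlap_counts"]

#: canonical trait categories; user-defined labels are carried through
TRAIT_CATEGORIES = [
    "Exterior", "Health", "Meat and Carcass", "Milk", "Production", "Reproduction",
]


@dataclass(frozen=True)
class QTLInterval:
    """1-based inclusive interval with a trait category."""

    chrom: str
    start: int
    end: int
    category: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if not self.category:
            raise ValueError("empty trait category")


def load_qtl_table(path: str | Path, dialect: str = "bed") -> list[QTLInterval]:
    """Load intervals, normalizing to 1-based inclusive coordinates.

    ``dialect="bed"``: whitespace-separated 0-based half-open
    (chrom, start, end, category); ``dialect="csv"``: comma-separated
    already-1-based with header columns chrom, start, end, category.
    """
    intervals: list[QTLInterval] = []
    if dialect == "bed":
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 BED fields")
            chrom, start, end = parts[0], parts[1], parts[2]
            category = " ".join(parts[3:])
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            intervals.append(QTLInterval(chrom, s + 1, e, category))
    elif dialect == "csv":
        df = pd.read_csv(path)
        for ln, row in enumerate(df.itertuples(index=False), start=2):
            intervals.append(
                QTLInterval(str(row.chrom), int(row.start), int(row.end), str(row.category))
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return intervals


def overlap_counts(
    significant: dict[str, pd.DataFrame],
    intervals: list[QTLInterval],
) -> pd.DataFrame:
    """Tabulate QTL containing significant variants, by category.

    ``significant`` maps a component label (e.g. ``"CW additive"``) to a
    frame of significant variant positions with columns chrom and pos.
    Each QTL is counted once per component when it contains >= 1 of that
    component's variants, and once in the All column when it contains any
    significant variant.  Output: one row per category, count and percent
    (column-wise) per component.
    """
    comps = list(significant)
    hit: dict[str, np.ndarray] = {
        c: np.zeros(len(intervals), dtype=bool) for c in comps
    }
    for comp, vars_df in significant.items():
        if vars_df.empty:
            continue
        chrom = vars_df["chrom"].astype(str).to_numpy()
        pos = vars_df["pos"].to_numpy()
        for i, iv in enumerate(intervals):
            inside = (chrom == iv.chrom) & (pos >= iv.start) & (pos <= iv.end)
            if inside.any():
                hit[comp][i] = True
    any_hit = np.zeros(len(intervals), dtype=bool)
    for c in comps:
        any_hit |= hit[c]

    categories = list(dict.fromkeys(iv.category for iv in intervals))
    cat_arr = np.array([iv.category for iv in intervals])
    rows = []
    columns = ["All"] + comps
    col_hits = {"All": any_hit, **hit}
    for cat in categories:
        row: dict = {"category": cat}
        mask = cat_arr == cat
        for col in columns:
            n = int((col_hits[col] & mask).sum())
            total = int(col_hits[col].sum())
            row[f"{col}_n"] = n
            row[f"{col}_pct"] = 100.0 * n / total if total else 0.0
        rows.append(row)
    total_row: dict = {"category": "Total"}
    for col in columns:
        total = int(col_hits[col].sum())
        total_row[f"{col}_n"] = total
        total_row[f"{col}_pct"] = 100.0 if total else 0.0
    rows.append(total_row)
    return pd.DataFrame(rows)
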