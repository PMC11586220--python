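"""MedDRA hierarchy handling: PT -> HLGT -> SOC mapping and aggregation.

MedDRA content is licensed, so the mapping is always user-supplied as a
three-column TSV (PT, HLGT, SOC); a synthetic toy hierarchy ships with the
generator's event catalog for testing. Signal-level results are aggregated
to per-HLGT or per-SOC case-count sums and proportions of a drug's total
signal case count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["MeddraMap", "load_meddra_map", "map_from_catalog", "aggregate_signals"]

UNMAPPED = "unmapped"


@dataclass
class MeddraMap:
    entries: dict[str, tuple[str, str]]  # PT -> (HLGT, SOC)
    version_label: str = "unversioned"

    def hlgt(self, pt: str) -> str | None:
        e = self.entries.get(pt)
        return e[0] if e else None

    def soc(self, pt: str) -> str | None:
        e = self.entries.get(pt)
        return e[1] if e else None

    def level_of(self, pt: str, level: str) -> str:
        if level not in ("HLGT", "SOC"):
            raise ValueError(f"level must be HLGT or SOC, got {level!r}")
        e = self.entries.get(pt)
        if e is None:
            return UNMAPPED
        return e[0] if level == "HLGT" else e[1]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["PT", "HLGT", "SOC"])
            for pt, (hlgt, soc) in sorted(self.entries.items()):
                w.writerow([pt, hlgt, soc])


def load_meddra_map(path: str | Path, version_label: str = "unversioned") -> MeddraMap:
    """Load a PT/HLGT/SOC TSV (header required).

    Duplicate rows with identical mappings collapse; a PT mapped to two
    different (HLGT, SOC) pairs is a configuration error.
    """
    entries: dict[str, tuple[str, str]] = {}
    conflicts: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().upper() for h in header[:3]] != ["PT", "HLGT", "SOC"]:
            raise ValueError(f"{path}: expected header 'PT<TAB>HLGT<TAB>SOC'")
        for row in reader:
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 3 or any(not f.strip() for f in row[:3]):
                raise ValueError(f"{path}: malformed row {row!r}")
            pt, hlgt, soc = (f.strip() for f in row[:3])
            if pt in entries and entries[pt] != (hlgt, soc):
                conflicts.append(pt)
            entries[pt] = (hlgt, soc)
    if conflicts:
        raise ValueError(f"conflicting mappings for PT(s): {sorted(set(conflicts))}")
    return MeddraMap(entries=entries, version_label=version_label)


def map_from_catalog(event_catalog: Iterable) -> MeddraMap:
    """Build the mapping from a synthetic event catalog (EventTerm sequence)."""
    return MeddraMap(
        entries={e.pt: (e.hlgt, e.soc) for e in event_catalog},
        version_label="synthetic-catalog",
    )


def aggregate_signals(
    signals: Sequence,
    meddra_map: MeddraMap,
    level: str = "SOC",
) -> pd.DataFrame:
    """Aggregate per-PT signals to HLGT or SOC groups.

    ``signals`` items need ``pt`` and ``a`` attributes (or be (pt, a)
    pairs). Returns one row per group with the signal count, summed case
    count, and two proportion weightings of the drug's totals: by case
    count (default reading) and by signal count. Unmappable PTs pool into
    an ``unmapped`` group. Empty input yields an empty table.
    """
    rows = []
    for s in signals:
        pt, a = (s.pt, s.a) if hasattr(s, "pt") else (s[0], s[1])
        rows.append({"group": meddra_map.level_of(pt, level), "pt": pt, "a": int(a)})
    if not rows:
        return pd.DataFrame(
            columns=["group", "n_signals", "case_count", "proportion", "proportion_signals"]
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("group", sort=True)
        .agg(n_signals=("pt", "size"), case_count=("a", "sum"))
        .reset_index()
    )
    agg["proportion"] = agg["case_count"] / agg["case_count"].sum()
    agg["proportion_signals"] = agg["n_signals"] / agg["n_signals"].sum()
    return agg
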