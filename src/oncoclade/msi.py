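"""Microsatellite-instability classification from the 5-marker panel.

The panel is the standard mononucleotide set for colon cancer (BAT25,
BAT26, NR21, NR22, NR27).  A sample with >=2 unstable markers is MSI-H,
exactly one is MSI-L, none is MSS.  Samples with too few evaluable markers
are reported as unclassifiable rather than silently called stable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

PANEL = ("BAT25", "BAT26", "NR21", "NR22", "NR27")
STATES = ("stable", "unstable", "missing")
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class MsiMarkerCalls:
    sample: str
    calls: Mapping[str, str]  # marker -> stable / unstable / missing

    def __post_init__(self) -> None:
        if set(self.calls) != set(PANEL):
            raise ValueError(
                f"sample {self.sample!r}: expected exactly the markers {PANEL}, "
                f"got {sorted(self.calls)}"
            )
        for marker, state in self.calls.items():
            if state not in STATES:
                raise ValueError(f"sample {self.sample!r}, marker {marker}: bad state {state!r}")


@dataclass(frozen=True)
class MsiStatus:
    sample: str
    status: str          # MSS / MSI-L / MSI-H / unclassifiable
    n_unstable: int
    n_evaluable: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_unstable <= self.n_evaluable <= len(PANEL):
            raise ValueError("inconsistent marker counts")


def classify_msi(marker_calls: MsiMarkerCalls, min_evaluable: int = 4) -> MsiStatus:
    """Classify one sample: >=2 unstable -> MSI-H, 1 -> MSI-L, 0 -> MSS.

    If fewer than ``min_evaluable`` markers are non-missing the call is
    refused and the status is ``unclassifiable``.
    """
    n_unstable = sum(1 for s in marker_calls.calls.values() if s == "unstable")
    n_evaluable = sum(1 for s in marker_calls.calls.values() if s != "missing")
    if n_evaluable < min_evaluable:
        status = UNCLASSIFIABLE
    elif n_unstable >= 2:
        status = "MSI-H"
    elif n_unstable == 1:
        status = "MSI-L"
    else:
        status = "MSS"
    return MsiStatus(marker_calls.sample, status, n_unstable, n_evaluable)


def cohort_msi_table(statuses: Iterable[MsiStatus]) -> dict[str, int]:
    """Tally of samples per status (MSS, MSI-L, MSI-H, unclassifiable)."""
    counts = Counter(s.status for s in statuses)
    return {k: counts.get(k, 0) for k in ("MSS", "MSI-L", "MSI-H", UNCLASSIFIABLE)}


# ---------------------------------------------------------------------------
# Tabular I/O (marker-call table format: sample + one column per marker)

def read_marker_calls(path: str | Path) -> list[MsiMarkerCalls]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [m for m in PANEL if m not in df.columns]
    if missing:
        raise ValueError(f"marker-call table {path} lacks columns {missing}")
    out = []
    for _, row in df.iterrows():
        calls = {m: ("missing" if pd.isna(row[m]) else str(row[m])) for m in PANEL}
        out.append(MsiMarkerCalls(str(row["sample"]), calls))
    return out


def write_status_table(statuses: Iterable[MsiStatus], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample": s.sample, "msi": s.status,
             "n_unstable": s.n_unstable, "n_evaluable": s.n_evaluable}
            for s in statuses
        ]
    ).to_csv(path, sep="\t", index=False)
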