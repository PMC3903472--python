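"""Simplified genome model used by the simulator and the toy gene panels.

The analysis itself is coordinate-system agnostic (0-based, half-open
everywhere); this module only fixes a small, round-numbered reference so
that synthetic cohorts, probe tracks and the shipped gene panels live on a
common set of chromosomes without requiring any external genome build.
"""

from __future__ import annotations

# 22 autosomes + X at 10 Mb, Y at 5 Mb.  Round lengths keep probe grids and
# interval arithmetic easy to reason about in tests.
CHROMOSOMES: dict[str, int] = {f"chr{i}": 10_000_000 for i in range(1, 23)}
CHROMOSOMES["chrX"] = 10_000_000
CHROMOSOMES["chrY"] = 5_000_000

CHROM_ORDER: tuple[str, ...] = tuple(CHROMOSOMES)
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort chromosomes in karyotype order; unknown names go last, lexically."""
    return (_CHROM_RANK.get(chrom, len(CHROM_ORDER)), chrom)
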