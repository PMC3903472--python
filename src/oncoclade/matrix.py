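"""Binary specimens x aberrations character matrix ("polarity assessment").

Every aberration across all specimens is pooled, duplicates removed, and
each specimen scored 1 (aberration present, derived) or 0 (absent,
ancestral) against the pooled list.  Character identity defaults to the
exact canonical interval plus direction; a merge tolerance snaps interval
ends to a grid so near-identical breakpoints can be treated as the same
event, and a gene-level mode builds characters from (gene, direction)
pairs instead.  The matrix serializes to the discrete-character PHYLIP
dialect used by binary-parsimony programs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cgh import GeneAberrationCall, IntervalCall
from .genome import chrom_sort_key

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=False)
class AberrationKey:
    chrom: str
    start: int
    end: int
    direction: str
    label: str | None = None  # gene symbol in gene mode

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.start, self.end, self.direction)

    def __str__(self) -> str:
        core = f"{self.chrom}:{self.start}-{self.end}:{self.direction}"
        return f"{self.label}({core})" if self.label else core


def canonicalize(call: IntervalCall, merge_tolerance_bp: int = 0) -> AberrationKey:
    """Canonical character key for an interval call.  With a positive
    tolerance both coordinates are snapped to the tolerance grid, so calls
    whose breakpoints differ by less than half a grid step collapse to the
    same key; tolerance 0 requires exact identity."""
    if call.direction not in ("gain", "loss"):
        raise ValueError("canonicalize expects a direction-filtered call")
    start, end = call.start, call.end
    if merge_tolerance_bp > 0:
        t = merge_tolerance_bp
        start = int(round(start / t)) * t
        end = int(round(end / t)) * t
        if end <= start:
            end = start + t
    return AberrationKey(call.chrom, start, end, call.direction)


def gene_key(call: GeneAberrationCall, annotation_index: Mapping[str, tuple[str, int, int]]) -> AberrationKey:
    chrom, start, end = annotation_index[call.gene]
    return AberrationKey(chrom, start, end, call.direction, label=call.gene)


@dataclass
class BinaryCharacterMatrix:
    taxa: list[str]
    characters: list[AberrationKey]
    entries: np.ndarray  # shape (n_taxa, n_characters), dtype int8
    mode: str = "interval"

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("matrix shape does not match taxa/characters")
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("entries must be 0/1")
        if len(set(map(str, self.characters))) != len(self.characters):
            raise ValueError("duplicate characters")
        if self.characters and (self.entries.sum(axis=0) == 0).any():
            raise ValueError("all-absent character present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def column(self, j: int) -> np.ndarray:
        return self.entries[:, j]

    def character_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": range(len(self.characters)),
             "character": [str(k) for k in self.characters]}
        )


def build_matrix(
    per_sample_calls: Mapping[str, Iterable],
    merge_tolerance_bp: int = 0,
    mode: str = "interval",
    annotation=None,
) -> BinaryCharacterMatrix:
    """Pool all specimens' aberrations, deduplicate, and score each
    specimen 0/1 against the pooled character list.

    ``mode='interval'`` takes IntervalCall lists and keys characters by
    canonical interval + direction; ``mode='gene'`` takes
    GeneAberrationCall lists (requires ``annotation``) and keys by gene +
    direction.  Characters are sorted by (chrom, start, end, direction).
    """
    taxa = list(per_sample_calls)
    if len(taxa) < 3:
        raise ValueError("need at least 3 specimens to build a matrix for tree inference")
    key_sets: dict[str, set[AberrationKey]] = {}
    for taxon, calls in per_sample_calls.items():
        if mode == "interval":
            keys = {canonicalize(c, merge_tolerance_bp) for c in calls}
        elif mode == "gene":
            if annotation is None:
                raise ValueError("gene mode requires an annotation")
            idx = {g.gene: (g.chrom, g.start, g.end) for g in annotation}
            keys = {gene_key(c, idx) for c in calls}
        else:
            raise ValueError(f"unknown mode {mode!r}")
        key_sets[str(taxon)] = keys
    characters = sorted(set().union(*key_sets.values()), key=AberrationKey.sort_key)
    entries = np.zeros((len(taxa), len(characters)), dtype=np.int8)
    index = {k: j for j, k in enumerate(characters)}
    for i, taxon in enumerate(taxa):
        for k in key_sets[str(taxon)]:
            entries[i, index[k]] = 1
    log.info("built %s-mode matrix: %d taxa x %d characters", mode, len(taxa), len(characters))
    return BinaryCharacterMatrix(list(map(str, taxa)), characters, entries, mode=mode)


# ---------------------------------------------------------------------------
# PHYLIP discrete-character I/O

_NAME_WIDTH = 10


def sanitize_names(names: Iterable[str]) -> dict[str, str]:
    """Map taxon names to unique PHYLIP-safe names of <=10 characters.
    Colliding truncations are disambiguated with a numeric suffix; raises if
    a unique set cannot be built (e.g. duplicate inputs)."""
    names = list(names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names")
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        base = re.sub(r"[^A-Za-z0-9_.]", "_", name)[:_NAME_WIDTH]
        cand = base
        k = 1
        while cand in used:
            suffix = f"_{k}"
            cand = base[:_NAME_WIDTH - len(suffix)] + suffix
            k += 1
            if k > len(names) + 1:
                raise ValueError(f"cannot build a unique sanitized name for {name!r}")
        mapping[name] = cand
        used.add(cand)
    return mapping


def write_phylip_discrete(
    matrix: BinaryCharacterMatrix, path: str | Path
) -> dict[str, str]:
    """Write the matrix in discrete-character PHYLIP format: a 'ntax nchar'
    header, then one line per taxon (name padded to width 10 + 0/1 string).
    Returns the original->sanitized name mapping, also written alongside as
    ``<path>.names.tsv`` whenever any name changed."""
    mapping = sanitize_names(matrix.taxa)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {len(matrix.characters)}\n")
        for i, taxon in enumerate(matrix.taxa):
            row = "".join(map(str, matrix.entries[i]))
            fh.write(f"{mapping[taxon]:<{_NAME_WIDTH}}{row}\n")
    if any(k != v for k, v in mapping.items()):
        pd.DataFrame(
            {"name": list(mapping), "phylip_name": list(mapping.values())}
        ).to_csv(path.with_suffix(path.suffix + ".names.tsv"), sep="\t", index=False)
    return mapping


def read_phylip_discrete(path: str | Path) -> BinaryCharacterMatrix:
    """Read a discrete-character PHYLIP file back into a matrix.  Character
    metadata is not stored in the format, so characters are rebuilt as
    anonymous placeholder keys preserving order."""
    with open(path) as fh:
        ntax, nchar = map(int, fh.readline().split())
        taxa, rows = [], []
        for _ in range(ntax):
            line = fh.readline().rstrip("\n")
            taxa.append(line[:_NAME_WIDTH].strip())
            rows.append([int(ch) for ch in line[_NAME_WIDTH:].strip()])
    entries = np.array(rows, dtype=np.int8)
    if entries.shape != (ntax, nchar):
        raise ValueError(f"malformed PHYLIP matrix in {path}")
    characters = [
        AberrationKey("char", j, j + 1, "gain", label=f"c{j}") for j in range(nchar)
    ]
    return BinaryCharacterMatrix(taxa, characters, entries)


def write_character_map(matrix: BinaryCharacterMatrix, path: str | Path) -> None:
    matrix.character_map().to_csv(path, sep="\t", index=False)
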