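"""Grouping assays into gel-resolvable multiplex reactions.

Assays sharing a reaction must have expected amplicon lengths far enough
apart to call on an agarose gel (``min_separation``, default 50 bp).  The
partitioner returns the minimum feasible number of reactions subject to the
plex-size and separation constraints, with a deterministic canonical
layout: assays sorted by expected length are dealt round-robin across the
reactions, falling back to an exact backtracking search when the dealt
layout violates a constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .panel import TaxonLabel
from .primers import AssayDefinition, PrimerCandidate, gc_percent, tm_wallace


@dataclass(frozen=True)
class GelModel:
    min_separation: int = 50        # bp between co-migrating bands to resolve
    length_tolerance: int = 0       # bp slack when calling a band (0 = exact)

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.length_tolerance < 0:
            raise ValueError("length_tolerance must be >= 0")


@dataclass
class MultiplexScheme:
    reactions: list[list[AssayDefinition]]
    gel: GelModel
    plex_size: int

    def __post_init__(self) -> None:
        for rxn in self.reactions:
            if len(rxn) > self.plex_size:
                raise ValueError("reaction exceeds plex size")
            lens = sorted(a.expected_length for a in rxn)
            for lo, hi in zip(lens, lens[1:]):
                if hi - lo < self.gel.min_separation:
                    raise ValueError(
                        f"bands {lo} and {hi} are not resolvable "
                        f"(min separation {self.gel.min_separation})")

    @property
    def assays(self) -> list[AssayDefinition]:
        return [a for rxn in self.reactions for a in rxn]

    def reaction_of(self, taxon: TaxonLabel) -> int:
        for i, rxn in enumerate(self.reactions):
            if any(str(a.taxon) == str(taxon) for a in rxn):
                return i
        raise KeyError(f"no assay for taxon {taxon}")


class PartitionInfeasibleError(RuntimeError):
    """Assays cannot be partitioned within the allowed number of reactions."""


def _separated(lengths: Sequence[int], min_sep: int) -> bool:
    s = sorted(lengths)
    return all(b - a >= min_sep for a, b in zip(s, s[1:]))


def _exact_partition(lengths: Sequence[int], r: int, k: int, min_sep: int):
    """First feasible assignment of length-sorted items into r groups, or None.

    Items arrive in ascending length order, so each group only needs its
    last (largest) length for the separation check.  Symmetry is broken by
    allowing an item to open only the first empty group.
    """
    n = len(lengths)
    assign = [-1] * n
    counts = [0] * r
    last = [None] * r

    def place(i: int) -> bool:
        if i == n:
            return True
        opened_empty = False
        for g in range(r):
            if counts[g] == 0:
                if opened_empty:
                    continue
                opened_empty = True
            elif counts[g] >= k or lengths[i] - last[g] < min_sep:
                continue
            prev = last[g]
            counts[g] += 1
            last[g] = lengths[i]
            assign[i] = g
            if place(i + 1):
                return True
            counts[g] -= 1
            last[g] = prev
            assign[i] = -1
        return False

    return assign if place(0) else None


def partition_assays(assays: Sequence[AssayDefinition],
                     plex_size: int,
                     gel: GelModel | None = None,
                     max_reactions: int | None = None) -> MultiplexScheme:
    """Partition assays into the minimum number of resolvable reactions.

    Exact: for each candidate reaction count r (from ``ceil(n/plex_size)``
    upward) the round-robin deal of length-sorted assays is tried first and
    an exhaustive backtracking search second, so the returned reaction
    count is optimal.  Raises :class:`PartitionInfeasibleError` only if a
    caller-imposed ``max_reactions`` is exceeded.
    """
    gel = gel or GelModel()
    if plex_size < 1:
        raise ValueError("plex_size must be >= 1")
    assays = list(assays)
    if not assays:
        return MultiplexScheme([], gel, plex_size)
    taxa = [str(a.taxon) for a in assays]
    if len(set(taxa)) != len(taxa):
        raise ValueError("assays must have distinct taxa")

    ordered = sorted(assays, key=lambda a: (a.expected_length, str(a.taxon)))
    lengths = [a.expected_length for a in ordered]
    n = len(ordered)
    r_min = math.ceil(n / plex_size)
    r_max = max_reactions if max_reactions is not None else n
    for r in range(r_min, r_max + 1):
        # canonical round-robin deal
        groups: list[list[AssayDefinition]] = [[] for _ in range(r)]
        for i, a in enumerate(ordered):
            groups[i % r].append(a)
        if all(len(g) <= plex_size and
               _separated([a.expected_length for a in g], gel.min_separation)
               for g in groups):
            return MultiplexScheme([g for g in groups if g], gel, plex_size)
        assign = _exact_partition(lengths, r, plex_size, gel.min_separation)
        if assign is not None:
            groups = [[] for _ in range(r)]
            for i, g in enumerate(assign):
                groups[g].append(ordered[i])
            groups = [g for g in groups if g]
            groups.sort(key=lambda g: (g[0].expected_length, str(g[0].taxon)))
            return MultiplexScheme(groups, gel, plex_size)
    raise PartitionInfeasibleError(
        f"cannot partition {n} assays into <= {r_max} reactions of size {plex_size}")


def minimum_reaction_count(lengths: Sequence[int], plex_size: int, min_sep: int) -> int:
    """Optimal reaction count by exhaustive search over group assignments."""
    lens = sorted(lengths)
    n = len(lens)
    if n == 0:
        return 0
    for r in range(math.ceil(n / plex_size), n + 1):
        if _exact_partition(lens, r, plex_size, min_sep) is not None:
            return r
    return n


def render_ladder(scheme: MultiplexScheme) -> list[list[tuple[int, str]]]:
    """Per reaction, the expected band ladder: ascending (length, taxon) pairs."""
    out = []
    for rxn in scheme.reactions:
        out.append(sorted((a.expected_length, str(a.taxon)) for a in rxn))
    return out


def format_ladders(scheme: MultiplexScheme) -> str:
    lines = []
    for i, ladder in enumerate(render_ladder(scheme)):
        lines.append(f"reaction {chr(ord('A') + i)}:")
        for length, taxon in ladder:
            lines.append(f"  {length:>5} bp  {taxon}")
    return "\n".join(lines)


def write_scheme_tsv(scheme: MultiplexScheme, path: str | Path) -> None:
    rows = []
    for i, rxn in enumerate(scheme.reactions):
        for a in rxn:
            rows.append({"reaction_id": chr(ord("A") + i), "taxon": str(a.taxon),
                         "forward": a.forward.sequence, "reverse": a.reverse.sequence,
                         "expected_length": a.expected_length, "kind": a.kind})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scheme_tsv(path: str | Path, gel: GelModel | None = None) -> MultiplexScheme:
    df = pd.read_csv(path, sep="\t", dtype=str)
    gel = gel or GelModel()
    reactions: dict[str, list[AssayDefinition]] = {}
    for _, row in df.iterrows():
        fwd = PrimerCandidate(row["forward"], "+", 0,
                              tm_wallace(row["forward"]), gc_percent(row["forward"]))
        rev = PrimerCandidate(row["reverse"], "-", 0,
                              tm_wallace(row["reverse"]), gc_percent(row["reverse"]))
        assay = AssayDefinition(TaxonLabel.parse(row["taxon"]), fwd, rev,
                                int(row["expected_length"]), row.get("kind", "species_level"))
        reactions.setdefault(row["reaction_id"], []).append(assay)
    groups = [reactions[k] for k in sorted(reactions)]
    plex = max((len(g) for g in groups), default=1)
    return MultiplexScheme(groups, gel, plex)
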