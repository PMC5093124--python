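"""Virtual amplification: binding-site scanning, amplicon prediction, cross-reactivity.

Coordinates are 0-based half-open on the + strand of the template as given.
A primer binds the − strand where its reverse complement matches the +
strand; its 3' end then sits at the window *start*, so extension proceeds
leftward.  A forward/reverse site pair pointing toward each other yields an
amplicon spanning from the + strand site's start to the − strand site's end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _scan
from .panel import MarkerPanel, MarkerSequence, TaxonLabel
from .primers import AssayDefinition


@dataclass(frozen=True)
class MismatchPolicy:
    """Binding stringency; the default is the exact-match policy."""

    max_total_mismatches: int = 0
    anchor_len: int = 3
    max_anchor_mismatches: int = 0
    max_product_len: int = 3000

    def __post_init__(self) -> None:
        if self.anchor_len < 0:
            raise ValueError("anchor_len must be >= 0")
        if self.max_anchor_mismatches > self.max_total_mismatches:
            raise ValueError("anchor mismatches cannot exceed total mismatches")


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str                 # '+' or '-'
    start: int                  # on the + strand, half-open [start, end)
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    assay: AssayDefinition = field(compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


class AssayValidationError(RuntimeError):
    """An assay fails to amplify its own target at the given policy."""


def find_binding_sites(primer: str, template: str,
                       policy: MismatchPolicy | None = None,
                       template_id: str = "") -> list[BindingSite]:
    """All windows (both strands) the primer can bind under the policy.

    Template symbols may be degenerate; a primer base matches a template
    symbol iff their IUPAC expansions intersect.  A window qualifies when
    total mismatches ≤ ``max_total_mismatches`` and mismatches within the
    primer's 3'-terminal ``anchor_len`` bases ≤ ``max_anchor_mismatches``.
    """
    policy = policy or MismatchPolicy()
    if len(primer) > len(template):
        raise ValueError("primer longer than template")
    m = len(primer)
    mm_p, anc_p, mm_m, anc_m = _scan.window_mismatches(primer, template, policy.anchor_len)
    sites: list[BindingSite] = []
    ok_p = (mm_p <= policy.max_total_mismatches) & (anc_p <= policy.max_anchor_mismatches)
    ok_m = (mm_m <= policy.max_total_mismatches) & (anc_m <= policy.max_anchor_mismatches)
    for start in np.flatnonzero(ok_p | ok_m):
        s = int(start)
        if ok_p[s]:
            sites.append(BindingSite(template_id, "+", s, s + m, int(mm_p[s])))
        if ok_m[s]:
            sites.append(BindingSite(template_id, "-", s, s + m, int(mm_m[s])))
    return sites


def predict_amplicons(assay: AssayDefinition,
                      template: MarkerSequence | str,
                      policy: MismatchPolicy | None = None) -> list[Amplicon]:
    """All products the assay's primer pair predicts on a template.

    A product arises from any + strand site of one primer and any − strand
    site of the *other* primer ending strictly downstream, with length at
    most ``max_product_len``; both orientations (forward on +, reverse on −
    and the converse) are considered.  Duplicated intervals are merged.
    """
    policy = policy or MismatchPolicy()
    if isinstance(template, MarkerSequence):
        seq, tid = template.sequence, template.source_id
    else:
        seq, tid = template, ""
    if not seq:
        raise ValueError("empty template")

    def sites(primer: str) -> list[BindingSite]:
        if len(primer) > len(seq):
            return []
        return find_binding_sites(primer, seq, policy, tid)

    f_sites = sites(assay.forward.sequence)
    r_sites = sites(assay.reverse.sequence)
    plus = [("F", s) for s in f_sites if s.strand == "+"] + \
           [("R", s) for s in r_sites if s.strand == "+"]
    minus = [("F", s) for s in f_sites if s.strand == "-"] + \
            [("R", s) for s in r_sites if s.strand == "-"]

    seen: set[tuple[int, int]] = set()
    out: list[Amplicon] = []
    for p_tag, p in plus:
        for m_tag, m in minus:
            if p_tag == m_tag:
                continue
            if m.end <= p.end:
                continue
            length = m.end - p.start
            if length > policy.max_product_len:
                continue
            key = (p.start, m.end)
            if key not in seen:
                seen.add(key)
                out.append(Amplicon(tid, p.start, m.end, assay))
    out.sort(key=lambda a: (a.start, a.end))
    return out


@dataclass
class CrossReactivityMatrix:
    """Predicted amplicon lengths of every assay against every panel taxon."""

    assays: list[AssayDefinition]
    taxa: list[TaxonLabel]
    cells: dict[tuple[int, int], list[int]]     # (assay idx, taxon idx) -> lengths

    def lengths(self, assay_idx: int, taxon_idx: int) -> list[int]:
        return self.cells.get((assay_idx, taxon_idx), [])

    def off_diagonal_hits(self) -> list[tuple[AssayDefinition, TaxonLabel, list[int]]]:
        out = []
        for (i, j), lens in sorted(self.cells.items()):
            if str(self.assays[i].taxon) != str(self.taxa[j]) and lens:
                out.append((self.assays[i], self.taxa[j], lens))
        return out

    def to_frame(self) -> pd.DataFrame:
        data = []
        for i, a in enumerate(self.assays):
            row = {}
            for j, t in enumerate(self.taxa):
                lens = self.lengths(i, j)
                row[str(t)] = ",".join(map(str, lens)) if lens else "-"
            data.append(row)
        return pd.DataFrame(data, index=[str(a.taxon) for a in self.assays])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def cross_reactivity(assays: Sequence[AssayDefinition],
                     panel: MarkerPanel,
                     policy: MismatchPolicy | None = None,
                     validate: bool = True) -> CrossReactivityMatrix:
    """Run every assay against every taxon's sequences.

    With ``validate=True`` (default) an assay whose own-taxon cell does not
    contain its expected length raises :class:`AssayValidationError` — the
    panel-level closure check that each assay amplifies its target.
    """
    policy = policy or MismatchPolicy()
    taxa = panel.taxa
    taxa_str = {str(t): j for j, t in enumerate(taxa)}
    cells: dict[tuple[int, int], list[int]] = {}
    for i, assay in enumerate(assays):
        if str(assay.taxon) not in taxa_str and str(assay.taxon.species_label) not in taxa_str:
            raise ValueError(f"panel does not cover assay taxon {assay.taxon}")
        for j, taxon in enumerate(taxa):
            lengths: list[int] = []
            for entry in panel.sequences_of(taxon):
                lengths.extend(a.length for a in predict_amplicons(assay, entry, policy))
            cells[(i, j)] = sorted(lengths)
        if validate:
            j = taxa_str.get(str(assay.taxon), taxa_str.get(str(assay.taxon.species_label)))
            if assay.expected_length not in cells[(i, j)]:
                raise AssayValidationError(
                    f"assay for {assay.taxon} fails its own target: expected "
                    f"{assay.expected_length}, predicted {cells[(i, j)]}")
    return CrossReactivityMatrix(list(assays), taxa, cells)
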