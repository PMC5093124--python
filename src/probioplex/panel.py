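"""Marker-gene panels: parsing, alignment, degenerate consensus, identity matrices.

A *marker panel* is a collection of marker-gene sequences (e.g. pgi or 16S
rRNA genes) grouped by species or sub-species.  Within each taxon the
sequences are aligned and collapsed into a degenerate consensus in which
every IUPAC symbol expands to exactly the set of bases observed at that
column, so the consensus represents the within-taxon variation at 100%
sequence identity.  Between taxa, percent-identity matrices summarise how
much discriminating signal a locus offers.
"""

from __future__ import annotations

import io
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from . import _iupac

Locus = Literal["pgi", "16S", "other"]

# Alignment scoring used throughout the package: match +2, mismatch -1,
# gap -2 (linear, terminal gaps penalized like internal ones).
MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_SCORE = -2


@dataclass(frozen=True, order=True)
class TaxonLabel:
    """Species / sub-species / strain identity of a panel member."""

    genus: str
    species: str
    subspecies: str | None = None
    strain: str | None = None

    def __post_init__(self) -> None:
        if not self.genus or not self.species:
            raise ValueError("genus and species must be non-empty")

    def __str__(self) -> str:
        parts = [self.genus, self.species]
        if self.strain:
            parts.append(self.subspecies or ".")   # '.' keeps parse() a round-trip
            parts.append(self.strain)
        elif self.subspecies:
            parts.append(self.subspecies)
        return " ".join(parts)

    @property
    def species_label(self) -> "TaxonLabel":
        """The label with any strain designation dropped."""
        return TaxonLabel(self.genus, self.species, self.subspecies)

    @classmethod
    def parse(cls, text: str) -> "TaxonLabel":
        """Parse 'Genus species [subspecies] [strain]'; '.' marks an absent field."""
        tokens = [t for t in text.split() if t]
        if len(tokens) < 2 or len(tokens) > 4:
            raise ValueError(f"cannot parse taxon label from {text!r}")
        none_if_dot = lambda t: None if t == "." else t
        sub = none_if_dot(tokens[2]) if len(tokens) > 2 else None
        strain = none_if_dot(tokens[3]) if len(tokens) > 3 else None
        return cls(tokens[0], tokens[1], sub, strain)


@dataclass(frozen=True)
class MarkerSequence:
    taxon: TaxonLabel
    locus: Locus
    sequence: str
    source_id: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.source_id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"record {self.source_id!r}: invalid symbols {sorted(bad)} "
                "(sequences must be uppercase DNA over A,C,G,T,N)"
            )


@dataclass
class MarkerPanel:
    """Marker sequences of one locus, grouped by taxon."""

    entries: list[MarkerSequence]
    locus: Locus

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("panel must contain at least one sequence")
        off = [e for e in self.entries if e.locus != self.locus]
        if off:
            raise ValueError(f"entry {off[0].source_id!r} has locus {off[0].locus!r}, panel is {self.locus!r}")

    @property
    def taxa(self) -> list[TaxonLabel]:
        seen: "OrderedDict[TaxonLabel, None]" = OrderedDict()
        for e in self.entries:
            seen.setdefault(e.taxon, None)
        return list(seen)

    def sequences_of(self, taxon: TaxonLabel) -> list[MarkerSequence]:
        return [e for e in self.entries if e.taxon == taxon]

    def subset(self, taxa: Iterable[TaxonLabel]) -> "MarkerPanel":
        wanted = set(taxa)
        kept = [e for e in self.entries if e.taxon in wanted]
        return MarkerPanel(kept, self.locus)


@dataclass
class ConsensusProfile:
    """Per-taxon degenerate consensus; '-' marks columns gapped in >=1 sequence."""

    taxon: TaxonLabel
    consensus: str
    column_support: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class IdentityMatrix:
    taxa: list[TaxonLabel]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        if v.min() < 0 or v.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def mean_offdiagonal(self) -> float:
        n = len(self.taxa)
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        labels = [str(t) for t in self.taxa]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.2f")


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def read_marker_fasta(path: str | Path, locus: Locus) -> MarkerPanel:
    """Read a marker FASTA whose headers carry the taxon annotation.

    Header dialect: ``>Genus species [subspecies] [strain]|id`` — the text
    before the last ``|`` is the space-separated taxon label ('.' for an
    absent subspecies when a strain follows), the text after it the source
    accession/identifier.  Sequences are upper-cased and U is mapped to T.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    entries = []
    for rec in records:
        header = rec.description.strip()
        if "|" not in header:
            raise ValueError(f"record {header!r}: missing '|id' suffix in header")
        taxon_text, _, source_id = header.rpartition("|")
        try:
            taxon = TaxonLabel.parse(taxon_text)
        except ValueError as exc:
            raise ValueError(f"record {header!r}: {exc}") from None
        seq = str(rec.seq).upper().replace("U", "T")
        try:
            entries.append(MarkerSequence(taxon, locus, seq, source_id.strip()))
        except ValueError as exc:
            raise ValueError(str(exc)) from None
    return MarkerPanel(entries, locus)


def write_marker_fasta(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in panel.entries:
            fh.write(f">{e.taxon}|{e.source_id}\n{e.sequence}\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


_ALIGNER = _make_aligner()


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Optimal global alignment of two sequences (match +2, mismatch -1, gap -2)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    al = _ALIGNER.align(a, b)[0]
    return str(al[0]), str(al[1])


def alignment_score(a_gapped: str, b_gapped: str) -> int:
    """Score of a gapped alignment under the package scoring scheme."""
    score = 0
    for x, y in zip(a_gapped, b_gapped):
        if x == "-" or y == "-":
            score += GAP_SCORE
        elif x == y:
            score += MATCH_SCORE
        else:
            score += MISMATCH_SCORE
    return score


def align_marker_set(sequences: Sequence[str]) -> list[str]:
    """Multiple alignment by center-star progressive merging.

    The center is the sequence maximising the sum of pairwise alignment
    scores against all others; every other sequence is aligned to it and
    the pairwise alignments are merged on the center's coordinates
    ("once a gap, always a gap").  De-gapping output *i* reproduces
    input *i*.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    if any(not s for s in seqs):
        raise ValueError("sequences must be non-empty")
    if len(seqs) == 1:
        return [seqs[0]]
    if len(seqs) == 2:
        return list(align_pair(seqs[0], seqs[1]))

    n = len(seqs)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = _ALIGNER.score(seqs[i], seqs[j])
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))

    center_seq = seqs[center]
    L = len(center_seq)
    # For each non-center sequence record, per center-residue slot k (0..L,
    # slot L = after the last residue): the run of seq characters inserted
    # there, and per residue k the character aligned to it ('-' or a base).
    others: list[tuple[list[str], list[str]]] = []
    for j in range(n):
        if j == center:
            continue
        c_gapped, s_gapped = align_pair(center_seq, seqs[j])
        ins: list[str] = ["" for _ in range(L + 1)]
        paired: list[str] = []
        k = 0
        for cc, sc in zip(c_gapped, s_gapped):
            if cc == "-":
                ins[k] += sc
            else:
                paired.append(sc)
                k += 1
        others.append((ins, paired))

    max_ins = [max(len(ins[k]) for ins, _ in others) for k in range(L + 1)]

    def render(ins: list[str] | None, paired: list[str] | None) -> str:
        out: list[str] = []
        for k in range(L + 1):
            run = ins[k] if ins is not None else ""
            out.append(run + "-" * (max_ins[k] - len(run)))
            if k < L:
                out.append(paired[k] if paired is not None else center_seq[k])
        return "".join(out)

    out_rows: list[str] = []
    it = iter(others)
    for j in range(n):
        if j == center:
            out_rows.append(render(None, None))
        else:
            ins, paired = next(it)
            out_rows.append(render(ins, paired))
    return out_rows


# ---------------------------------------------------------------------------
# Consensus and identity
# ---------------------------------------------------------------------------

def build_consensus(aligned: Sequence[str], taxon: TaxonLabel) -> ConsensusProfile:
    """Collapse an alignment into a degenerate consensus.

    Per column the consensus symbol is the unique IUPAC code expanding to
    exactly the set of bases observed (N in any input yields N).  Columns
    gapped in at least one sequence are recorded as '-' and are ineligible
    for primer placement.
    """
    rows = list(aligned)
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows must have equal length")
    symbols: list[str] = []
    support = np.zeros(width, dtype=int)
    for i in range(width):
        col = [r[i] for r in rows]
        bases = {b for b in col if b != "-"}
        support[i] = len(col) - col.count("-")
        if not bases:
            raise ValueError(f"column {i} contains only gaps")
        if "-" in col:
            symbols.append("-")
        elif "N" in bases:
            symbols.append("N")
        else:
            symbols.append(_iupac.code_for(frozenset(bases)))
    return ConsensusProfile(taxon, "".join(symbols), support)


def consensus_for_taxon(panel: MarkerPanel, taxon: TaxonLabel) -> ConsensusProfile:
    seqs = [e.sequence for e in panel.sequences_of(taxon)]
    if not seqs:
        raise ValueError(f"taxon {taxon} not in panel")
    return build_consensus(align_marker_set(seqs), taxon)


def write_consensus_fasta(profiles: Iterable[ConsensusProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(f">{p.taxon}\n{p.consensus}\n")


def percent_identity(a: str, b: str) -> float:
    """Percent identity over the optimal global alignment (gaps count as mismatches)."""
    ga, gb = align_pair(a, b)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return 100.0 * matches / len(ga)


def identity_matrix(panel: MarkerPanel, representative: str = "first") -> IdentityMatrix:
    """Cross-taxon percent-identity matrix with one representative per taxon.

    `representative`: "first" uses each taxon's first panel sequence;
    "consensus" uses the degenerate within-taxon consensus (identities then
    compare IUPAC strings symbol-wise).
    """
    taxa = panel.taxa
    if len(taxa) < 2:
        raise ValueError("identity matrix needs at least two taxa")
    if representative == "first":
        reps = [panel.sequences_of(t)[0].sequence for t in taxa]
    elif representative == "consensus":
        reps = [consensus_for_taxon(panel, t).consensus.replace("-", "") for t in taxa]
    else:
        raise ValueError(f"unknown representative mode {representative!r}")
    n = len(taxa)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(reps[i], reps[j])
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(taxa, values)
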