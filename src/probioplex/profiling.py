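"""16S-V4 relative-abundance profiling of amplicon reads.

Pipeline: merge read pairs on their best overlap, drop reads with any
ambiguous base or a Phred quality below 30, dereplicate at 100% identity
(each distinct sequence is one OTU), assign each OTU to the type-strain
group with the highest global-alignment percent identity (references whose
V4 sequences are identical are collapsed into one group beforehand),
discard OTUs at or below 0.1% of total reads, and report per-sample
percent abundance by taxon group.  Two summary regressions mirror the
standard-curve and rank-abundance analyses: percent reads on log10 CFU,
and mean abundance on ln(rank).
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from ._iupac import reverse_complement
from .panel import TaxonLabel, percent_identity


@dataclass(frozen=True)
class Read:
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality must have equal length")
        if self.quality and not (0 <= min(self.quality) and max(self.quality) <= 60):
            raise ValueError("Phred scores must lie in [0, 60]")


@dataclass
class ReadSet:
    sample_id: str
    reads: list[Read]

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class ReferenceGroup:
    taxon_group: str
    member_taxa: frozenset[TaxonLabel]
    v4_sequence: str


@dataclass
class ReferenceSet:
    entries: list[ReferenceGroup]

    def __post_init__(self) -> None:
        seqs = [e.v4_sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("reference V4 sequences must be unique per group")

    def group_of(self, taxon: TaxonLabel) -> str:
        for e in self.entries:
            if taxon in e.member_taxa:
                return e.taxon_group
        raise KeyError(f"no reference group contains {taxon}")


def build_reference_set(references: Iterable[tuple[TaxonLabel, str]]) -> ReferenceSet:
    """Collapse taxa with identical V4 sequences into indistinguishable groups."""
    by_seq: "OrderedDict[str, set[TaxonLabel]]" = OrderedDict()
    for taxon, seq in references:
        by_seq.setdefault(seq, set()).add(taxon)
    entries = []
    for seq, taxa in by_seq.items():
        name = "|".join(sorted(str(t) for t in taxa))
        entries.append(ReferenceGroup(name, frozenset(taxa), seq))
    return ReferenceSet(entries)


@dataclass
class OTU:
    sequence: str
    counts: dict[str, int]                 # sample_id -> read count
    taxon_group: str | None = None
    identity: float | None = None
    ambiguous: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class OTUTable:
    otus: list[OTU]
    samples: list[str]

    def totals(self) -> dict[str, int]:
        out = {s: 0 for s in self.samples}
        for otu in self.otus:
            for s, c in otu.counts.items():
                out[s] += c
        return out

    @property
    def grand_total(self) -> int:
        return sum(self.totals().values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, otu in enumerate(self.otus):
            row = {"otu": f"otu{i + 1}", "taxon_group": otu.taxon_group or "",
                   "identity": otu.identity if otu.identity is not None else "",
                   "sequence": otu.sequence}
            for s in self.samples:
                row[s] = otu.counts.get(s, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")


# ---------------------------------------------------------------------------
# FASTQ IO (Phred+33)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path, sample_id: str | None = None) -> ReadSet:
    sample_id = sample_id or Path(path).stem
    reads = [Read(str(rec.seq).upper(),
                  tuple(rec.letter_annotations["phred_quality"]))
             for rec in SeqIO.parse(str(path), "fastq")]
    return ReadSet(sample_id, reads)


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    records = []
    for i, r in enumerate(readset.reads):
        rec = SeqRecord(Seq(r.sequence), id=f"{readset.sample_id}.{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Stage 1: pair merging
# ---------------------------------------------------------------------------

@dataclass
class MergeResult:
    reads: ReadSet
    n_pairs: int
    n_merged: int
    n_dropped: int


def merge_pairs(forward: ReadSet, reverse: ReadSet,
                min_overlap: int = 20,
                max_overlap_mismatch_frac: float = 0.25) -> MergeResult:
    """Merge mate pairs on their best ungapped overlap.

    The reverse read is reverse-complemented and slid against the forward
    read; the overlap maximising (matches − mismatches), with at least
    ``min_overlap`` columns and a mismatch fraction at most
    ``max_overlap_mismatch_frac``, wins (longer overlap on score ties).
    Disagreeing overlap bases take the higher-quality base (forward wins
    quality ties); pairs with no acceptable overlap are dropped.
    """
    if len(forward.reads) != len(reverse.reads):
        raise ValueError("mate lists must have equal length and order")
    n_pairs = len(forward.reads)
    merged_by_index: dict[int, Read] = {}

    # batch reads by mate lengths so the overlap search is vectorised
    groups: dict[tuple[int, int], list[int]] = {}
    for i, (f, r) in enumerate(zip(forward.reads, reverse.reads)):
        groups.setdefault((len(f.sequence), len(r.sequence)), []).append(i)

    for (lf, lr), idxs in groups.items():
        top = min(lf, lr)
        if top < min_overlap or lf == 0 or lr == 0:
            continue
        N = len(idxs)
        F = np.frombuffer("".join(forward.reads[i].sequence for i in idxs).encode(),
                          dtype=np.uint8).reshape(N, lf)
        FQ = np.array([forward.reads[i].quality for i in idxs], dtype=np.int16)
        RC = np.frombuffer("".join(reverse_complement(reverse.reads[i].sequence)
                                   for i in idxs).encode(),
                           dtype=np.uint8).reshape(N, lr)
        RQ = np.array([reverse.reads[i].quality[::-1] for i in idxs], dtype=np.int16)

        best_score = np.full(N, -(10 ** 9), dtype=np.int64)
        best_o = np.zeros(N, dtype=np.int64)
        # descending overlap: a shorter overlap scores at most its own
        # length, so reads whose best score already reaches o are settled
        for o in range(top, min_overlap - 1, -1):
            active = best_score < o
            if not active.any():
                break
            mm = (F[:, lf - o:] != RC[:, :o]).sum(axis=1)
            score = o - 2 * mm
            upd = active & (mm <= max_overlap_mismatch_frac * o) & (score > best_score)
            best_score[upd] = score[upd]
            best_o[upd] = o
        for k in np.flatnonzero(best_o):
            o = int(best_o[k])
            split = lf - o
            fa, fq = F[k, split:], FQ[k, split:]
            ra, rq = RC[k, :o], RQ[k, :o]
            take_f = (fa == ra) | (fq >= rq)
            mid = np.where(take_f, fa, ra)
            seq = (F[k, :split].tobytes() + mid.astype(np.uint8).tobytes()
                   + RC[k, o:].tobytes()).decode()
            qual = (list(map(int, FQ[k, :split])) + list(map(int, np.maximum(fq, rq)))
                    + list(map(int, RQ[k, o:])))
            merged_by_index[idxs[k]] = Read(seq, tuple(qual))

    merged = [merged_by_index[i] for i in sorted(merged_by_index)]
    reads = ReadSet(forward.sample_id, merged)
    return MergeResult(reads, n_pairs, len(merged), n_pairs - len(merged))


# ---------------------------------------------------------------------------
# Stage 2: quality filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    reads: ReadSet
    n_retained: int
    n_removed: int


def quality_filter(reads: ReadSet, min_q: int = 30) -> FilterResult:
    """Drop reads containing any ambiguous base or any quality below ``min_q``."""
    kept = [r for r in reads.reads
            if "N" not in r.sequence and (not r.quality or min(r.quality) >= min_q)]
    return FilterResult(ReadSet(reads.sample_id, kept),
                        len(kept), len(reads.reads) - len(kept))


# ---------------------------------------------------------------------------
# Stage 3: dereplication (100% identity OTUs)
# ---------------------------------------------------------------------------

def dereplicate(readsets: ReadSet | Sequence[ReadSet]) -> OTUTable:
    """Collapse identical sequences into OTUs with per-sample counts."""
    if isinstance(readsets, ReadSet):
        readsets = [readsets]
    samples = [rs.sample_id for rs in readsets]
    counts: "OrderedDict[str, dict[str, int]]" = OrderedDict()
    for rs in readsets:
        for r in rs.reads:
            per = counts.setdefault(r.sequence, {})
            per[rs.sample_id] = per.get(rs.sample_id, 0) + 1
    otus = [OTU(seq, per) for seq, per in counts.items()]
    otus.sort(key=lambda o: (-o.total, o.sequence))
    return OTUTable(otus, samples)


# ---------------------------------------------------------------------------
# Stage 4: type-strain assignment
# ---------------------------------------------------------------------------

def assign_taxonomy(table: OTUTable, refs: ReferenceSet) -> OTUTable:
    """Assign each OTU to its best-identity reference group.

    Identity is percent identity over the optimal global alignment against
    each group's V4 sequence, taking the better of the two read
    orientations.  An exact tie across groups assigns the union of the
    tied groups and flags the OTU ambiguous.
    """
    if not refs.entries:
        raise ValueError("reference set is empty")
    for otu in table.otus:
        best_ident = -1.0
        best_groups: list[str] = []
        for ref in refs.entries:
            ident = max(percent_identity(otu.sequence, ref.v4_sequence),
                        percent_identity(reverse_complement(otu.sequence), ref.v4_sequence))
            if ident > best_ident + 1e-9:
                best_ident = ident
                best_groups = [ref.taxon_group]
            elif abs(ident - best_ident) <= 1e-9:
                best_groups.append(ref.taxon_group)
        otu.identity = best_ident
        otu.ambiguous = len(best_groups) > 1
        otu.taxon_group = "|".join(sorted(best_groups))
    return table


# ---------------------------------------------------------------------------
# Stage 5: minor-OTU filter and abundance
# ---------------------------------------------------------------------------

@dataclass
class MinorFilterResult:
    table: OTUTable
    removed_otus: int
    removed_reads: int


def filter_minor(table: OTUTable, min_frac: float = 0.001,
                 per_sample: bool = False) -> MinorFilterResult:
    """Keep OTUs strictly above ``min_frac`` of the total read count.

    The fraction is taken over the grand total across all samples by
    default ("more than 0.1% of total reads"); ``per_sample=True`` keeps an
    OTU if it clears the threshold in any single sample instead.
    """
    grand = table.grand_total
    totals = table.totals()
    kept, removed = [], []
    for otu in table.otus:
        if per_sample:
            keep = any(totals[s] and c / totals[s] > min_frac
                       for s, c in otu.counts.items())
        else:
            keep = grand > 0 and otu.total / grand > min_frac
        (kept if keep else removed).append(otu)
    return MinorFilterResult(OTUTable(kept, table.samples),
                             len(removed), sum(o.total for o in removed))


def relative_abundance(table: OTUTable, min_reads: int = 1) -> pd.DataFrame:
    """Per-sample percent abundance by taxon group (columns sum to 100).

    Samples whose retained reads fall below ``min_reads`` are excluded with
    a warning (the study-scale default for a MiSeq run is 10,000 reads;
    the package default only drops empty samples).
    """
    totals = table.totals()
    groups = sorted({o.taxon_group or "unassigned" for o in table.otus})
    data: dict[str, dict[str, float]] = {}
    for s in table.samples:
        if totals[s] < max(min_reads, 1):
            warnings.warn(f"sample {s!r} has {totals[s]} retained reads; excluded")
            continue
        col = {g: 0.0 for g in groups}
        for otu in table.otus:
            col[otu.taxon_group or "unassigned"] += otu.counts.get(s, 0)
        data[s] = {g: 100.0 * c / totals[s] for g, c in col.items()}
    return pd.DataFrame(data, index=groups).fillna(0.0)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if np.allclose(y, y[0]):
        return RegressionResult(0.0, float(y[0]), 1.0, len(x))
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), len(x))


def cfu_read_regression(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of percent reads on log10 CFU over a standard dilution series."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("log10 CFU predictor has zero variance")
    return _ols(x, y)


def rank_abundance_fit(mean_abundances: Sequence[float]) -> RegressionResult:
    """OLS of mean abundance on ln(rank), ranks 1..m.

    A decreasing-logarithmic abundance profile a − b·ln(rank) fits exactly
    with slope −b; a negative slope is the signature of the strongly
    skewed blends the rank-abundance analysis describes.
    """
    m = len(mean_abundances)
    if m < 3:
        raise ValueError("need at least 3 ranks")
    x = np.log(np.arange(1, m + 1, dtype=float))
    y = np.asarray(mean_abundances, dtype=float)
    return _ols(x, y)


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class ProfileRun:
    table: OTUTable
    abundance: pd.DataFrame                 # after the minor-OTU filter
    abundance_unfiltered: pd.DataFrame      # before it (all assigned OTUs)
    stage_counts: dict[str, dict[str, int]]


def profile_samples(pairs: Sequence[tuple[ReadSet, ReadSet]],
                    refs: ReferenceSet,
                    min_overlap: int = 20,
                    max_overlap_mismatch_frac: float = 0.25,
                    min_q: int = 30,
                    min_frac: float = 0.001,
                    min_reads: int = 10_000) -> ProfileRun:
    """Full profiler: merge, filter, dereplicate, assign, minor-filter, summarise."""
    filtered: list[ReadSet] = []
    stage_counts: dict[str, dict[str, int]] = {}
    for fwd, rev in pairs:
        merged = merge_pairs(fwd, rev, min_overlap, max_overlap_mismatch_frac)
        qf = quality_filter(merged.reads, min_q)
        filtered.append(qf.reads)
        stage_counts[fwd.sample_id] = {
            "pairs": merged.n_pairs, "merged": merged.n_merged,
            "merge_dropped": merged.n_dropped,
            "quality_retained": qf.n_retained, "quality_removed": qf.n_removed,
        }
    table = dereplicate(filtered)
    table = assign_taxonomy(table, refs)
    minor = filter_minor(table, min_frac)
    for s in table.samples:
        stage_counts[s]["minor_removed_reads"] = minor.removed_reads
    abundance = relative_abundance(minor.table, min_reads=min_reads)
    abundance_unfiltered = relative_abundance(table, min_reads=min_reads)
    return ProfileRun(minor.table, abundance, abundance_unfiltered, stage_counts)
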