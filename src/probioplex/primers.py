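"""Discriminative primer design on degenerate taxon consensuses.

Candidates are enumerated inside within-taxon conserved (degeneracy-free)
consensus windows, screened for composition (GC, Wallace Tm) and secondary
structure (hairpin / self-dimer run lengths), scored for discrimination
against every non-target taxon by exhaustive IUPAC-aware window scanning,
and combined into one assay — a forward/reverse pair with an expected
amplicon length — per taxon using an explicit lexicographic objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _scan
from ._iupac import UNAMBIGUOUS, is_unambiguous, reverse_complement
from .panel import ConsensusProfile, MarkerPanel, TaxonLabel, consensus_for_taxon

_WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class DesignParams:
    """Screening thresholds for candidate enumeration and pairing.

    Lengths in nucleotides, Tm in °C (Wallace rule), GC in percent,
    amplicon lengths in bp.  A candidate fails the hairpin screen when its
    longest self-complementary run reaches ``max_self_comp_run`` or a run
    anchored at its 3' end reaches ``max_3prime_comp_run``; the same run
    thresholds screen cross-dimers between pair members.
    """

    primer_len_range: tuple[int, int] = (18, 25)
    gc_range: tuple[float, float] = (40.0, 60.0)
    tm_range: tuple[float, float] = (50.0, 70.0)
    amplicon_len_range: tuple[int, int] = (100, 1000)
    max_self_comp_run: int = 8
    max_3prime_comp_run: int = 5
    three_prime_anchor: int = 3

    def __post_init__(self) -> None:
        for lo, hi in (self.primer_len_range, self.gc_range,
                       self.tm_range, self.amplicon_len_range):
            if lo > hi:
                raise ValueError("parameter ranges must be non-empty")
        if self.three_prime_anchor > self.primer_len_range[0]:
            raise ValueError("3' anchor cannot exceed the minimum primer length")


@dataclass(frozen=True)
class PrimerCandidate:
    """An exact (non-degenerate) primer window on a taxon consensus.

    `start` is the 0-based position of the window on the consensus; for a
    − strand candidate the stored sequence is the reverse complement of
    the consensus window, written 5'→3'.
    """

    sequence: str
    strand: str            # '+' or '-'
    start: int
    tm: float
    gc: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not is_unambiguous(self.sequence):
            raise ValueError("primer sequence must be unambiguous DNA")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class AssayDefinition:
    """One taxon's primer pair and the amplicon length it predicts."""

    taxon: TaxonLabel
    forward: PrimerCandidate
    reverse: PrimerCandidate
    expected_length: int
    kind: str = "species_level"     # or "strain_level"

    def __post_init__(self) -> None:
        if self.kind not in ("species_level", "strain_level"):
            raise ValueError(f"unknown assay kind {self.kind!r}")
        if self.forward.strand != "+" or self.reverse.strand != "-":
            raise ValueError("forward primer must be on '+', reverse on '-'")
        if self.expected_length <= 0:
            raise ValueError("expected_length must be positive")


class DesignInfeasibleError(RuntimeError):
    """No primer pair discriminates the target from every off-target taxon."""


# ---------------------------------------------------------------------------
# Elementary screens
# ---------------------------------------------------------------------------

def tm_wallace(sequence: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) °C."""
    if not sequence:
        raise ValueError("empty sequence")
    if not is_unambiguous(sequence):
        raise ValueError("Tm is defined for unambiguous sequences only")
    at = sequence.count("A") + sequence.count("T")
    return float(2 * at + 4 * (len(sequence) - at))


def gc_percent(sequence: str) -> float:
    if not sequence:
        raise ValueError("empty sequence")
    return 100.0 * (sequence.count("G") + sequence.count("C")) / len(sequence)


def complementarity_run(a: str, b: str) -> dict[str, int]:
    """Longest Watson–Crick complementary run between `a` and reverse(`b`).

    Models antiparallel annealing: `a` 5'→3' is slid over `b` 3'→5' at every
    ungapped offset.  ``max_run`` is the longest contiguous complementary
    stretch over all offsets; ``three_prime_run_a`` the longest such stretch
    that includes a's 3'-terminal base.  ``complementarity_run(a, a)`` is the
    hairpin / self-dimer check.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    rb = b[::-1]
    na, nb = len(a), len(rb)
    max_run = 0
    three_prime = 0
    for shift in range(-(nb - 1), na):
        run = 0
        for i in range(max(0, shift), min(na, shift + nb)):
            if (a[i], rb[i - shift]) in _WC_PAIRS:
                run += 1
                if run > max_run:
                    max_run = run
                if i == na - 1 and run > three_prime:
                    three_prime = run
            else:
                run = 0
    return {"max_run": max_run, "three_prime_run_a": three_prime}


def passes_hairpin_screen(sequence: str, params: DesignParams) -> bool:
    r = complementarity_run(sequence, sequence)
    return (r["max_run"] < params.max_self_comp_run
            and r["three_prime_run_a"] < params.max_3prime_comp_run)


def passes_dimer_screen(a: str, b: str, params: DesignParams) -> bool:
    ab = complementarity_run(a, b)
    ba = complementarity_run(b, a)
    return (ab["max_run"] < params.max_self_comp_run
            and ab["three_prime_run_a"] < params.max_3prime_comp_run
            and ba["three_prime_run_a"] < params.max_3prime_comp_run)


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(profile: ConsensusProfile,
                         params: DesignParams | None = None) -> list[PrimerCandidate]:
    """All primer windows on a consensus passing every single-primer screen.

    Windows containing any degenerate or gap symbol are skipped (the primer
    must sit in a within-taxon fully conserved region).  Both strands are
    enumerated; ordering is (start, length, strand) with '+' first.
    """
    params = params or DesignParams()
    cons = profile.consensus
    if not cons:
        raise ValueError("empty consensus")
    lo, hi = params.primer_len_range
    out: list[PrimerCandidate] = []

    # longest clean (ACGT-only) stretches, then windows inside them
    clean = np.fromiter((c in UNAMBIGUOUS for c in cons), dtype=bool, count=len(cons))
    for start in range(len(cons)):
        if not clean[start]:
            continue
        for length in range(lo, hi + 1):
            stop = start + length
            if stop > len(cons) or not clean[start:stop].all():
                break
            window = cons[start:stop]
            for strand in "+-":
                seq = window if strand == "+" else reverse_complement(window)
                gc = gc_percent(seq)
                if not params.gc_range[0] <= gc <= params.gc_range[1]:
                    continue
                tm = tm_wallace(seq)
                if not params.tm_range[0] <= tm <= params.tm_range[1]:
                    continue
                if not passes_hairpin_screen(seq, params):
                    continue
                out.append(PrimerCandidate(seq, strand, start, tm, gc))
    return out


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def specificity_profile(candidate: PrimerCandidate | str,
                        offtargets: MarkerPanel,
                        anchor_len: int = 3) -> dict[TaxonLabel, dict[str, int]]:
    """Best off-target hit of a primer per taxon, by exhaustive window scan.

    For each off-target taxon: the minimum Hamming mismatch count of the
    primer against every same-length window of every sequence, on both
    strands (IUPAC-aware on the template side), plus the mismatch count
    within the primer's 3'-terminal anchor at that best window (ties over
    equally good windows resolved toward the fewest anchor mismatches —
    the most amplification-prone interpretation).
    """
    seq = candidate.sequence if isinstance(candidate, PrimerCandidate) else candidate
    if not offtargets.entries:
        raise ValueError("off-target panel is empty")
    result: dict[TaxonLabel, dict[str, int]] = {}
    for taxon in offtargets.taxa:
        best: tuple[int, int] | None = None
        for entry in offtargets.sequences_of(taxon):
            mm_p, anc_p, mm_m, anc_m = _scan.window_mismatches(seq, entry.sequence, anchor_len)
            for mm, anc in ((mm_p, anc_p), (mm_m, anc_m)):
                if mm.size == 0:
                    continue
                lo = int(mm.min())
                a = int(anc[mm == lo].min())
                if best is None or (lo, a) < best:
                    best = (lo, a)
        if best is None:
            best = (len(seq), min(anchor_len, len(seq)))
        result[taxon] = {"min_mismatches": best[0], "three_prime_mismatches": best[1]}
    return result


def _batch_specificity(candidates: Sequence[PrimerCandidate],
                       offtargets: MarkerPanel,
                       anchor_len: int) -> list[tuple[int, int]]:
    """Worst-case (most cross-reactive) off-target score per candidate.

    Returns for each candidate the lexicographic minimum over off-target
    taxa of (min mismatches, anchor mismatches at best window) — identical
    to reducing :func:`specificity_profile` over taxa, but computed in
    batch.  Each distinct variant sequence (candidate or its reverse
    complement) is scanned once per template + strand; minus-strand binding
    of a primer is the plus-strand hit of its reverse complement with the
    anchor read at the window start.
    """
    variant_index: dict[str, int] = {}
    variants: list[str] = []

    def vid(s: str) -> int:
        if s not in variant_index:
            variant_index[s] = len(variants)
            variants.append(s)
        return variant_index[s]

    fwd_vid = [vid(c.sequence) for c in candidates]
    rc_vid = [vid(reverse_complement(c.sequence)) for c in candidates]

    by_len: dict[int, list[int]] = {}
    for i, v in enumerate(variants):
        by_len.setdefault(len(v), []).append(i)

    n_var = len(variants)
    batches = {length: _scan.PrimerBatch([variants[i] for i in ids], anchor_len)
               for length, ids in by_len.items()}

    INF = (10 ** 6, 10 ** 6)
    per_taxon: dict[TaxonLabel, list[list[tuple[int, int]]]] = {}
    for entry in offtargets.entries:
        compat = _scan.template_compat(entry.sequence)
        tail_here = [INF] * n_var
        head_here = [INF] * n_var
        for length, ids in by_len.items():
            mm, anc_tail, anc_head = batches[length].best_hits(compat)
            for pos, i in enumerate(ids):
                tail_here[i] = (int(mm[pos]), int(anc_tail[pos]))
                head_here[i] = (int(mm[pos]), int(anc_head[pos]))
        per_taxon.setdefault(entry.taxon, []).append(
            [(tail_here[f], head_here[r]) for f, r in zip(fwd_vid, rc_vid)])

    scores: list[tuple[int, int]] = []
    for ci in range(len(candidates)):
        worst: tuple[int, int] | None = None
        for taxon, entries in per_taxon.items():
            taxon_best = min(min(e[ci][0], e[ci][1]) for e in entries)
            if worst is None or taxon_best < worst:
                worst = taxon_best
        scores.append(worst if worst is not None else INF)
    return scores


# ---------------------------------------------------------------------------
# Assay selection
# ---------------------------------------------------------------------------

def design_assay(taxon: TaxonLabel,
                 panel: MarkerPanel,
                 params: DesignParams | None = None,
                 kind: str = "species_level",
                 consensus: ConsensusProfile | None = None) -> AssayDefinition:
    """Design the canonical discriminative assay for one taxon.

    Pair selection maximises, lexicographically: (1) the off-target total
    mismatch count of the worse primer, (2) its 3'-anchor mismatch count,
    (3) passing the cross-dimer screen, then minimises (4) the distance of
    the amplicon length from the midpoint of the allowed range; remaining
    ties break by leftmost forward start, then shortest primers.

    Feasibility is an amplification property: when even the best pair's
    worse primer has an exact off-target window (0 mismatches), the pair is
    accepted only if it predicts no off-target product under the strict
    zero-mismatch policy (one discriminating primer suffices for a specific
    assay); pairs at that level are scanned preferring the more
    discriminating better primer.  If no window anywhere discriminates the
    target — e.g. target and off-target sequences are identical — the
    design is infeasible.
    """
    params = params or DesignParams()
    if taxon not in panel.taxa:
        raise ValueError(f"taxon {taxon} not present in panel")
    offtargets = panel.subset([t for t in panel.taxa if t != taxon])
    if not offtargets.entries:
        raise ValueError("need at least one off-target taxon")

    profile = consensus or consensus_for_taxon(panel, taxon)
    candidates = enumerate_candidates(profile, params)
    if not candidates:
        raise DesignInfeasibleError(f"design infeasible for taxon {taxon}: no candidates")

    scores = _batch_specificity(candidates, offtargets, params.three_prime_anchor)
    if max(s[0] for s in scores) == 0:
        raise DesignInfeasibleError(
            f"design infeasible for taxon {taxon}: no consensus window "
            "discriminates the target from every off-target taxon")

    lo_amp, hi_amp = params.amplicon_len_range
    mid = (lo_amp + hi_amp) / 2.0

    def pair_quality(fi: int, ri: int):
        f, r = candidates[fi], candidates[ri]
        length = r.end - f.start
        dimer_ok = passes_dimer_screen(f.sequence, r.sequence, params)
        return (not dimer_ok, abs(length - mid), f.start,
                len(f) + len(r), len(f), r.start)

    def valid_pair(fi: int, ri: int) -> bool:
        f, r = candidates[fi], candidates[ri]
        if r.end <= f.end or r.start < f.end:
            return False
        return lo_amp <= r.end - f.start <= hi_amp

    def finish(fi: int, ri: int) -> AssayDefinition:
        f, r = candidates[fi], candidates[ri]
        return AssayDefinition(taxon, f, r, r.end - f.start, kind)

    # Phase 1: pairs of two discriminating primers, best worse-score first.
    disc = [i for i in range(len(candidates)) if scores[i][0] >= 1]
    order = sorted(disc, key=lambda i: scores[i], reverse=True)
    fwd_pool: list[int] = []
    rev_pool: list[int] = []
    pos = 0
    while pos < len(order):
        level = scores[order[pos]]
        new_f: list[int] = []
        new_r: list[int] = []
        while pos < len(order) and scores[order[pos]] == level:
            i = order[pos]
            (new_f if candidates[i].strand == "+" else new_r).append(i)
            pos += 1
        hits = [(fi, ri) for fi in new_f for ri in rev_pool + new_r if valid_pair(fi, ri)]
        hits += [(fi, ri) for ri in new_r for fi in fwd_pool if valid_pair(fi, ri)]
        fwd_pool.extend(new_f)
        rev_pool.extend(new_r)
        if hits:
            return finish(*min(hits, key=lambda p: pair_quality(*p)))

    # Phase 2: one discriminating primer paired with a non-discriminating
    # partner.  The worse primer has an exact off-target window somewhere,
    # so the pair is acceptable only if it predicts no off-target product
    # under the strict policy.  Scan: most discriminating primer first,
    # partners by 3'-anchor mismatches then amplicon-length preference;
    # dimer-passing pairs win, a dimer-failing pair is kept as fallback.
    from .pcr import MismatchPolicy, predict_amplicons   # late import: avoids cycle
    strict = MismatchPolicy(anchor_len=params.three_prime_anchor)

    def specific(fi: int, ri: int) -> bool:
        assay = finish(fi, ri)
        return not any(predict_amplicons(assay, e.sequence, strict)
                       for e in offtargets.entries)

    others = [i for i in range(len(candidates)) if scores[i][0] == 0]
    fallback: tuple[int, int] | None = None
    for d in sorted(disc, key=lambda i: (tuple(-v for v in scores[i]),
                                         candidates[i].start, len(candidates[i]))):
        partners = [o for o in others
                    if candidates[o].strand != candidates[d].strand]
        def as_pair(o: int) -> tuple[int, int]:
            return (d, o) if candidates[d].strand == "+" else (o, d)
        partners = [o for o in partners if valid_pair(*as_pair(o))]
        partners.sort(key=lambda o: (-scores[o][1],
                                     abs(candidates[as_pair(o)[1]].end
                                         - candidates[as_pair(o)[0]].start - mid),
                                     candidates[as_pair(o)[0]].start,
                                     len(candidates[o])))
        for o in partners:
            fi, ri = as_pair(o)
            dimer_ok = passes_dimer_screen(candidates[fi].sequence,
                                           candidates[ri].sequence, params)
            if dimer_ok:
                if specific(fi, ri):
                    return finish(fi, ri)
            elif fallback is None and specific(fi, ri):
                fallback = (fi, ri)
    if fallback is not None:
        return finish(*fallback)
    raise DesignInfeasibleError(
        f"design infeasible for taxon {taxon}: no primer pair yields a specific "
        f"amplicon within {params.amplicon_len_range}")


def design_panel_assays(panel: MarkerPanel,
                        params: DesignParams | None = None) -> list[AssayDefinition]:
    """One species-level assay per panel taxon, in panel order."""
    params = params or DesignParams()
    return [design_assay(t, panel, params) for t in panel.taxa]


# ---------------------------------------------------------------------------
# Import / export
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["taxon", "forward", "reverse", "expected_length", "kind"]


def write_assay_tsv(assays: Iterable[AssayDefinition], path: str | Path) -> None:
    rows = [{"taxon": str(a.taxon), "forward": a.forward.sequence,
             "reverse": a.reverse.sequence, "expected_length": a.expected_length,
             "kind": a.kind} for a in assays]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_assay_tsv(path: str | Path) -> list[AssayDefinition]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        fwd = PrimerCandidate(row["forward"], "+", 0,
                              tm_wallace(row["forward"]), gc_percent(row["forward"]))
        rev = PrimerCandidate(row["reverse"], "-", 0,
                              tm_wallace(row["reverse"]), gc_percent(row["reverse"]))
        out.append(AssayDefinition(TaxonLabel.parse(row["taxon"]), fwd, rev,
                                   int(row["expected_length"]), row["kind"]))
    return out


def write_primer_fasta(assays: Iterable[AssayDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in assays:
            fh.write(f">{a.taxon}|F\n{a.forward.sequence}\n")
            fh.write(f">{a.taxon}|R\n{a.reverse.sequence}\n")
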