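"""Independent brute-force oracles the fast implementations are checked against.

Everything here is written as plainly as possible — single loops, explicit
set intersections, full recursion — and shares no code path with the
package internals it verifies.
"""

from __future__ import annotations

from functools import lru_cache

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def compatible(primer_base: str, template_symbol: str) -> bool:
    return bool(IUPAC_SETS[primer_base] & IUPAC_SETS.get(template_symbol, set()))


def naive_window_mismatches(primer: str, window: str) -> int:
    return sum(not compatible(p, t) for p, t in zip(primer, window))


def naive_sites(primer: str, template: str, max_mm: int, anchor: int, max_anchor_mm: int):
    """All (strand, start, mismatches) binding sites by a plain double loop."""
    m = len(primer)
    out = []
    for start in range(len(template) - m + 1):
        window = template[start:start + m]
        mm = naive_window_mismatches(primer, window)
        anc = naive_window_mismatches(primer[m - anchor:], window[m - anchor:]) if anchor else 0
        if mm <= max_mm and anc <= max_anchor_mm:
            out.append(("+", start, mm))
        rc = revcomp(primer)
        mm2 = naive_window_mismatches(rc, window)
        anc2 = naive_window_mismatches(rc[:anchor], window[:anchor]) if anchor else 0
        if mm2 <= max_mm and anc2 <= max_anchor_mm:
            out.append(("-", start, mm2))
    return sorted(out, key=lambda s: (s[1], s[0]))


def naive_specificity(primer: str, sequences: list[str]) -> tuple[int, int]:
    """(min mismatches, anchor-3 mismatches at best window) over all windows,
    both strands, of all sequences."""
    best = None
    m = len(primer)
    for template in sequences:
        for variant, anchor_at_end in ((primer, True), (revcomp(primer), False)):
            for start in range(len(template) - m + 1):
                window = template[start:start + m]
                mm = naive_window_mismatches(variant, window)
                if anchor_at_end:
                    anc = naive_window_mismatches(variant[m - 3:], window[m - 3:])
                else:
                    anc = naive_window_mismatches(variant[:3], window[:3])
                if best is None or (mm, anc) < best:
                    best = (mm, anc)
    assert best is not None
    return best


def naive_amplicons(forward: str, reverse: str, template: str,
                    max_mm: int, anchor: int, max_anchor_mm: int,
                    max_len: int) -> list[tuple[int, int]]:
    """Brute-force double loop over all site pairs, both orientations."""
    f_sites = naive_sites(forward, template, max_mm, anchor, max_anchor_mm)
    r_sites = naive_sites(reverse, template, max_mm, anchor, max_anchor_mm)
    out = set()
    for tag_p, sites_p, tag_m, sites_m in (("F", f_sites, "R", r_sites),
                                           ("R", r_sites, "F", f_sites)):
        for strand_p, start_p, _ in sites_p:
            if strand_p != "+":
                continue
            for strand_m, start_m, _ in sites_m:
                if strand_m != "-":
                    continue
                p_end = start_p + (len(forward) if tag_p == "F" else len(reverse))
                m_end = start_m + (len(forward) if tag_m == "F" else len(reverse))
                if m_end > p_end and m_end - start_p <= max_len:
                    out.add((start_p, m_end))
    return sorted(out)


def best_alignment_score(a: str, b: str, match=2, mismatch=-1, gap=-2) -> int:
    """Optimal global alignment score by exhaustive recursion (memoised)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        opts = []
        if i < len(a) and j < len(b):
            opts.append((match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1))
        if i < len(a):
            opts.append(gap + rec(i + 1, j))
        if j < len(b):
            opts.append(gap + rec(i, j + 1))
        return max(opts)

    return rec(0, 0)


def enumerate_alignment_scores(a: str, b: str, match=2, mismatch=-1, gap=-2):
    """Yield the score of every distinct global alignment (tiny inputs only)."""
    def rec(i, j, score):
        if i == len(a) and j == len(b):
            yield score
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            yield from rec(i + 1, j, score + gap)
        if j < len(b):
            yield from rec(i, j + 1, score + gap)
    yield from rec(0, 0, 0)


def all_set_partitions(items: list):
    """Every partition of `items` into non-empty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def min_reactions_by_enumeration(lengths: list[int], plex: int, min_sep: int) -> int:
    best = len(lengths)
    for part in all_set_partitions(list(lengths)):
        if any(len(block) > plex for block in part):
            continue
        ok = True
        for block in part:
            s = sorted(block)
            if any(b - a < min_sep for a, b in zip(s, s[1:])):
                ok = False
                break
        if ok:
            best = min(best, len(part))
    return best
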