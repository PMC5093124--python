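"""Low-level IUPAC-aware window scanning shared by primer scoring and virtual PCR."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._iupac import encode, reverse_complement


def window_mismatches(primer: str, template: str, anchor_len: int):
    """Mismatch profiles of a primer against every same-length template window.

    A primer base and a template symbol mismatch iff their IUPAC expansions
    are disjoint, so degenerate template symbols count as compatible with
    any base they contain.  Returns four arrays over the ``len(template) -
    len(primer) + 1`` windows:

    - ``mm_plus``:  total mismatches for the primer on the + strand
    - ``anc_plus``: mismatches within the primer's 3'-terminal ``anchor_len``
      bases (the *last* ``anchor_len`` window positions)
    - ``mm_minus``: total mismatches for the primer on the − strand (i.e. its
      reverse complement scanned against the + strand)
    - ``anc_minus``: 3'-anchor mismatches for the − strand orientation (the
      *first* ``anchor_len`` window positions, where the primer's 3' end sits)
    """
    p = encode(primer)
    t = encode(template)
    m = len(p)
    if m > len(t):
        z = np.zeros(0, dtype=np.intp)
        return z, z, z, z
    a = min(anchor_len, m)
    w = sliding_window_view(t, m)

    inc_p = (w & p) == 0
    mm_plus = inc_p.sum(axis=1)
    anc_plus = inc_p[:, m - a:].sum(axis=1) if a else np.zeros_like(mm_plus)

    prc = encode(reverse_complement(primer))
    inc_m = (w & prc) == 0
    mm_minus = inc_m.sum(axis=1)
    anc_minus = inc_m[:, :a].sum(axis=1) if a else np.zeros_like(mm_minus)
    return mm_plus, anc_plus, mm_minus, anc_minus


_BASE_INDEX = {1: 0, 2: 1, 4: 2, 8: 3}


def template_compat(template: str) -> np.ndarray:
    """(4, n) float32 matrix: compat[b, j] = 1 if base b can pair template[j]."""
    t = encode(template)
    out = np.empty((4, len(t)), dtype=np.float32)
    for b in range(4):
        out[b] = (t & (1 << b)) != 0
    return out


class PrimerBatch:
    """Same-length exact primers, one-hot encoded once for repeated scans.

    ``best_hits`` returns, per primer, the minimum total mismatches over all
    + strand windows of a template and the minimum 3'-anchor mismatch count
    among those best windows under both anchor conventions: anchor at the
    window *end* (primer scanned as-is) and at the window *start* (primer
    scanned as a reverse complement standing in for − strand binding).  The
    scan is a one-hot × compatibility-matrix product, one BLAS call per
    template.
    """

    def __init__(self, variants: list[str], anchor_len: int):
        K = len(variants)
        m = len(variants[0])
        if any(len(v) != m for v in variants):
            raise ValueError("all variants must share one length")
        self.m = m
        self.anchor = a = min(anchor_len, m)
        # layout: column b*m + d  <->  base b at primer offset d
        idx = np.empty((K, m), dtype=np.intp)
        for k, v in enumerate(variants):
            enc = encode(v)
            idx[k] = [_BASE_INDEX[int(x)] for x in enc]
        onehot = np.zeros((K, 4 * m), dtype=np.float32)
        rows = np.repeat(np.arange(K), m)
        cols = (idx * m + np.arange(m)).ravel()
        onehot[rows, cols] = 1.0
        self.onehot = onehot
        tail = np.zeros(4 * m, dtype=bool)
        head = np.zeros(4 * m, dtype=bool)
        for b in range(4):
            tail[b * m + m - a: b * m + m] = True
            head[b * m: b * m + a] = True
        self.tail_cols, self.head_cols = tail, head
        self.onehot_tail = onehot[:, tail]
        self.onehot_head = onehot[:, head]

    def best_hits(self, compat: np.ndarray):
        m, a = self.m, self.anchor
        K = self.onehot.shape[0]
        n = compat.shape[1]
        if m > n:
            big = np.full(K, m, dtype=np.int64)
            return big, big.copy(), big.copy()
        W = n - m + 1
        X = np.empty((4 * m, W), dtype=np.float32)
        for b in range(4):
            X[b * m:(b + 1) * m, :] = sliding_window_view(compat[b], m).T

        # counts stay exact in float32 (values <= m << 2**24); convert only
        # the final K-length reductions
        mm = m - self.onehot @ X                                      # (K, W)
        anc_tail = a - self.onehot_tail @ X[self.tail_cols]
        anc_head = a - self.onehot_head @ X[self.head_cols]

        best = mm.min(axis=1)
        is_best = mm <= best[:, None] + 0.5
        big = m + 1
        anc_tail_best = np.where(is_best, anc_tail, big).min(axis=1)
        anc_head_best = np.where(is_best, anc_head, big).min(axis=1)
        return (np.rint(best).astype(np.int64),
                np.rint(anc_tail_best).astype(np.int64),
                np.rint(anc_head_best).astype(np.int64))
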