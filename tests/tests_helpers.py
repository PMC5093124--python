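"""Tiny construction helpers shared across test modules."""

from probioplex.panel import TaxonLabel
from probioplex.primers import AssayDefinition, PrimerCandidate


def make_assays(lengths, seq="ACGTACGTACGTACGTAC"):
    """Placeholder assays with the given expected lengths (primers unused)."""
    out = []
    for i, L in enumerate(lengths):
        f = PrimerCandidate(seq, "+", 0, 44.0, 50.0)
        r = PrimerCandidate(seq, "-", 0, 44.0, 50.0)
        out.append(AssayDefinition(TaxonLabel("Lactobacillus", f"sp{i:02d}"), f, r, int(L)))
    return out
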