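"""Virtual-gel genotyping of product samples and label-claim auditing.

The multiplex panel is run in silico on a sample's sequences; each
reaction's predicted amplicon lengths form a band pattern which is matched
against the scheme's expected ladder.  A taxon is called present only when
a band matches its expected length within the gel tolerance (default 0 —
the exact-length positivity rule).  Calls are then compared with the
product label: every panel taxon falls in one of four categories
(claimed+present, claimed+absent, unclaimed+present, unclaimed+absent),
with strain-level assays adding confirmed/mismatched/unresolvable calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .panel import TaxonLabel
from .pcr import MismatchPolicy, predict_amplicons
from .scheme import MultiplexScheme

CLAIMED_PRESENT = "claimed_present"
CLAIMED_ABSENT = "claimed_absent"
UNCLAIMED_PRESENT = "unclaimed_present"
UNCLAIMED_ABSENT = "unclaimed_absent"
NOT_TESTABLE = "not_testable"

STRAIN_CONFIRMED = "confirmed"
STRAIN_MISMATCHED = "mismatched"
STRAIN_UNRESOLVABLE = "unresolvable"


class SchemeIntegrityError(RuntimeError):
    """A band matches two assays exactly — the scheme separation is violated."""


@dataclass(frozen=True)
class LabelClaim:
    product_id: str
    claimed_taxa: frozenset[TaxonLabel]
    claimed_cfu_per_g: float
    potency_basis: str = "through_expiration"   # or "time_of_manufacture"
    months_to_expiration: float = 12.0
    claimed_strains: frozenset[TaxonLabel] = frozenset()

    def __post_init__(self) -> None:
        if self.claimed_cfu_per_g <= 0:
            raise ValueError("claimed CFU must be positive")
        if not self.claimed_taxa:
            raise ValueError("a label must claim at least one taxon")
        if self.potency_basis not in ("time_of_manufacture", "through_expiration"):
            raise ValueError(f"unknown potency basis {self.potency_basis!r}")


@dataclass
class BandPattern:
    """Per-reaction sorted band lengths (bp)."""

    bands: list[list[int]]

    def __post_init__(self) -> None:
        self.bands = [sorted(set(b)) for b in self.bands]
        if any(l <= 0 for b in self.bands for l in b):
            raise ValueError("band lengths must be positive")


@dataclass(frozen=True)
class PresenceCall:
    taxon: TaxonLabel
    detected: bool
    matched_length: int | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.detected and self.matched_length is None:
            raise ValueError("a detected call must carry the matched band length")


@dataclass
class AuditRow:
    product_id: str
    categories: dict[str, str]              # taxon rendering -> category
    strain_categories: dict[str, str] = field(default_factory=dict)
    not_testable: list[str] = field(default_factory=list)
    retest: bool = False                    # flags label discrepancies for re-run

    @property
    def has_missing_claimed(self) -> bool:
        return CLAIMED_ABSENT in self.categories.values()

    @property
    def has_unclaimed(self) -> bool:
        return UNCLAIMED_PRESENT in self.categories.values()

    @property
    def discrepant(self) -> bool:
        return self.has_missing_claimed or self.has_unclaimed


@dataclass
class AuditMatrix:
    rows: list[AuditRow]

    def to_frame(self) -> pd.DataFrame:
        taxa: list[str] = []
        for row in self.rows:
            for t in row.categories:
                if t not in taxa:
                    taxa.append(t)
        data = [{**{"product": r.product_id}, **{t: r.categories.get(t, "") for t in taxa}}
                for r in self.rows]
        return pd.DataFrame(data).set_index("product")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def percentage(count: int, total: int) -> float:
    """Survey-style percentage, rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------

def virtual_gel(sample_sequences: Sequence[str],
                scheme: MultiplexScheme,
                policy: MismatchPolicy | None = None) -> BandPattern:
    """Predicted band pattern of a sample: per reaction, the union of
    amplicon lengths of that reaction's assays over all sample sequences."""
    policy = policy or MismatchPolicy()
    bands: list[list[int]] = []
    for rxn in scheme.reactions:
        lengths: set[int] = set()
        for assay in rxn:
            for seq in sample_sequences:
                if len(seq) < min(len(assay.forward), len(assay.reverse)):
                    continue
                lengths.update(a.length for a in predict_amplicons(assay, seq, policy))
        bands.append(sorted(lengths))
    return BandPattern(bands)


def call_presence(pattern: BandPattern, scheme: MultiplexScheme) -> list[PresenceCall]:
    """Exact-length band calling against the scheme's expected ladders.

    Each band is assigned to at most one assay in its reaction: the one
    whose expected length is nearest within ``gel.length_tolerance``; a
    distance tie resolves to the lower expected length and flags the call
    ambiguous.  A band equal to two expected lengths at once means the
    scheme's separation guarantee was broken and raises
    :class:`SchemeIntegrityError`.
    """
    if len(pattern.bands) != len(scheme.reactions):
        raise ValueError("band pattern does not align with scheme reactions")
    tol = scheme.gel.length_tolerance
    calls: list[PresenceCall] = []
    for rxn, bands in zip(scheme.reactions, pattern.bands):
        matched: dict[str, tuple[int, bool]] = {}
        for band in bands:
            in_tol = [a for a in rxn if abs(band - a.expected_length) <= tol]
            if not in_tol:
                continue
            exact = [a for a in in_tol if a.expected_length == band]
            if len(exact) > 1:
                raise SchemeIntegrityError(
                    f"band {band} matches {len(exact)} assays exactly")
            best_dist = min(abs(band - a.expected_length) for a in in_tol)
            nearest = [a for a in in_tol if abs(band - a.expected_length) == best_dist]
            ambiguous = len(nearest) > 1
            chosen = min(nearest, key=lambda a: a.expected_length)
            key = str(chosen.taxon)
            if key not in matched:
                matched[key] = (band, ambiguous)
        for assay in rxn:
            hit = matched.get(str(assay.taxon))
            if hit is None:
                calls.append(PresenceCall(assay.taxon, False))
            else:
                calls.append(PresenceCall(assay.taxon, True, hit[0], hit[1]))
    return calls


def genotype_sample(sample_sequences: Sequence[str],
                    scheme: MultiplexScheme,
                    policy: MismatchPolicy | None = None) -> list[PresenceCall]:
    """Virtual gel + band calling in one step."""
    return call_presence(virtual_gel(sample_sequences, scheme, policy), scheme)


# ---------------------------------------------------------------------------
# Label audit
# ---------------------------------------------------------------------------

def audit_against_label(calls: Sequence[PresenceCall],
                        claim: LabelClaim,
                        strain_calls: Sequence[PresenceCall] = ()) -> AuditRow:
    """Classify every panel taxon of one product against its label claim.

    Claimed taxa the panel cannot test are recorded separately as
    not-testable and never count toward discrepancy summaries.  Claimed
    strains with a strain-level assay call become confirmed/mismatched;
    claimed strains without one are unresolvable.
    """
    detected = {str(c.taxon) for c in calls if c.detected}
    panel_taxa = [str(c.taxon) for c in calls]
    claimed = {str(t) for t in claim.claimed_taxa}

    categories: dict[str, str] = {}
    for taxon in panel_taxa:
        is_claimed = taxon in claimed
        is_present = taxon in detected
        categories[taxon] = (
            CLAIMED_PRESENT if is_claimed and is_present
            else CLAIMED_ABSENT if is_claimed
            else UNCLAIMED_PRESENT if is_present
            else UNCLAIMED_ABSENT)
    not_testable = sorted(claimed - set(panel_taxa))

    strain_by_label = {str(c.taxon): c for c in strain_calls}
    strain_categories: dict[str, str] = {}
    for strain in sorted(claim.claimed_strains, key=str):
        call = strain_by_label.get(str(strain))
        if call is None:
            strain_categories[str(strain)] = STRAIN_UNRESOLVABLE
        else:
            strain_categories[str(strain)] = (
                STRAIN_CONFIRMED if call.detected else STRAIN_MISMATCHED)

    row = AuditRow(claim.product_id, categories, strain_categories, not_testable)
    row.retest = row.discrepant
    return row


def summarize_audit(matrix: AuditMatrix) -> dict[str, float | int]:
    """Cohort-level mislabeling summary.

    A product is discrepant when it has at least one claimed-but-absent or
    one unclaimed-but-present panel taxon.  Percentages are over all
    products, rounded to one decimal.
    """
    if not matrix.rows:
        raise ValueError("audit matrix is empty")
    n = len(matrix.rows)
    n_missing = sum(r.has_missing_claimed for r in matrix.rows)
    n_unclaimed = sum(r.has_unclaimed for r in matrix.rows)
    n_discrepant = sum(r.discrepant for r in matrix.rows)
    return {
        "n_products": n,
        "n_with_missing_claimed": n_missing,
        "n_with_unclaimed": n_unclaimed,
        "n_discrepant": n_discrepant,
        "pct_with_missing_claimed": percentage(n_missing, n),
        "pct_with_unclaimed": percentage(n_unclaimed, n),
        "pct_discrepant": percentage(n_discrepant, n),
        "pct_correct": percentage(n - n_discrepant, n),
    }


# ---------------------------------------------------------------------------
# Label-claim tables
# ---------------------------------------------------------------------------

_CLAIM_COLUMNS = ["product_id", "claimed_taxa", "claimed_cfu_per_g",
                  "potency_basis", "months_to_expiration", "claimed_strains"]


def write_claims_tsv(claims: Iterable[LabelClaim], path: str | Path) -> None:
    rows = []
    for c in claims:
        rows.append({
            "product_id": c.product_id,
            "claimed_taxa": ";".join(sorted(str(t) for t in c.claimed_taxa)),
            "claimed_cfu_per_g": f"{c.claimed_cfu_per_g:.6g}",
            "potency_basis": c.potency_basis,
            "months_to_expiration": c.months_to_expiration,
            "claimed_strains": ";".join(sorted(str(t) for t in c.claimed_strains)),
        })
    pd.DataFrame(rows, columns=_CLAIM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_claims_tsv(path: str | Path) -> list[LabelClaim]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_CLAIM_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"claims table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        taxa = frozenset(TaxonLabel.parse(t) for t in row["claimed_taxa"].split(";") if t)
        strains = frozenset(TaxonLabel.parse(t)
                            for t in row.get("claimed_strains", "").split(";") if t)
        out.append(LabelClaim(
            product_id=row["product_id"],
            claimed_taxa=taxa,
            claimed_cfu_per_g=float(row["claimed_cfu_per_g"]),
            potency_basis=row["potency_basis"],
            months_to_expiration=float(row["months_to_expiration"] or 12.0),
            claimed_strains=strains,
        ))
    return out
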