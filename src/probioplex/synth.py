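"""Seeded generators emulating the study's materials.

Everything downstream is exercised on synthetic inputs shaped like the
study's: marker panels whose 16S-like locus is far more conserved than the
pgi-like locus, mock communities (even, per-reaction and 1000:1 spiked
standards), paired amplicon reads from V4-like references, calibration
dilution series, and mislabeled products whose labels swap, omit or add
species.  Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._iupac import reverse_complement
from .genotype import LabelClaim
from .panel import MarkerPanel, MarkerSequence, TaxonLabel
from .profiling import Read, ReadSet, ReferenceSet, build_reference_set

#: The 20-species/sub-species assay roster.  The related pairs that are
#: notoriously hard to distinguish (and that mislabeled products swap) are
#: all present: B. longum subsp. longum / subsp. infantis, L. casei /
#: L. paracasei, L. acidophilus / L. helveticus.
DEFAULT_TAXA: tuple[TaxonLabel, ...] = tuple(
    TaxonLabel.parse(t) for t in (
        "Lactobacillus acidophilus",
        "Lactobacillus helveticus",
        "Lactobacillus casei",
        "Lactobacillus paracasei",
        "Lactobacillus rhamnosus",
        "Lactobacillus plantarum",
        "Lactobacillus gasseri",
        "Lactobacillus reuteri",
        "Lactobacillus salivarius",
        "Lactobacillus fermentum",
        "Lactobacillus brevis",
        "Lactobacillus delbrueckii bulgaricus",
        "Bifidobacterium animalis lactis",
        "Bifidobacterium animalis animalis",
        "Bifidobacterium longum longum",
        "Bifidobacterium longum infantis",
        "Bifidobacterium breve",
        "Bifidobacterium bifidum",
        "Bifidobacterium adolescentis",
        "Streptococcus thermophilus",
    )
)

#: Species pairs eligible for label swaps in mislabeled-product fixtures.
RELATED_PAIRS: tuple[tuple[TaxonLabel, TaxonLabel], ...] = (
    (TaxonLabel.parse("Bifidobacterium longum longum"),
     TaxonLabel.parse("Bifidobacterium longum infantis")),
    (TaxonLabel.parse("Lactobacillus casei"),
     TaxonLabel.parse("Lactobacillus paracasei")),
    (TaxonLabel.parse("Lactobacillus acidophilus"),
     TaxonLabel.parse("Lactobacillus helveticus")),
)

# Mock-standard concentrations
EVEN_CFU_PER_ML = 1e8
SPIKE_KEY_CFU_PER_ML = 1e8
SPIKE_OTHER_CFU_PER_ML = 1e5
EVEN_DNA_PG_PER_UL = 100.0
SPIKE_KEY_DNA_PG_PER_UL = 1000.0
SPIKE_OTHER_DNA_PG_PER_UL = 1.0


@dataclass(frozen=True)
class PanelSpec:
    """Shape of a synthetic marker panel for one locus.

    Identities are expected pairwise percent identities; the generator
    derives per-site substitution rates so measured identities land near
    the targets.  A pgi-like locus uses a lower ``between_taxon_identity``
    than a 16S-like locus.
    """

    locus: str = "pgi"
    n_taxa: int = 20
    strains_per_taxon: int = 2
    gene_length: int = 600
    within_taxon_identity: float = 99.5
    between_taxon_identity: float = 85.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.between_taxon_identity <= 100
                and 0 < self.within_taxon_identity <= 100):
            raise ValueError("identities must lie in (0, 100]")
        if self.within_taxon_identity <= self.between_taxon_identity:
            raise ValueError("within-taxon identity must exceed between-taxon identity")
        if self.n_taxa < 1 or self.strains_per_taxon < 1 or self.gene_length < 1:
            raise ValueError("counts and lengths must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if "seed" not in cfg:
            raise ValueError("generator config must carry an explicit 'seed'")
        return cls(**cfg)


def default_pgi_spec(seed: int = 0, **overrides) -> PanelSpec:
    return replace(PanelSpec(locus="pgi", gene_length=600,
                             between_taxon_identity=85.0, seed=seed), **overrides)


def default_16s_spec(seed: int = 0, **overrides) -> PanelSpec:
    return replace(PanelSpec(locus="16S", gene_length=800,
                             within_taxon_identity=99.8,
                             between_taxon_identity=98.0, seed=seed), **overrides)


def _site_rate(identity_pct: float) -> float:
    """Per-sequence substitution rate so two derived copies match at the target.

    Both copies mutate independently from a common ancestor; a mutated
    site takes a uniformly random different base, so the expected pairwise
    identity is (1-q)^2 + q^2/3.  Solve for q.
    """
    i = identity_pct / 100.0
    disc = 4.0 - (16.0 / 3.0) * (1.0 - i)
    if disc < 0:
        raise ValueError(f"identity target {identity_pct}% is unreachable "
                         "under a substitution-only model")
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        idx = (np.searchsorted(_BASES, out[hits]) + shift) % 4
        out[hits] = _BASES[idx]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def generate_panel(spec: PanelSpec,
                   taxa: Sequence[TaxonLabel] | None = None) -> MarkerPanel:
    """A marker panel: one ancestral gene, taxa and strains by substitution.

    Each taxon founder mutates the ancestral sequence at the between-taxon
    rate; each strain mutates its founder at the within-taxon rate.
    Deterministic per ``spec.seed``.
    """
    taxa = list(taxa) if taxa is not None else list(DEFAULT_TAXA[:spec.n_taxa])
    if len(taxa) < spec.n_taxa:
        raise ValueError("not enough taxon labels for the requested panel size")
    taxa = taxa[:spec.n_taxa]
    rng = np.random.default_rng(spec.seed)
    ancestor = _BASES[rng.integers(0, 4, size=spec.gene_length)]
    q_between = _site_rate(spec.between_taxon_identity)
    q_within = _site_rate(spec.within_taxon_identity)
    entries: list[MarkerSequence] = []
    for t_idx, taxon in enumerate(taxa):
        founder = _mutate(ancestor, q_between, rng)
        for s_idx in range(spec.strains_per_taxon):
            strain = _mutate(founder, q_within, rng) if spec.strains_per_taxon > 1 else founder
            entries.append(MarkerSequence(
                taxon, spec.locus if spec.locus in ("pgi", "16S") else "other",
                _to_str(strain), f"syn-{spec.locus}-{t_idx + 1}.{s_idx + 1}"))
    return MarkerPanel(entries, spec.locus if spec.locus in ("pgi", "16S") else "other")


def v4_references(panel_16s: MarkerPanel, start: int = 250,
                  length: int = 250) -> ReferenceSet:
    """Type-strain V4-like references: a fixed window of each taxon's first
    16S sequence, with identical windows collapsed into one group."""
    refs = []
    for taxon in panel_16s.taxa:
        seq = panel_16s.sequences_of(taxon)[0].sequence
        if start + length > len(seq):
            raise ValueError("16S sequences too short for the requested V4 window")
        refs.append((taxon, seq[start:start + length]))
    return build_reference_set(refs)


# ---------------------------------------------------------------------------
# Mock communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityDesign:
    members: dict[TaxonLabel, float]     # taxon -> abundance (CFU/mL or pg/µL)
    design_kind: str                     # even | reaction_subset | spiked
    units: str = "cfu"                   # cfu | dna

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.members.values()):
            raise ValueError("abundances must be positive")

    def fractions(self) -> dict[TaxonLabel, float]:
        total = sum(self.members.values())
        return {t: v / total for t, v in self.members.items()}


def generate_mock_community(design_kind: str,
                            key_taxa: Sequence[TaxonLabel],
                            taxa: Sequence[TaxonLabel],
                            units: str = "cfu") -> CommunityDesign:
    """The study's standard designs.

    ``even``: every panel taxon at the same level; ``reaction_subset``:
    only ``key_taxa`` (one reaction's targets), all equal; ``spiked``: key
    targets 1000× over the remaining panel taxa (1e8 vs 1e5 CFU/mL, or
    1 ng/µL vs 1 pg/µL in DNA units).
    """
    taxa = list(taxa)
    keys = set(key_taxa)
    if units not in ("cfu", "dna"):
        raise ValueError(f"unknown units {units!r}")
    if design_kind in ("reaction_subset", "spiked") and not keys <= set(taxa):
        raise ValueError("key taxa must be panel members")
    hi = SPIKE_KEY_CFU_PER_ML if units == "cfu" else SPIKE_KEY_DNA_PG_PER_UL
    lo = SPIKE_OTHER_CFU_PER_ML if units == "cfu" else SPIKE_OTHER_DNA_PG_PER_UL
    even = EVEN_CFU_PER_ML if units == "cfu" else EVEN_DNA_PG_PER_UL
    if design_kind == "even":
        members = {t: even for t in taxa}
    elif design_kind == "reaction_subset":
        members = {t: hi for t in taxa if t in keys}
    elif design_kind == "spiked":
        members = {t: (hi if t in keys else lo) for t in taxa}
    else:
        raise ValueError(f"unknown design kind {design_kind!r}")
    return CommunityDesign(members, design_kind, units)


def calibration_series(key_taxon: TaxonLabel,
                       taxa: Sequence[TaxonLabel],
                       log10_cfus: Sequence[float] = (5.0, 6.0, 7.0, 8.0),
                       percents: Sequence[float] = (20.0, 40.0, 60.0, 80.0),
                       ) -> list[tuple[CommunityDesign, float, float]]:
    """Standard dilution series for the CFU-vs-percent-reads calibration.

    Per point the key taxon sits at the given CFU and the background (the
    other taxa, evenly split) is chosen so the designed read percentage is
    the stated value; the design makes percent reads linear in log10 CFU,
    so sequencing noise is the only deviation from a perfect fit.
    Returns (community, log10_cfu, designed_percent) triples.
    """
    if len(log10_cfus) != len(percents):
        raise ValueError("need one designed percent per dilution")
    others = [t for t in taxa if t != key_taxon]
    if not others:
        raise ValueError("need at least one background taxon")
    out = []
    for x, p in zip(log10_cfus, percents):
        if not 0 < p < 100:
            raise ValueError("designed percents must lie in (0, 100)")
        key_cfu = 10.0 ** x
        background = key_cfu * (100.0 - p) / p
        members = {key_taxon: key_cfu}
        for t in others:
            members[t] = background / len(others)
        out.append((CommunityDesign(members, "spiked"), x, p))
    return out


def log_decreasing_abundances(n_ranks: int = 10, top: float = 40.7,
                              bottom: float = 0.6) -> list[float]:
    """Rank-abundance design a − b·ln(rank) spanning `top`..`bottom` percent."""
    if n_ranks < 3:
        raise ValueError("need at least 3 ranks")
    b = (top - bottom) / math.log(n_ranks)
    return [top - b * math.log(r) for r in range(1, n_ranks + 1)]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(community: CommunityDesign,
                   refs: ReferenceSet,
                   n_reads: int,
                   error_rate: float = 0.0,
                   quality_q: int = 38,
                   seed: int = 0,
                   read_len: int = 160,
                   sample_id: str = "sample",
                   n_low_quality: int = 0,
                   low_q: int = 2,
                   n_ambiguous: int = 0,
                   ) -> tuple[ReadSet, ReadSet, dict[str, int]]:
    """Paired V4 amplicon reads drawn proportional to community abundance.

    Each read pair covers its reference from both ends with an overlap of
    ``2*read_len - len(reference)``.  Substitution errors are planted at
    ``error_rate`` per base; the first ``n_low_quality`` pairs get one
    forward base at quality ``low_q`` and the next ``n_ambiguous`` pairs
    one forward N (both planted in the forward read's unpaired prefix, so
    pair merging preserves them for the quality filter).  Returns the
    forward and reverse read sets plus the true per-group pair counts.
    """
    rng = np.random.default_rng(seed)
    group_names: list[str] = []
    group_seqs: list[str] = []
    weights: list[float] = []
    totals: dict[str, float] = {}
    for taxon, abundance in community.members.items():
        g = refs.group_of(taxon)
        totals[g] = totals.get(g, 0.0) + abundance
    for entry in refs.entries:
        if entry.taxon_group in totals:
            group_names.append(entry.taxon_group)
            group_seqs.append(entry.v4_sequence)
            weights.append(totals[entry.taxon_group])
    if not group_names:
        raise ValueError("no community member maps to a reference group")
    probs = np.asarray(weights) / sum(weights)

    fwd_reads: list[Read] = []
    rev_reads: list[Read] = []
    truth: dict[str, int] = {g: 0 for g in group_names}
    if n_reads:
        choice = rng.choice(len(group_names), size=n_reads, p=probs)
    else:
        choice = np.zeros(0, dtype=int)
    const_q = (quality_q,) * read_len
    for i, gi in enumerate(choice):
        template = group_seqs[gi]
        truth[group_names[gi]] += 1
        if read_len > len(template):
            raise ValueError("read length exceeds reference length")
        f = template[:read_len]
        r = reverse_complement(template[len(template) - read_len:])
        if error_rate > 0:
            f = _to_str(_mutate(np.frombuffer(f.encode(), dtype=np.uint8), error_rate, rng))
            r = _to_str(_mutate(np.frombuffer(r.encode(), dtype=np.uint8), error_rate, rng))
        fq: tuple[int, ...] = const_q
        plant_span = max(1, min(read_len, len(template) - read_len))
        if i < n_low_quality:
            pos = int(rng.integers(0, plant_span))
            fq = const_q[:pos] + (low_q,) + const_q[pos + 1:]
        elif i < n_low_quality + n_ambiguous:
            pos = int(rng.integers(0, plant_span))
            f = f[:pos] + "N" + f[pos + 1:]
        fwd_reads.append(Read(f, fq))
        rev_reads.append(Read(r, const_q))
    return (ReadSet(sample_id, fwd_reads), ReadSet(sample_id, rev_reads), truth)


# ---------------------------------------------------------------------------
# Mislabeled products
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProductFixture:
    true_taxa: frozenset[TaxonLabel]
    label: LabelClaim
    injected_errors: tuple[tuple[str, ...], ...]   # ("swap", a, b) / ("omit", a) / ("add", a)


def generate_product_fixture(panel: MarkerPanel,
                             error_menu: Sequence[str] = (),
                             seed: int = 0,
                             product_id: str = "P1",
                             n_claimed: tuple[int, int] = (2, 6),
                             related_pairs: Sequence[tuple[TaxonLabel, TaxonLabel]] = RELATED_PAIRS,
                             ) -> tuple[ProductFixture, list[str]]:
    """A product with a label claim and its (possibly different) true content.

    ``error_menu`` entries from {"swap_related", "omit", "add"} are applied
    in order: a swap replaces a claimed species with its related partner
    in the true content; an omit drops a claimed species from the content;
    an add puts an unclaimed species in.  The label and the injected
    errors exactly reconstruct the true content.  Returns the fixture plus
    the true content's marker sequences.
    """
    rng = np.random.default_rng(seed)
    taxa = panel.taxa
    lo, hi = n_claimed
    k = int(rng.integers(lo, min(hi, len(taxa)) + 1))

    allowed = {"swap_related", "omit", "add"}
    if not set(error_menu) <= allowed:
        raise ValueError(f"error menu entries must come from {sorted(allowed)}")

    pair_lookup: dict[str, TaxonLabel] = {}
    for a, b in related_pairs:
        pair_lookup[str(a)] = b
        pair_lookup[str(b)] = a

    for _ in range(200):     # resample until the error menu is applicable
        claimed = [taxa[i] for i in sorted(rng.choice(len(taxa), size=k, replace=False))]
        truth = list(claimed)
        errors: list[tuple[str, ...]] = []
        ok = True
        for err in error_menu:
            if err == "swap_related":
                options = [t for t in truth
                           if str(t) in pair_lookup
                           and pair_lookup[str(t)] in taxa
                           and pair_lookup[str(t)] not in truth
                           and pair_lookup[str(t)] not in claimed
                           and t in claimed]
                if not options:
                    ok = False
                    break
                a = options[int(rng.integers(0, len(options)))]
                b = pair_lookup[str(a)]
                truth.remove(a)
                truth.append(b)
                errors.append(("swap", str(a), str(b)))
            elif err == "omit":
                options = [t for t in truth if t in claimed
                           and not any(e[1] == str(t) for e in errors)]
                if not options:
                    ok = False
                    break
                a = options[int(rng.integers(0, len(options)))]
                truth.remove(a)
                errors.append(("omit", str(a)))
            else:  # add
                options = [t for t in taxa if t not in truth and t not in claimed]
                if not options:
                    ok = False
                    break
                a = options[int(rng.integers(0, len(options)))]
                truth.append(a)
                errors.append(("add", str(a)))
        if ok:
            break
    else:
        raise RuntimeError("could not build a fixture honouring the error menu")

    claim = LabelClaim(
        product_id=product_id,
        claimed_taxa=frozenset(claimed),
        claimed_cfu_per_g=float(10 ** rng.uniform(9, 10.7)),
        potency_basis="time_of_manufacture" if rng.random() < 24 / 52 else "through_expiration",
        months_to_expiration=float(np.round(rng.uniform(1, 24), 1)),
    )
    fixture = ProductFixture(frozenset(truth), claim, tuple(errors))
    sequences = [e.sequence for t in truth for e in panel.sequences_of(t)]
    return fixture, sequences
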