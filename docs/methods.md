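# Methods

`probioplex` implements a complete in-silico counterpart of a multiplex-PCR
(mPCR) species-genotyping workflow for probiotic products, together with a
16S-V4 relative-abundance profiler and the plate-count arithmetic used to
audit CFU label claims. This note documents the models, the parameters that
matter, the synthetic-data conditions everything is tested under, and the
design choices made where the workflow left details open.

## Marker panels and degenerate consensus

A panel is a set of marker-gene sequences (a single-copy discriminative
locus such as *pgi*, or 16S rRNA genes) grouped by species or sub-species.
Within a taxon, sequences are aligned and collapsed into a degenerate
consensus: at every column the IUPAC symbol expands to *exactly* the set of
bases observed, so the consensus encodes within-taxon variation at 100%
identity (an A/T column becomes W, never a majority call). Columns gapped
in any member are marked `-` and are ineligible for primer placement —
indels in priming regions are excluded conservatively rather than modelled.

Pairwise alignment is global Needleman–Wunsch with match +2, mismatch −1,
gap −2 (linear). Terminal gaps are penalized like internal ones: with free
end gaps the optimal alignment of near-identical sequences of unequal ends
staggers them, which misstates percent identity (e.g. `AAAA` vs `AAAT`
would score 60% instead of the intended 75%). Multiple alignment uses
center-star progressive merging (the center maximizes summed pairwise
scores; "once a gap, always a gap"), which is exact enough for the
near-identical within-taxon sets it is applied to. Percent identity is
matches over alignment columns, gap columns counting as mismatches.

## Primer and assay design

Candidates are all windows of a taxon consensus that are degeneracy-free
(fully conserved within the taxon) and pass the composition and structure
screens. Defaults, all exposed on `DesignParams`:

| parameter | default | meaning |
|---|---|---|
| `primer_len_range` | 18–25 nt | candidate window lengths |
| `gc_range` | 40–60 % | GC content |
| `tm_range` | 50–70 °C | Wallace-rule Tm, 2(A+T)+4(G+C) |
| `amplicon_len_range` | 100–1000 bp | product length window |
| `max_self_comp_run` | 8 nt | hairpin/dimer run that fails a primer |
| `max_3prime_comp_run` | 5 nt | 3'-anchored complementary run that fails |
| `three_prime_anchor` | 3 nt | anchor length for specificity scoring |

The Wallace rule and run-length hairpin/dimer proxies stand in for
nearest-neighbour thermodynamics: they are deterministic, order-preserving
for the screening purpose, and simple to verify; the parameters are exposed
so a ΔG model can replace them.

Specificity is an exhaustive in-panel scan (no external database): each
candidate is slid over every off-target sequence on both strands,
IUPAC-aware on the template side, recording the minimum mismatch count and
the 3'-anchor mismatches at the best window. Assay selection maximizes,
lexicographically: (1) the worse primer's off-target mismatch minimum,
(2) its anchor mismatches, (3) passing the cross-dimer screen, then
minimizes (4) |amplicon − midpoint of the allowed range|, with positional
tie-breaks for byte-identical reproducibility.

Feasibility is an *amplification* property. When the best achievable pair
still leaves one primer with an exact off-target window (common when only a
short divergent region exists), the pair is accepted if it predicts no
off-target product under the strict zero-mismatch policy — one
discriminating primer suffices for a specific assay. If no consensus window
anywhere discriminates the target (e.g. two taxa with identical markers),
design fails explicitly.

## Virtual amplification and the gel

Binding sites are all template windows, both strands, with total mismatches
and 3'-anchor mismatches within the `MismatchPolicy` (defaults: 0 total, 0
in a 3-nt anchor — the strictest reading, matching a positivity rule of
exact band-length agreement). Products pair any + strand site of one primer
with any − strand site of the other pointing toward it, capped at 3000 bp.
Coordinates are 0-based half-open on the + strand throughout.

Multiplexing packs assays into reactions whose expected lengths differ by
at least `min_separation` (default 50 bp — conservative for 100–1000 bp
bands on 2% agarose). The partitioner deals length-sorted assays
round-robin over r reactions and falls back to exact backtracking, trying
r from ⌈n/plex⌉ upward, so the reaction count is provably minimal.

Band calling is exact by default (`length_tolerance` 0): a taxon is present
iff its reaction shows a band equal to its expected length; with a nonzero
tolerance each band goes to the nearest expected length, ties to the lower
length and flagged ambiguous. Audit categories per (product, panel taxon)
are claimed+present / claimed+absent / unclaimed+present /
unclaimed+absent; claimed taxa outside the panel are recorded not-testable
and excluded from discrepancy rates; claimed strains are confirmed or
mismatched when a strain-level assay exists, otherwise unresolvable.
Measured-equals-claimed CFU counts as meeting the claim.

## 16S-V4 profiler

Stages, each reporting its removals so read counts are conserved:

1. **merge**: best ungapped overlap of the mates (≥20 nt, mismatch fraction
   ≤0.25, score = matches − mismatches, longer overlap on ties);
   disagreeing bases take the higher quality, forward winning ties.
2. **filter**: drop reads with any N or any Phred <30 (Q30 exactly is kept).
3. **dereplicate**: identical sequences collapse to OTUs (100% identity).
4. **assign**: each OTU goes to the type-strain group with the highest
   global-alignment identity (both orientations tried); references with
   identical V4 windows are collapsed into indistinguishable groups first,
   and exact ties assign the union group, flagged ambiguous.
5. **minor filter**: OTUs at ≤0.1% of the grand total across samples are
   dropped (strictly-greater rule; a per-sample variant is exposed).
6. **abundance**: per-sample percents over retained reads (sum to 100).
   Samples below `min_reads` are excluded with a warning; the pipeline
   helper uses 10,000 — the scale at which a MiSeq sample is unusable —
   while the unit default only drops empty samples.

Two summary regressions: percent reads on log10 CFU over a standard
dilution series (orientation fixed and documented; raw percents, not
log-transformed), and mean abundance on ln(rank) for rank-abundance
profiles, where a − b·ln(rank) profiles fit exactly with slope −b.

## Plate counts and LOD bookkeeping

CFU/g is mean(triplicate colonies) × dilution factor, spread reported as
the sample SD of the scaled counts; all-zero plates flag below-detection.
Claim comparison is on the log10 scale. The potency-basis comparison
defaults to Welch's t-test on log10 CFU (pooled-variance and raw-scale
variants exposed): CFU spreads are multiplicative and group variances
cannot be assumed equal. The cell-equivalence conversion divides a target
template concentration by the calibration yield (ng/µL → pg/µL) and scales
by the calibrated cell input, reported to 2 significant figures as assay
sensitivities conventionally are.

## Synthetic study conditions

The generators emulate the study's materials; their defaults are the
conditions every test and the acceptance script run under.

- **Panels**: one random ancestral gene per locus; taxon founders mutate it
  at a rate solving (1−q)² + q²/3 = target identity (substitutions only, a
  mutated site takes a uniform different base); strains mutate founders the
  same way. Defaults: 20 taxa, 2 strains/taxon; pgi-like locus 600 bp at
  85% between-taxon identity, 16S-like 800 bp at 98%, within-taxon 99.5%
  (99.8% for 16S). The 600/800 bp lengths are a working marker-region
  size chosen to keep the exhaustive design search comfortable; divergence,
  not length, is what the method depends on. The 20-name roster covers the
  commercially common *Lactobacillus*/*Bifidobacterium* species and the
  three notoriously confusable pairs (B. longum subsp. longum/infantis,
  L. casei/paracasei, L. acidophilus/helveticus), which are also the
  default swap pairs for mislabeled-product fixtures.
- **Mock communities**: even (all members 1e8 CFU/mL), reaction-subset
  (one reaction's taxa), and spiked (key at 1e8, others at 1e5 CFU/mL —
  1000:1; 1 ng/µL vs 1 pg/µL in DNA units).
- **Reads**: paired 160-nt reads off a 250-nt V4-like window (fixed slice
  of each taxon's first 16S sequence), drawn per pair proportional to
  abundance, uniform substitution errors, constant quality, with optional
  planted low-quality bases and Ns placed in the forward read's unpaired
  prefix so merging preserves them. One 16S copy per cell is assumed;
  copy-number weights are not modelled.
- **Calibration series**: the key taxon at log10 CFU 5–8 with background
  chosen so the designed read percentage is linear in log10 CFU (20/40/
  60/80%), making sampling noise the only deviation from a perfect fit.
- **Mislabeled products**: a label claims 2–6 panel species; swap/omit/add
  errors transform label into true content, and the two reconstruct each
  other exactly.

What the generator does **not** emulate: indels (substitution-only
evolution keeps consensus and oracles exact; an indel mode would exercise
the gap handling), MiSeq error profiles (quality decay, indel errors),
chimeras, 16S copy-number heterogeneity, and PCR efficiency/competition.
Passing tests therefore demonstrate the correctness of the algorithms under
clean divergence and sampling noise, not robustness to real sequencer
artefacts.

## Problem sizes

The default suite designs one full 20-taxon panel (shared across tests),
genotypes 200 synthetic products, profiles mocks of 4,000–50,000 read
pairs, and calibrates the t-test on 1,000 null replicates; the acceptance
script uses 100 products and the same read depths. These sizes put every
binomial bound comfortably inside its tolerance while keeping a full run in
a few minutes.

## Known limitations

- Center-star alignment is not guaranteed optimal for deeply diverged
  within-taxon sets; it is used where members are ≥99% identical.
- Wallace Tm and run-length structure screens are rankings, not
  thermodynamics; absolute °C/ΔG values are not comparable to NN models.
- The exhaustive specificity scan is panel-internal by construction;
  behaviour against arbitrary out-of-panel genomes is whatever the scan
  yields on the sequences provided.
- Strain-level assays are modelled as ordinary primer pairs with
  presence/absence semantics, not SNP-typing chemistry.
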