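# Methods

## Problem and approach

`ppiscreen` implements the scoring and orchestration layer of a deep-learning
virtual screen for protein–protein interactions (PPIs): given predicted
structures of candidate dimers and their confidence output (the predicted
aligned error matrix, PAE, and per-residue pLDDT), decide which pairs
plausibly interact and rank an entire library of candidate partners per query.
The motivating application is the *E. coli* cell envelope: a query protein is
screened against every envelope protein (including itself, to catch
homo-oligomers), with the structure predictor itself hidden behind an adapter
boundary so that the surrounding pipeline — feature assembly, scoring,
filtering, ranking, reporting — is fully testable offline.

## The interface score

For a predicted complex, interface residues are all residues with at least
one heavy atom strictly within 4.5 Å of a different chain. With N_I interface
residues and PAE entries e_ij (the expected error, in Å, of residue j's
position when the model is aligned on residue i's local frame), the interface
score is

    iScore = max_{i ∈ I} mean_{j ∈ I, chain(j) ≠ chain(i)}  1 / (1 + (e_ij / d0(N_I))²)

with the TM-score normalisation distance

    d0(n) = 1.24 · (max(n, 19) − 15)^{1/3} − 1.8 .

Restricting both frames i and targets j to interface residues **on opposite
chains** makes the score insensitive to monomer fold quality and purely a
statement about predicted inter-chain geometry. The score is 0 for an empty
interface and 1 when every cross-chain error vanishes. Design choices worth
stating explicitly, since several conventions would fit the verbal definition:

- **Frame set.** Frames range over interface residues only, and each frame's
  mean is taken over its qualifying cross-chain interface residues (so a
  perfect interface scores exactly 1.0). The alternative — dividing by N_I
  regardless of chain membership — is available via
  `iscore(..., normalize_by_total=True)` for sensitivity checks.
- **Asymmetry.** PAE is used as read; e_ij ≠ e_ji is meaningful (frame
  semantics) and no symmetrisation is applied.
- **d0 argument.** d0 is evaluated at N_I (the interface size), with the
  standard short-sequence clamp at 19; the clamp matters because interfaces
  of 10–30 residues are common.

The global analogue, pTM, uses the same kernel with frames and targets over
all N residues and d0(N).

## Confidence tiers and clash gating

iScore thresholds of 0.40 / 0.50 / 0.70 label predictions medium / high /
very-high confidence (boundaries inclusive). Benchmarks of this score on
~7000 putatively non-interacting *E. coli* pairs place the false-positive
rates of the three cutoffs at roughly 1.2%, 0.4% and <0.01%; those numbers
are carried as metadata on `TierScheme` for documentation — they depend on
thousands of GPU predictions and are not recomputed here.

Predicted models occasionally interpenetrate, which can produce an
artifactually high iScore; such models are filtered with a **clash
indicator**: the fraction of interface residues having any inter-chain
heavy-atom pair closer than 1.6 Å (a deep van-der-Waals overlap). Models with
indicator ≥ 0.4 are rejected before best-model selection. The published
screening protocol states the 0.4 rejection threshold but not the
indicator's internals; the 1.6 Å residue-fraction definition used here is a
documented stand-in that reproduces the intended behaviour (reject grossly
interpenetrating models) and both numbers are configuration knobs.

Per-target selection takes the highest iScore among surviving models; ties
break on higher mean pLDDT, then lexicographic model name. If every model of
a target is clash-rejected, a sentinel result with iScore 0 is reported
rather than an error, so a screen never stalls on one bad target.

## Screening protocol

Each (query, partner) job runs the predictor over 10 network names × 2 seeds
(defaults; seeds (0, 1)) with up to 8 recycles — 20 predictions per target —
and the per-target best scores are ranked over the whole library. Individual
prediction failures are logged and skipped; a target errors only if all its
predictions fail. Results are persisted one JSON per pair, so interrupted
screens resume exactly and desk-scale reruns are byte-reproducible. Reports
comprise a histogram of best iScores (bin width 0.05 on [0, 1]) and a table
of hits at tier medium or better.

## Feature assembly

Monomer feature bundles (sequence, MSA with the ungapped query as row 0,
template descriptors, residue range) are combined into complex features.
Caps reflect large-scale screening practice: MSA depth ≤ 5000 rows per
monomer, ≤ 4 templates per monomer, and ≤ 1600 residues per complex (jobs
over the cap are excluded and counted). Cropping an arbitrary residue window
restricts the sequence, every MSA column, and template spans consistently;
it implements the mature-chain convention (screening uses sequences with
their signal peptides removed) and protocols that deliberately starve the
predictor of coevolution signal (e.g. MSA depth 20 and zero templates, used
to model an unfolded substrate).

MSA pairing modes: `none` builds a block-diagonal MSA; `all_paired`
additionally joins rows sharing a species across **all** monomers into joint
rows placed before the unpaired block. The pairing key is the taxon
identifier parsed from sequence headers (`OX=`/`TaxID=`); untagged rows never
pair, and when a species has several rows in one monomer the first
(highest-ranked) is used — deterministic and in line with rank-based pairing
conventions. `cyclic`, `linear` and `arbitrary` are recognised and rejected
as not implemented.

## Library construction

The screening library ("envelopome") keeps every proteome entry whose
primary — first-listed — subcellular location is not cytosolic (keyword set:
`cytoplasm`, `cytosol`; configurable), with an accession allow-list for
peripheral-membrane proteins annotated as cytoplasmic that belong in the
library (the SecA case). Sequences containing non-standard amino acids are
removed before prediction. Mature ranges come from the annotated signal
peptide span (1..k → mature (k+1, L)). Input is a flattened TSV rather than
UniProt's native flat file, keeping the contract testable offline; the exact
keyword logic behind "primary location is not the cytosol" is not published,
so the keyword sets here are explicit configuration. The published library
counts (1466 envelope proteins, 11 non-standard removals, ~1450 after the
size cap) depend on a specific UniProt release and are documentation, not a
target of this package.

## Synthetic data

The fixture generator produces what the tests need and nothing more:

- **Toy dimers** — two ideal poly-alanine helices (rise 1.5 Å/residue, twist
  100°, Cα radius 2.3 Å, four pseudo-atoms N/C/O/Cβ at fixed local offsets
  with non-positive radial components) on parallel axes. Chain B is
  phase-shifted 180° so the chains face each other; the closest heavy-atom
  approach is then ≈ separation − 5 Å. The default separation of 7 Å gives a
  contact-rich, clash-free interface; 20 Å gives none. Translating the first
  k residues of chain B onto chain A forces k clash pairs.
- **Spaced dimers** — one residue pair per requested inter-chain distance,
  50 Å apart from the next pair, for exact analytic control of contact maps
  and clash fractions.
- **Confidence bundles** — two-level PAE (one value within chains, one
  across) with optional seeded uniform jitter (off by default so closed-form
  score checks hold exactly), and a flat pLDDT.
- **Mock predictor** — a deterministic adapter mapping (pair, model, seed) to
  fixture specs, enabling engineered score schedules for end-to-end screens.
- **Synthetic proteomes** — annotation tables with controlled fractions of
  cytosolic, signal-peptide-bearing (default 30%, typical of a cell
  envelope) and non-standard-residue entries.

What this synthetic surface does **not** emulate: real predictor error
structure (PAE correlations, per-residue pLDDT variation), realistic decoy
geometry, or sequence biology. Passing tests demonstrate that the scoring,
filtering and orchestration math is correct and deterministic — not that the
score separates true from false PPIs on real predictions; that evidence comes
from the benchmarks documented on `TierScheme`.

## Numerical and engineering choices

- Contact and clash criteria use strict `<`; ties at the cutoff are
  non-contacts.
- The scoring path is vectorised but gathers kernel terms in ascending
  global-index order, matching the exhaustive-frame reference ordering, so
  oracle comparisons in the tests are exact rather than tolerance-based.
- Alternate locations collapse to the highest-occupancy atom per name;
  hydrogens, waters and hetero-residues are dropped on read; NMR-style
  multi-model files use model 1.
- pLDDT precedence: an explicit vector in the confidence JSON overrides
  B-factor-derived values; B-factors are only interpreted as pLDDT when every
  per-residue mean lies in [0, 100].
- Binding a structure to a confidence bundle validates the total residue
  count, and per-chain lengths when the bundle records them — catching
  chain-order mismatches that preserve the total.
- Reported values follow the field's display convention: iScore to 2
  decimals, mean pLDDT to the integer.
- Test and validation problem sizes (dimers of ≤ 50 residues, 10-target
  screens, 100-entry proteomes, 200-case oracle sweeps) were chosen as the
  smallest sizes that exercise every code path and invariant; all suites run
  in seconds on one CPU.

## Limitations

- No neural-network inference: the predictor is an adapter contract, and the
  shipped mock generates geometry, not physics.
- No MSA construction or template retrieval; feature assembly starts from
  pre-generated monomer bundles.
- No buried-surface-area, hydrogen-bond or salt-bridge analysis; the
  interface model is purely distance-based.
- The clash indicator definition is a documented stand-in (see above), and
  the envelopome keyword filter is configuration, not a curated location
  ontology.
- The deposited-model validation harness (`ppiscreen.validate`) recomputes
  scores from coordinate+confidence pairs on disk and returns an empty result
  when a deposit directory is absent or lacks PAE files, by design.
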