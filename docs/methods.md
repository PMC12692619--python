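# Methods

This note records the models, parameter choices and numerical conventions
behind `allermap`, and what its tests do and do not establish.

## Coordinates and sequence handling

All interval coordinates are 1-based and inclusive end-to-end ("38~45"
means residues 38..45, both included), matching the convention of published
epitope tables; exports that resemble BED state this in their header.
Ambiguity letters (U/B/Z/J/O) are mapped to X at parse time with a logged
warning, and numeric operations reject X rather than invent a scale value
for it.  Signal peptides are removed with `mature_sequence(record,
signal_end)`; GRAVY and friends can be computed on either form — for the
reference allergens both forms are tried against the reported values, since
sources do not always state which form a summary statistic was computed on.

## Global physicochemistry

GRAVY is the unweighted mean of Kyte–Doolittle hydropathy; molecular weight
is the sum of average residue masses plus one water (via Biopython).  The
isoelectric point solves net-charge(pH) = 0 by bisection on the
Henderson–Hasselbalch charge with the EMBOSS pKa set (N-term 8.6, C-term
3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1), to
|charge| < 1e-4.  Commercial tools use other pKa tables (e.g. Bjellqvist);
pI values are therefore comparable only to ±0.2 pH across tools.  Percent
identity uses a substitution-free scheme (match 1, mismatch 0, gap −1, open
= extend) with identities counted over all alignment columns of one optimal
alignment; where several optimal alignments disagree the value is that of
the aligner's first, and the test oracle accepts any optimum.

## Propensity profiles

Windowed-mean profiles use the original publications' default windows:
Hopp–Woods 7, Kyte–Doolittle 9, Parker 7, Karplus–Schulz 7.  The default
edge policy is *shrink* (truncated window) so that profiles cover the
termini — published per-tool tables do report predictions at positions 1–2,
and an NaN-edged profile could never call them.  `edge_policy="undefined"`
yields NaN at non-fitting positions instead; NaN never passes a calling
criterion.

The Emini surface probability for the hexapeptide starting at n is
S = 0.37⁻⁶ · ∏ δᵢ, anchored at position n+2 (a center-ish anchor keeps
interval calling roughly symmetric; the original leaves the anchor to the
implementation).  Under the shrink policy terminal positions use the
truncated window with a matching 0.37^−len normalisation, so S = 1 remains
the random-expectation point everywhere.

The Jameson–Wolf antigenic index is
AI = 0.3·h + 0.15·s + 0.15·f + 0.4·c, where h, s, f are the
hydrophilicity, surface and flexibility tracks discretised onto
{−0.6, −0.3, 0, +0.3, +0.6} and c = +0.6 for turn/coil residues, −0.6 for
helix/sheet.  Two departures from the original are deliberate: (1) the
original's two 0.2-weighted secondary-structure terms (two predictors) are
collapsed into a single 0.4-weighted consensus term, because this package
produces one secondary-structure consensus; (2) class cutoffs are the
track's own quintiles rather than the commercial implementation's
unpublished absolute thresholds — per-sequence quantiles keep class
occupancy stable across sequences with very different dynamic ranges.  A
constant track lands in the lowest class under this rule; acceptable, since
a track with no variation carries no signal to rank.

## Secondary structure

Chou–Fasman follows the published nucleation/extension scheme: helices
nucleate where ≥ 4 of 6 consecutive residues have P(helix) ≥ 100 and extend
while the running 4-residue mean stays ≥ 100; sheets nucleate at ≥ 3 of 5
with P(sheet) ≥ 105 and extend at ≥ 105; a tetrapeptide is a turn when the
positional bend-frequency product exceeds 7.5e-5 and its mean P(turn)
exceeds 100 and both the helix and sheet means.  Turns override
helix/sheet; helix/sheet overlaps go to the locally higher mean propensity;
everything else is coil.

The GOR-style predictor sums directional information values over a
17-residue window (offsets −8..+8) and takes the per-residue argmax, ties
resolving to coil.  **Parameter provenance:** the shipped table
(`allermap-dr1`) is a *derived* set — self-information 10·ln(P/100) from
single-residue conformational propensities, attenuated linearly with
distance from the window centre — not a transcription of the original
experimentally counted table.  It follows the GOR functional form and is
exercised against an independent re-summation oracle, but no numerical
parity with published GOR servers is claimed.  Consequently the
SOPMA-style stage of the pipeline is a documented stand-in (SOPMA proper
depends on a homolog database whose state is unreproducible), and
reproduction of published SOPMA interval tables is explicitly not asserted;
those tables enter the consensus as packaged fixtures instead.

Turn (T) is kept as a first-class state end-to-end because the epitope
selection criteria favour turn/coil residues; the coil-fraction statistic
over epitope regions is computable as coil-only or coil+turn via a flag.

## Two-state epitope scorer

The scorer mirrors the classic design of an HMM plus a hydrophilicity
scale.  The published tool's trained weights are unavailable, so the
two-state model (epitope/background) is re-estimated from interval-labelled
sequences: add-one-smoothed emission counts per state, add-one-smoothed
label-pair transition counts.  The posterior epitope probability comes from
scaled forward–backward initialised at the transition matrix's stationary
distribution (so uninformative emissions give a flat posterior equal to the
stationary epitope mass).  The final score is
w·(2·posterior − 1) + (1 − w)·z(Parker), w = 0.5 by default, with the
conventional 0.35 decision threshold applied by interval calling.  The
affine calibration of the score is a free choice recorded here; downstream
consensus consumes only intervals, so fixture intervals and scorer
intervals are interchangeable by construction.

## Region calling and consensus

A residue passes the multi-criterion call iff every enabled criterion holds
strictly: hydrophilicity > 0, antigenic index > 0, surface > 1, flexibility
> 1 (the average-mobility baseline of the flexibility scale —
"flexibility" alone names no cutoff, so the baseline is the natural
operationalisation, config-overridable), optionally SS ∈ {T, C}.  Maximal
passing runs shorter than 5 are dropped; runs longer than 30 are split
recursively at the weakest antigenic-index residue (the length bound is
stated in the literature without a mechanism; splitting at the weakest link
is this package's choice).  Residue-wise AND, rather than region-averaged
criteria, is implemented.

Consensus semantics are residue-level: support(i) = number of distinct
tools covering residue i (duplicate intervals within one tool count once);
consensus epitopes are maximal runs with support ≥ k, filtered at min_len
(defaults k=2, n=3, min_len=5).  Residue-level counting, not pairwise
interval intersection, is the load-bearing choice: it reproduces the
textbook common-segment example *and* regions stitched together by
different supporting pairs, which pairwise intersection cannot.  Gap
semantics for `merge_adjacent`: the gap between two intervals is the count
of uncovered residues between them, so [1,5] and [6,9] (gap 0) merge at
max_gap 0 while [1,5] and [8,9] (gap 2) do not merge at max_gap 1.

### Packaged fixtures and their corrections

The per-tool interval tables for Ses i 1–7 are shipped verbatim with two
corrections, each a data record (`FixtureCorrection`) applied at load time
and returned to the caller: Ses i 1 "5~52" → "50~52" (an interval 5..52
would contradict the published consensus row under any k-of-n rule) and
Ses i 7 "4576~459" → "457~459" (position 4576 exceeds the protein length).
Running the consensus on the corrected tables regenerates the published
consensus rows exactly for Ses i 1, 2, 3 and 5 (flagged rule-consistent).
Ses i 4 and Ses i 6 rows contradict the stated rule applied to the printed
inputs, and Ses i 7 yields one extra region (415–419) beyond the printed
fourteen; these are flagged discrepant — whether manual curation or
unprinted intermediate data intervened is unknowable, so the package
reports the discrepancy rather than forcing the printed rows.  The
sequence length used per allergen is the maximum interval end over the
three corrected tables (a lower bound on the true length; support counting
only needs coverage of the printed extent).

## Structure mapping

PDB and mmCIF models are read with gemmi (first model, first protein
chain unless a chain id is given; hydrogens dropped).  Solvent-accessible
surface area is Shrake–Rupley with probe 1.4 Å and a deterministic golden-
spiral point set (960 points per atom by default): a sample point on the
expanded sphere (vdw + probe) is accessible iff it lies outside every
neighbour's expanded sphere.  Determinism makes the tests exact; the
sampler is cross-checked against an independent Fibonacci-lattice
implementation with identical per-atom radii (1 % agreement at 3840
points) and against the closed-form sphere area for an isolated atom.
Relative accessibility divides per-residue ASA by a fixed theoretical
maximal-ASA table (extended Gly-X-Gly reference, recorded in
`allermap.scales`); several such tables exist, and the choice is part of
the configuration.  An epitope is called exposed at mean RSA ≥ 0.25, a
common convention — the underlying visual-inspection practice states no
cutoff, so the threshold is this package's own and config-overridable.
pLDDT is read from the B-factor column; files on the 0–1 scale are
auto-detected (max ≤ 1.0) and rescaled to 0–100.  pTM is pass-through
metadata, never recomputed.  A numbering offset parameter reconciles
mature-chain models with full-length sequence coordinates.

## Synthetic data

`generate_protein` draws background residues uniformly over the 20-letter
alphabet and planted segments from a biased alphabet enriched in K/E/D
(hydrophilic) and G/S/P (flexible, coil-prone) — the residue classes the
selection criteria reward — so planted segments are hydrophilic in nearly
every realisation (sign test in the suite).  `generate_tool_predictions`
perturbs the truth per tool: boundary jitter ±j, per-interval drop
probability, Poisson false positives (rate per 100 residues, lengths
5–12).  Defaults for the round-trip experiments are jitter 2 and fp rate
0.02, i.e. a few-residue boundary disagreement and an occasional spurious
call per few hundred residues — the scale of disagreement actually seen
between epitope servers.  All generators are bit-reproducible given
(spec, seed).

`end_to_end_recovery` has two modes.  `mode="intervals"` (default) runs
truth → jittered tools → consensus and is the basis of the recovery
guarantees: with zero noise the round trip is lossless for segments ≥
min_len, and across 20 seeds the jittered consensus recall is at least the
average single-tool recall.  `mode="profiles"` replaces the simulated
tools with the real scoring routes (profile-suite calling, turn/coil runs,
a two-state scorer trained on the generated labels); no recovery guarantee
holds there — which is the honest situation for real sequences, where the
synthetic generator's uniform background and clean composition bias do not
capture domain structure, repeats or family homology.  Passing tests on
synthetic data therefore validate the *algebra* of the pipeline (calling,
merging, consensus, recovery bookkeeping), not predictive accuracy on real
allergens.

## Problem sizes and determinism

The oracle-equivalence batteries run at sizes where the oracles are exact
and fast: consensus vs counting oracle on 1000 random instances (≤ 4
tools, length ≤ 200), forward–backward vs exhaustive enumeration at length
≤ 8 (≤ 256 paths), GOR vs re-summation on 200 random 30-mers, SASA
convergence at 240/960/3840 points on ~10-atom models.  Every stochastic
test and generator is explicitly seeded; hypothesis-based property tests
run derandomised.

## Known limitations

- The GOR parameter set is derived, not the historical table; secondary-
  structure output should be treated as a coarse four-state prior, not a
  modern prediction.
- The two-state scorer is a re-estimated stand-in; its absolute scores are
  not comparable to the original server's, only its interval behaviour is.
- Percent identity under the match/mismatch/gap scheme is one convention
  among several; published identity percentages computed with other
  denominators can differ by several points.
- The exposure call reduces an epitope to its mean RSA; a region can be
  "exposed" on average while burying individual anchor residues.
- Fixture sequence lengths are lower bounds inferred from interval extents;
  peptide strings for fixture consensus regions require supplying the
  actual sequences.
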