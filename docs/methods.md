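# Methods

This note records the model, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Chain model and geometry

Residues carry five centres — backbone N, CA, C, O and an ideal tetrahedral
Cβ (also placed virtually on glycine so contact distances are uniformly
defined). Coordinates are a deterministic function of per-residue
(φ, ψ, ω) torsions via natural-extension (NeRF) construction with fixed
ideal bonds (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å) and angles.
ω defaults to 180° (trans) unless a fragment supplies otherwise. There are
no side chains beyond Cβ: the fidelity target of the tool is topology
(TM-score), which Cβ-level geometry supports; all contact distances follow
the Cβ–Cβ (Cα for glycine) convention.

Secondary structure of built chains is classified from torsions
(helix: φ ∈ [−120°, −20°], ψ ∈ [−100°, 10°]; strand: φ ∈ [−180°, −80°],
ψ ≥ 90° or ≤ −170°); the same windows drive the HB term, fragment
annotation and the synthetic generator, so the three never disagree.

### TM-score search

TM = (1/L)·Σ 1/(1 + (dᵢ/d₀)²), d₀ = 1.24·(L−15)^⅓ − 1.8 clamped to
≥ 0.5 Å. The maximisation seeds a superposition from every contiguous
window of lengths {L, L/2, L/4, 4} and refines each by iteratively
reweighted Kabsch superposition with weights 1/(1 + (d/d₀)²)² — the
stationarity weights of the TM objective, so fixed points are exactly its
local maxima. For chains of ≤ 24 residues the search additionally seeds
from every 3-residue subset: short chains have d₀ at its floor and a spiky
multi-modal landscape where window seeding alone can stop ~0.01–0.04 below
the global optimum. With subset seeding the returned score matches an
independent brute-force optimiser to ~1e−9 on random chains. The search is
deterministic; for equal-length pairs the score of (a, b) and (b, a) can
differ by search noise, so ensemble statistics use the maximum of the two
orientations.

## Energy function

E_total = Σ Wₖ·Eₖ over seven terms. The contact term (RR) implements the
square-well-with-decay law: −P inside d_con = 8 Å, then
P·(1 − 2·e^{−(d−d_con)/τ}) with decay length τ = 4 Å — continuous at the
well edge, strictly increasing outside it, linear in P, and saturating at
the +P violation penalty. τ = 4 Å puts ~95% of the asymptotic penalty at
d ≈ 20 Å, keeping gradients local.

The statistical terms are desk-scale stand-ins with fixed functional forms
(the classic fragment-assembly potentials are not published in portable
form); each sits behind the `EnergyModel` interface so a faithful port can
replace it:

* **SR/LR** — inverse-Boltzmann pair potentials over a reduced 7-class
  alphabet (hydrophobic, aromatic, polar, positive, negative, glycine,
  proline), Cβ distances binned 0–15 Å in 0.5 Å steps, separation classes
  5–10 and > 10. Entries are −ln[(f_obs + α)/(f_exp + α)] with expected
  frequencies from the pair × bin marginals. The pseudocount α = 1e−4 acts
  on *frequencies*, making the table exactly invariant under rescaling all
  counts; it corresponds to roughly one count at desk-scale training sizes
  (~10⁴ pairs).
* **SOLV** — per-residue burial preference: −h·min(n, 12)/12 with h the
  Kyte–Doolittle hydropathy scaled to [−1, 1] and n the number of Cβ
  neighbours within 10 Å.
* **HB** — a secondary-structure reward: −(confidence) for each residue
  whose backbone torsions fall in the basin of its predicted H/E state.
* **COMPACT** — (R_g − 2.2·L^0.38)², penalising both collapse and
  expansion around the globular scaling law.
* **STERIC** — quadratic clash repulsion Σ max(0, r_clash − d)² over Cα
  and Cβ centres with residue separation ≥ 2 (thresholds 4.0 / 3.7 /
  3.85 Å for Cα–Cα / Cβ–Cβ / mixed). Restricting clash detection to the
  two largest centres keeps a full energy evaluation at ~10⁴ distance
  computations for a 60-mer, which the Monte Carlo inner loop requires.

### Weight calibration

Wₖ = factorₖ · σ(SR)/σ(termₖ), with spreads measured over 200
random-torsion conformations of the target (φ, ψ uniform, ω trans) and
user factors 1 everywhere except STERIC ×3 and RR ×5. A caveat worth
recording: STERIC and COMPACT are heavy-tailed over uniform random chains
(excess kurtosis ≈ 4.5), so a standard deviation estimated from 200
conformations carries ~9% sampling error; comparing calibrated spreads
against an *independent* 200-strong ensemble shows 10–27% deviations
across seed pairs. Calibration checks therefore verify the weight
definition on the calibration seed family; users wanting tighter
equalisation should raise `n_random`.

## Fragments

Fixed 9-residue windows (one helical turn plus flanks) and supersecondary
fragments — two secondary elements of ≥ 4 residues joined by a loop of
≤ 8 — are cut from source structures, with secondary structure assigned
geometrically. Windows with ungapped local sequence identity ≥ 0.35 to the
target are removed (blind-prediction decontamination). Shortlists per
position keep fragments whose geometric secondary structure matches the
prediction at ≥ 70% confidence-weighted agreement, ranked by a threading
score (the pair potential evaluated on the target residues mounted on the
fragment geometry; no solvation term, for speed), ties broken by
(source, offset) for determinism.

## Sampling

Replica-exchange Metropolis Monte Carlo over torsions, starting from an
extended chain (φ = −139°, ψ = 135°). Moves: fragment replacement at a
random shortlist position (p = 0.8) and single-angle Gaussian perturbation
(σ = 10°, p = 0.2). Defaults: 8 replicas on a geometric ladder between
kT = 10 and 0.5, exchanges between neighbours every 500 steps, the whole
ladder annealed linearly over the run; all exposed in `AnnealConfig`.
`steps` counts moves summed over replicas. One exchange block is one
*cycle*: in sequential mode the maximum active contact separation ramps
linearly from 9 to L−1 across cycles (round-half-up), so the active set is
nested and ends complete. The decoy returned is the lowest-energy
conformation visited by the coldest replica (ties keep the latest state, so
a flat objective returns the final state rather than the start). Full-scale
step counts (5M below 120 residues, 10M at or above) are reachable through
`steps_for_length`; the shipped studies use 50 000-step runs, which suffice
to fold the 60-residue synthetic targets.

## Model selection and quality assessment

Selection: ascending-energy ranking (top-1, top-5, best-top-5 against a
native in benchmark mode) and greedy TM-score clustering (repeatedly take
the decoy with most neighbours at TM ≥ 0.5 as a representative). QA without
a native combines the ensemble's mean pairwise TM-score with the
long-range contact-satisfaction score MQA_LR = CON_LR·ln(1 + N_LR), where
N_LR counts top-L predicted contacts with separation > 23 and CON_LR the
fraction satisfied at Cβ–Cβ ≤ 8 Å in the assessed model; separation 23
itself is classed mid-range. CS = 7·⟨TM⟩ + 1·MQA_LR, with CS > 3.4 the
default predicted-correct call (alternatives 3.0 ↔ TM ≥ 0.4 and
6.0 ↔ TM ≥ 0.7). The assessed model is the lowest-energy decoy when
energies exist, else the ensemble medoid (relevant for synthetic decoy sets
that were never annealed). The fragment-fit outlier rule flags values
≥ Q3 + 1.5·IQR with type-7 (linear-interpolation) quartiles; constant
lists return no outliers.

## Synthetic benchmark

Toy proteins are ideal-torsion elements joined by short loops whose base
torsions were optimised once so the elements pack (helices ~9 Å apart,
paired strands ~5 Å): a helix hairpin, a three-helix bundle (the middle
helix length is kept at 12 + 18k residues to preserve the packing phase of
the third helix), a β-hairpin, and a mixed β-β-α fold. Generation jitters
loop torsions (σ = 5°) and resamples up to 100 times until the chain is
clash-free *and* retains at least half of the jitter-free layout's
contacts — the second condition keeps accepted "natives" genuinely packed
(a 60-residue hairpin accepted at the floor still holds ~12–20 long-range
contacts). Stricter retention levels make the rejection sampler exhaust
its budget on long two-element topologies, where loop jitter acts on a
long lever arm; at one-half the generator succeeds across topologies,
lengths 30–120 and wide seed ranges. A seed that still exhausts the
budget raises, per the generator's error contract. Sequences are drawn per position from
secondary-structure-appropriate residue pools (heptad hydrophobic pattern
in helices, alternation in strands), randomised so independent toys do not
trip the library decontamination filter.

Contact predictions sample round(n·p) true native contacts (Cβ ≤ 8 Å,
separation ≥ 5) and n − round(n·p) false pairs whose native distance
exceeds 12 Å, so truth labels survive coordinate jitter. PPVs are drawn
iid (uniform) by default, making every top-k prefix unbiased at precision
p; the truth-correlated mode draws Beta(4,2)/Beta(2,4), mimicking an
informative ranking. Labelled decoy sets combine near-native decoys
(loop-torsion jitter, σ = 8°) with fold-destroyed ones (9-residue torsion
blocks permuted and junction torsions re-drawn — pure block permutation
would leave quasi-periodic all-helix chains nearly native).

### What passing means — and does not

The synthetic study conditions demonstrate that the machinery works as
specified: contacts of controlled precision measurably and significantly
improve folding over the no-contact baseline; CS separates correct from
incorrect ensembles. Real proteins differ in ways the generator does not
emulate: irregular loops and element geometries, side-chain packing,
predicted-contact error structure that correlates with alignment depth,
and much larger conformational spaces. Quantities measured here (e.g.
fold-success fractions near 0.9 on 60-residue toys) therefore characterise
the implementation under idealised inputs, not expected performance on
crystallographic targets.

## Numerical and reproducibility notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; Monte Carlo blocks derive per-block seeds
  from the run seed, making `fold`, `assess` and `synth` bit-reproducible.
* Energies are evaluated by full recomputation per move (no incremental
  updates), in numba-compiled kernels; a decoy's stored energy is always
  recomputable from its coordinates to 1e−6.
* Torsions wrap modulo 360°; φ of the first residue and ω of the last are
  not encoded in coordinates and are restored to extended-chain defaults
  on extraction.
* PDB output is ATOM-record only (one chain, sequential numbering);
  ensembles use MODEL/ENDMDL blocks with per-model energy REMARKs. Readers
  keep altloc 'A'/blank, collapse insertion codes, and record chain breaks
  (Cα–Cα > 4.5 Å) and incomplete residues as fragment-segment boundaries
  rather than errors.
* MSA filtering removes duplicates first, then query-gapped columns, then
  rows under 30% identity to the target (identity = matches over non-gap
  query columns); the operation order among the first two is immaterial,
  the identity filter must come after column deletion for its stated
  denominator.
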