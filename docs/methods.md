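# Methods

This note documents the models implemented in `memsense`, the assumptions
behind them, the parameter choices that were genuinely open, and what the
test suite does and does not establish.

## The free-energy chain

The central quantity is the relative curvature-sensing free energy ΔΔF
(kJ/mol) of a peptide: its affinity for a curved/stretched membrane relative
to a flat, relaxed one. Binding into lipid packing defects at curved surfaces
removes an energetic penalty, so ΔΔF ≤ 0 for almost all sequences, with the
theoretical optimum near −30 kJ/mol for hydrophobic, bulky 24-mers.

Four fitted transformations connect ΔΔF to an observable binding probability;
all constants live in `memsense.constants.PhysicsConstants` and can be
overridden from a `key = value` file:

| constant | value | units | role |
|---|---|---|---|
| a_L, b_L | −1.03, 3.28 | kJ/mol per residue, kJ/mol | linear length trend used to extrapolate ΔΔF to the 24-residue reference |
| c_z | −0.93 | kJ/mol per charge | anionic-membrane charge correction |
| α, β | 3.83, 12.27 | —, kJ/mol | affine ΔΔF → ΔF_sm map (flat membrane) |
| ε_ref | 0.165 | — | reference membrane strain dividing ΔΔF in the curvature term |
| N_s/N_m | 5.2·10³ | — | solvent/membrane microstate ratio in the sigmoid |
| RT | 2.478 | kJ/mol | thermal energy (298.15 K) |

Numerical choices made here:

* **The sigmoid exponent is ΔF_sm/RT.** The probability switch is written as
  a bare exponential in some presentations; dimensional consistency requires
  division by a thermal energy, and only RT ≈ 2.478 kJ/mol makes the
  P_m = 0.05/0.95 crossings at R = 50 nm coincide with the published class
  boundaries (−6.4, −10.0 kJ/mol). 300 K would also round correctly at one
  decimal; 298.15 K is the documented default.
* **The curvature term divides by ε_ref** (ΔΔF per unit strain, scaled by the
  vesicle strain 1/R² + 2/R). The alternative reading (multiplication) fails
  to reproduce the same boundary values, which is the package's internal
  consistency test (`derive_class_boundaries`).
* **Flat membranes are a sentinel** (`FLAT`), never a large finite radius;
  vesicle radii are in nanometres throughout.
* **Sensor boundaries are inclusive on both ends**: ΔΔF_eff of exactly −6.4
  or −10.0 kJ/mol classifies as sensor. No rounding is applied before
  thresholding.
* **Saturation**: the sigmoid's exponent is clamped at ±700 (dimensionless)
  so extreme inputs saturate toward 0/1 instead of overflowing.
* The charge correction accepts any integer charge but logs a caution outside
  z ∈ [−1, +4], where the linear fit is an extrapolation.

## Sequence descriptors

Net charge counts K/R as +1 and D/E as −1, with histidine neutral and termini
ignored — the underlying free-energy data used fixed-length 24-mers, and no
terminus rule is defined for them; the residue table is overridable. Mean
hydrophobicity uses the Fauchère–Pliška (1983) octanol/water scale. The
hydrophobic moment places residue k at k·100° (ideal α-helix) and reports the
per-residue mean |Σ h_k e^{ikθ}|/N; the same Fauchère–Pliška values are used
inside the moment for internal consistency (conventions differ across tools,
and the normalized Eisenberg consensus scale is a common alternative). The
total (unnormalized) moment is exposed as well.

## The sequence regressor

The regressor maps a tokenized peptide (20 residue tokens + padding, right-
padded to 24) to ΔΔF. The architecture is a pre-norm transformer encoder:
learned token and positional embeddings, self-attention blocks with a key
padding mask, masked mean pooling, and a linear head; training minimizes MSE
with Adam and early-stops on a validation split. It is implemented directly
in numpy (float64, analytic gradients, finite-difference-checked in the test
suite), which keeps the package dependency-light and makes seeded runs
bit-reproducible.

Defaults — 2 layers, 8 heads, 64-dim embeddings, 128-dim feed-forward,
batch 64, learning rate 10⁻³, 80/10/10 split, patience 10 — are sized for the
few-thousand-example synthetic datasets the package trains on by default;
every knob is a `ModelConfig` field so larger settings can be dropped in for
the external MD dataset. Dropout exists but defaults to 0 (the default
datasets are small enough that early stopping is the effective regularizer,
and 0 keeps training deterministic).

An additive least-squares model on residue counts (`AdditiveDdgModel`) serves
as baseline and oracle. It fits without an intercept by default: counts sum
to the fixed length 24, so with an intercept the coefficients are only
identifiable up to a uniform shift (the gauge is fixed by centring when
comparing to generative truth). Residues absent from the training data yield
flagged NaN coefficients; a design whose informative columns are dependent
(e.g. all-identical sequences) sets a rank-deficiency flag instead of
raising.

## Synthetic data

`generate_synthetic_dataset` emulates the salient structure of the MD-derived
training set: 24-residue sequences with an additive composition → ΔΔF ground
truth in which hydrophobic/bulky residues (L I V F W M Y C) contribute
−1.4…−0.8 kJ/mol each and all others −0.25…+0.15 kJ/mol, plus Gaussian noise
of 1.0 kJ/mol (the typical MD replica standard deviation). Coefficients are
drawn once per dataset from these ranges. Each sequence receives its own
hydrophobicity propensity p ~ U(0,1) so that the ΔΔF distribution covers the
whole applicability domain from ≈0 down to ≈−30 kJ/mol; uniform-random
sequences would concentrate near the middle by the central limit theorem.

What this does *not* emulate: position-dependent and pairwise interactions
(amphipathic periodicity, helix capping), the non-uniform sequence
composition of an evolutionary search, and MD force-field systematics.
Consequently, passing tests demonstrate that the regression stack recovers an
additive signal at the stated noise level and scale — they do not certify the
published accuracy on real MD data, which would require the external dataset.
Default test/acceptance problem sizes are 5 000 examples (noise 1.0 kJ/mol)
for training and recovery checks, chosen as the smallest scale at which the
noise-floor behaviour is clearly visible.

## Structure screening

Per chain, contiguous fragments of standard residues are extracted
(nonstandard residues with a standard parent, e.g. selenomethionine, are
mapped to it; anything unmappable, plus author-numbering gaps, splits the
fragment). Each fragment is scanned with a stride-1 window (default 15,
range 7–24); fragments shorter than the window but ≥ 7 residues are scored as
a single segment; shorter ones are skipped with a warning and marked
"not screened".

Order of operations (pinned by tests): each window's predicted ΔΔF is first
length-extrapolated to 24 residues, then charge-corrected with the *window's*
net side-chain charge when the membrane is anionic, and only then averaged
per residue and thresholded. Both averaging windows (segment scores and SASA
smoothing) truncate at fragment ends.

SASA uses the Shrake–Rupley algorithm (Biopython's implementation, probe
1.4 Å, 960 sphere points, bundled Bondi-type element radii with a 1.8 Å
fallback), aggregated per residue in nm², computed once on the full assembly
so chains occlude each other. Hydrogens are stripped by default (most
depositions lack them, and this keeps results comparable); ligands and waters
are excluded from sequences but kept as occluders, switchable via
`ScreenConfig`. The exposure gate compares the *smoothed* SASA (mean over
n−4…n+4) against the 0.8 nm² threshold — smoothing is what turns atomically
rough accessibility into a motif-level quantity. An independent Monte-Carlo
surface sampler in the test suite pins the per-atom values within 2%.

The annotated PDB encodes the residue call in the B-factor column
(0.0 non-binder or not accessible / not screened, 0.5 sensor, 1.0 binder);
for PDB inputs only those six columns are rewritten and every other byte is
preserved.

## Benchmarking

Chains are cut into consecutive non-overlapping 15-residue fragments
(trailing remainder dropped). A fragment is positive when it contains at
least `min_hits` flagged residues; sensor and binder calls both count as
prediction hits. `min_hits` defaults to 1 — the ≥1 reading closes the gap
between "more than one residue" and "none" phrasings of the rule — with the
stricter ≥2 reading one flag away. MCC, FDR = FP/(FP+TP) and
FOR = FN/(FN+TN) are reported; zero denominators yield 0.0 with an explicit
degeneracy flag. Reference regions are user-supplied (chain, start, end)
ranges; no curated test set ships with the package.

## Known limitations

* The predictor assumes α-helical folding of every window; non-helical
  regions get composition-driven scores that should be read with caution.
* Short peptides (≤ 12 residues) sit on the steep end of the length
  extrapolation; predictions there are flagged in the log.
* The charge correction is linear and window-local; long-range electrostatics
  and terminus charges are ignored.
* The bundled regressor defaults are tuned for synthetic-scale data, not for
  the external 50k-peptide MD dataset; reproducing the published held-out
  error requires that dataset and is deliberately out of scope here.
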