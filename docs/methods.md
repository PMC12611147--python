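# Methods

## The mechanistic model

`pottsnet` simulates in-vitro vasculogenesis with a two-dimensional
Cellular-Potts (Glazier–Graner–Hogeweg) model on a periodic square lattice.
Each of ~1000 endothelial cell agents is a set of lattice sites sharing an
integer id; site 0 is the extracellular medium.  The effective energy is

    H = Σ_{⟨i,j⟩} J_{τ(σ_i),τ(σ_j)} (1 − δ_{σ_i,σ_j})
      + Σ_cells [ λ_vol (V − V_t)² + λ_surf (S − S_t)² ]

with a per-copy saturated chemotaxis bias
`−λ_chem [ c_dest/(s·c_dest+1) − c_src/(s·c_src+1) ]` toward a chemoattractant
field `c` that the cells themselves secrete, and which obeys

    ∂c/∂t = D ∇²c − k c + secretion·1(site occupied).

Dynamics are modified-Metropolis: one Monte-Carlo step (MCS) is `L²` random
pixel-copy attempts (uniform site, uniform 4-neighbor source), each accepted
with probability `exp(−max(0, ΔH/H′))`, followed by one field update.  The
chemotaxis term is path-dependent (it compares source and destination sites
of a specific copy), so it contributes to per-attempt ΔH only and adds
nothing to the static total energy.

### Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| λ_vol, V_t | volume constraint | 5, 50 | energy/site², sites |
| λ_surf, S_t | surface constraint | 1, 16.8 | energy/face², faces |
| J_cm, J_cc | contact energies | 8.2, 6 | energy/face |
| λ_chem, s | chemotaxis strength, saturation | 2000, 0.5 | energy, 1/conc. |
| k | field decay | 0.6 | 1/MCS |
| H′ | Potts temperature | 8 | energy |
| D | field diffusion | 8.0 | sites²/MCS |
| secretion | per-site secretion rate | 100.0 | conc./MCS |
| L, N | lattice size, initial cells | 256, 1000 | — |

The energy and decay parameters are the published parameterization of this
model.  `D` and the secretion rate have no published values; they were chosen
once from the calibration scan in `docs/calibration.md` (morphology gate plus
the most mobile interfaces among passing candidates) and are not revisited.

### Conventions the energy function does not fix

- **Contact neighborhood.** The contact sum runs over the 8-connected Moore
  neighborhood by default (`contact_neighbor_order=2`), matching common
  practice for this model family; copy-attempt candidates and surface-face
  counting use the 4-connected neighborhood.  Both are configurable.
- **Chemotaxis interface rule.** `chemotaxis_mode="push_pull"` (default)
  applies the bias whenever source and destination ids differ: a cell
  advancing up-gradient is rewarded, a cell displaced by medium is penalized
  for retreating from high concentration.  `"extension_only"` restricts the
  bias to copies whose source is a cell.  Calibration scans showed the choice
  does not alter the study conditions materially.
- **Cell book-keeping.** No connectivity constraint: cells may fragment, and
  a cell whose volume reaches zero is removed.  The medium carries no volume
  or surface term.
- **MCS unit.** Same-id copy proposals count as attempts but are skipped
  without energy evaluation, keeping one MCS = L² attempts exactly.

### Field solver numerics

Forward Euler with the 5-point periodic Laplacian, `pde_substeps` substeps of
`dt = 1/n` MCS each.  Stability and positivity require `D·dt ≤ 1/4`,
`k·dt ≤ 1` **and** the combined bound `dt·(4D + k) ≤ 1`: the update scales the
central value by `1 − 4D·dt − k·dt`, which must stay non-negative for
concentrations to remain non-negative.  The configuration object refuses to
integrate outside these bounds rather than produce quietly unstable output.
Secretion adds a constant rate at every cell-occupied site (no concentration
clamping).  A fused jitted kernel (`step_field_fast`) produces bit-identical
results to the numpy reference and is what the MCS loop calls.

### Initialization and protocol

Exactly `n_cells_initial` cells (default 1000) are placed as non-overlapping
5×5 blocks (25 sites ≈ half the target volume, so cells grow into contact)
uniformly at random, field zero.  `simulate` burns in unsaved to
`mcs_start_save` (default 200, by which the cells have settled into a
network), then records (vessel mask, field) snapshots every `save_every` MCS
through `mcs_end` (protocol default 20,000 at unit cadence).  Runs are
bit-reproducible given `(params, seed)`; the sweep kernel's generator is
seeded from the simulation's seed stream.

## Dataset construction

Frames are two channels: the binary occupancy mask, and the field divided by
the saturation concentration `c* = secretion/k` — the analytic fixed point of
the field equation, which puts typical concentrations at O(1); the constant
is stored in the dataset.  Pairs match `t` with `t + horizon` (default 100
MCS).  The pairing convention is half-open: a pair is kept only when its
target precedes the final saved MCS, so the full protocol window
(200…20,000 at unit cadence, 19,801 states) yields exactly 19,700 pairs per
simulation.  The 80/20 split is a seeded shuffle over pairs; passing
per-pair simulation labels (`split_dataset(..., groups=...)`) switches to a
group-level split so no simulation contributes to both sides, avoiding
temporal leakage — random-over-pairs remains the default.

## The surrogate

A classic U-Net reconstructed at configurable depth/width (default 4 levels,
32→512 channels; tests and the desk-scale protocol use smaller
configurations): per level two 3×3 convolutions with PReLU, 2×2 max-pool
down, nearest-neighbor up plus a channel-halving convolution, skip
concatenation, and two 1×1 heads — mask logits and a linear field head.
Every convolution uses circular padding, so the network commutes exactly
with cyclic shifts by multiples of `2^depth` — the symmetry the periodic
lattice demands, and a property the tests assert.  The layers are implemented
directly on numpy (float32, im2col-style einsum convolutions) with explicit
backward passes; the whole-network gradient is verified against central
differences in the test suite.

Training minimizes per-pixel binary cross-entropy on the mask channel plus
10× mean-squared error on the field channel (the documented weighting),
using Adam (lr 1e-3 default; desk-scale runs use 2e-3) with seeded shuffling.
Prediction applies a sigmoid to the mask head (probabilities in (0,1);
binarization at 0.5 is the metrics module's concern) and clips the field at
zero.  Rollout feeds continuous outputs back by default — the smoothing this
compounds is a documented failure mode, not an artifact — with an optional
binarized mode.

## Evaluation

- **Dice** `2|A∩B|/(|A|+|B|)` on masks thresholded at 0.5; defined 1 when
  both masks are empty.
- **Field MSE** on the normalized concentration scale.
- **Lacunae areas**: medium regions are extracted with the plus-shaped
  5-tile patterning of the mask (corners filled with vessel), 4-connected
  labeling, a shape descriptor per region (area + image inertia-tensor
  eigenvalues rounded to 6 decimals), duplicate removal, and a 3-site floor
  (1–2-site holes are Potts noise).  Duplicates are keyed by torus-component
  identity by default, which is provably identical to brute-force connected
  components on the torus (asserted against a union-find oracle on random
  masks); the pure shape-signature rule is available as `dedup="signature"`
  but collapses congruent distinct lacunae.  Regions the plus canvas cannot
  close (they touch its outer frame) take their area from the torus
  component.
- **EMD**: Wasserstein-1 between the two empirical area distributions with
  equal total mass, so frames with different lacunae counts are comparable.
  Two empty sets give 0; one empty set is an error surfaced to the caller
  (rollout evaluation records NaN for such steps).
- **Divergence diagnostics**: per-step total vessel area and un-normalized
  field mass for prediction and truth — the conserved-quantity drift that
  explains long-rollout failure.
- `evaluate_rollout` applies the one-step model recursively from an unseen
  MCS-2000 configuration and reports every metric next to the frozen
  reference (the unchanged input frame) against the same ground truth: the
  do-nothing predictor the surrogate must beat.

## What the generator emulates, and what it does not

The generator produces the study conditions end to end: stochastic
network-forming dynamics, a co-evolving secreted field, and rendered
two-channel training data.  It does not emulate real microscopy (no imaging
noise, no segmentation errors, no sub-pixel structure), so passing tests
demonstrate the surrogate pipeline against the mechanistic model only, not
against experimental images.

One measured property of the defaults matters when reading the numbers:
under this parameterization the network forms during the burn-in and is then
nearly static at the 100-MCS horizon.  Across the full calibration scan
(D ∈ 0.5…60, secretion ∈ 0.03…1000, both chemotaxis modes, both contact
neighborhoods) the frozen-reference Dice at lag 100 stays in 0.98–0.9999
(defaults: 0.991 ± 0.0004 over seeds at 256²; field MSE ≈ 1.4e-4; lacunae
EMD ≈ 2.2).  Strong chemotaxis pins interfaces inside self-generated
gradient wells, and with chemotaxis off the contact/constraint stiffness at
H′ = 8 still yields Dice ≈ 0.985 — interface motion of order one site per
100 MCS, not one cell diameter.  Consequently the frozen reference is a
near-perfect single-step predictor here, and a trained surrogate
(reconstruction fidelity Dice ≈ 0.992, field MSE ≈ 4e-4 at desk scale)
tracks it closely but does not overtake it.  The capacity and learning
properties (single-pair overfit to Dice > 0.99, monotone loss decrease,
equivariance) are asserted independently of this regime.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script, chosen
as this package's own study sizes: reference-baseline pilots run 3 full-size
simulations (256², 1000 cells, 2100 MCS); learning experiments use a 64²
lattice with 62 cells (the same site density), 4 training simulations over
MCS 200–1200 at 25-MCS cadence (144 pairs), horizon 100, a depth-2/8-channel
network, 50 epochs.  The full 256²/19,700-pair/100-epoch protocol is
available through the same interfaces.

## Known limitations

- 2D only; one motile cell type; no cell-connectivity constraint.
- Explicit Euler only for the field (no implicit/ADI path), so large `D`
  costs proportionally many substeps.
- The surrogate engine is CPU-bound numpy; the full-scale 100-epoch training
  protocol is impractical on one core (the architecture and loss are the
  point, not throughput).
- Timing comparisons (`benchmark`) are hardware-dependent and reported, never
  asserted.
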