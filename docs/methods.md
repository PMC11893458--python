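# Methods

## Model

The latent circuit model explains an N-dimensional population response
`y(t)` as an orthonormal embedding of an n-node recurrent circuit,

    y = Q x (+ b),    tau dx/dt = -x + [w_rec x + w_in u]_+,    z = w_out x,

with `Q^T Q = I_n`. The circuit receives the task inputs `u` (6 channels)
and produces the behavioral outputs `z` (2 channels). Node identity is
pinned structurally: input channel i drives node i only (`w_in` is
diagonal, nonnegative), and the last two nodes alone drive the outputs
(`w_out` nonnegative, one entry per output). This removes the permutation
symmetry of the latent nodes, so recurrent matrices of independent fits
can be compared entry-by-entry, which underlies the uniqueness and
clustering analyses. The intercept `b` is used only in the neural-data
mode, where recordings are centered.

Orthonormality is enforced exactly by the Cayley parameterization
`Q = (I + A)(I - A)^{-1} pi_n`, `A = B - B^T`, optimized over the
unconstrained square matrix `B`. `B`'s parameterization of `A` is
redundant (N(N-1)/2 degrees of freedom in N^2 entries); the redundancy is
harmless and left in place. The N(N-1)/2-dimensional tangent moves of `Q`
are obtained by an exact analytic chain rule through the Cayley map
(`cayley_embed_backward`), verified against finite differences in the test
suite.

Both the latent circuit and the RNN testbed follow the same discretized
dynamics (first-order Euler, `alpha = dt/tau`):

    y_t = (1 - alpha) y_{t-1} + alpha [W_rec y_{t-1} + W_in u_t
          + sqrt(2/alpha) sigma_rec xi_t]_+ .

Defaults: `tau` = 200 ms, `dt` = 40 ms (`alpha` = 0.2), `sigma_rec` = 0.15,
`sigma_in` = 0.01, all exposed in configuration.

## Task

Context-dependent decision making. Six inputs: two context cues, two
motion-evidence channels, two color-evidence channels. A trial lasts
3,000 ms (75 steps): context cue at 1.2 (cued) / 0.2 (other) during
320-1,000 ms; sensory evidence `(1 ± c)/2` per channel from 1,200 ms on,
with coherence c drawn from {±0.04, ±0.12, ±0.2} independently for motion
and color (72 conditions: 2 contexts x 6 x 6). A baseline 0.2 is added to
every channel at every step (also on top of the cue amplitudes; a config
flag can disable that). Targets are 0.2 on both outputs during the cue
epoch and 1.2/0.2 (by correct choice) from 2,250 ms; the loss mask covers
the cue epoch and the final 750 ms. The 3,000-ms trial end is a design
choice: it makes the target onset coincide with the start of the penalized
response window. Epoch boundaries snap to the nearest 40-ms grid step, so
the response window is 19 steps (760 ms).

## RNN training

50 units, 80% excitatory / 20% inhibitory. Excitatory recurrent weights
initialized |N(1/sqrt(N), 1/N)|, inhibitory |N(4/sqrt(N), 1/N)| with signs
applied, rescaled to spectral radius 1.5. `W_in`/`W_out` are initialized
|N(0, 1/N)| (their initialization is a free choice; any small nonnegative
scheme works). Adam (lr 0.01, betas 0.9/0.999), minibatch 128, 1,800
training trials sampled uniformly over the 72 conditions with frozen input
noise and fresh recurrent noise every pass. After every update, recurrent
weights violating their unit's sign are clipped to zero and `W_in`,
`W_out` are clamped nonnegative. An L2 penalty
`lambda_orth * ||off-diag(B_io^T B_io)||_F` on the column-normalized
concatenation `B_io = [W_in, W_out^T]` (weight 1.0) keeps the input and
output vectors nearly orthogonal; with nonnegativity this drives them
toward disjoint supports.

Loss normalization. The task error is averaged over penalized entries and
the rate penalty is `lambda_r * mean(y^2)` with `lambda_r = 0.05`. Two
alternatives were examined and rejected on behavioral grounds: weighting
the rate penalty by the penalized-entry count (the literal summed-loss
ratio) suppresses activity so strongly that the trained network's
psychometric function never develops context gating, and a torch-style
weight decay of 0.001 against the normalized loss (equivalent to a decay
orders of magnitude stronger than against a summed loss) prunes most input
weights and caps task performance near r^2 = 0.5. The trainer therefore
defaults to zero weight decay; on the normalized scale the equivalent of
the conventional 0.001-against-sums is ~1e-7.

Gradients are clipped to a global norm of 1.0; without clipping a
minority of seeds destabilizes late in training (the spectral radius
grows until the loss jumps by two orders of magnitude), while clipped
runs of the same seeds converge normally.

Training runs for a fixed epoch budget with early stopping (improvement
< 0.001 over 25 epochs). The plateau rule suits coarse runs; the
acceptance script and the test fixtures disable it and use the epoch
budget alone, because near convergence the per-epoch improvement falls
below the threshold long before task performance saturates. 600-700 epochs reach task r^2 ~ 0.92-0.97 and a
psychometric function that is steep in the relevant coherence and flat in
the irrelevant one. Choices are the sign of the output difference at the
final step; exact ties are broken by a seeded fair coin and flagged.

## Fitting latent circuits

Loss: mean squared error between `y` and `Q x` plus mean squared error
between `z` and `w_out x` (each term a per-element mean), minimized with
Adam (lr 0.02, weight decay 0.001, minibatch 128) over `(B, w_rec, w_in,
w_out)`. The latent trajectories are re-simulated every minibatch with
fresh recurrent noise of the same magnitude as the fitted network.
Initialization: `w_rec` uniform centered on zero with s.d. 1/n, `w_in` and
`w_out` zero except positive structural entries, `B` uniform on [0, 1].
Structural zeros and nonnegativity of `w_in`/`w_out` are re-imposed after
every update. Trials are split 50/50 within condition; all fits of an
ensemble share the split, and fits are ranked by held-out r^2 (pooled
1 - SSE/SST about the pooled mean, with the latent circuit simulated
noiselessly — the deterministic trajectory is the model's conditional-mean
prediction). An optional cosine learning-rate floor (`lr_min`) is
available; it matters when high-precision parameter recovery is required
(see below) and is used by the ensemble runs in the acceptance script.

Neural-data mode (`fit_neural`) fits `y = Qx + b` to condition-averaged
rates with the normalized three-term loss

    L = lambda * ||(y-b) - QQ^T(y-b)||^2 / ||y||^2
        + ||Q^T(y-b) - x||^2 / ||Q^T y||^2
        + ||z - w_out x||^2 / ||z||^2,

summed over conditions and observed timesteps (the behavioral term only
over the final 250 ms), with `lambda` (default 0.5) trading off subspace
variance against task performance; a grid-search helper over [0, 1.5]
replicates the selection logic. The subspace term is centered on `b` so
the intercept is identified in all directions; for centered recordings
(b ~ 0) this coincides with the uncentered form. The simulation grid is
150 steps of 10 ms (contextual input throughout, stimulus from 750 ms),
with responses observed on the last 15 steps.

## Identifiability and the recovery oracle

With noiseless data generated by an embedded ground-truth circuit, the
structural constraints make the generative parameters identifiable up to
optimization error *provided the inputs are persistently exciting*. Under
the behavioral task's tiny input noise (sigma_in = 0.01) the trajectories
are dominated by a few fixed-point approaches and near-equivalent
connectivity matrices fit them almost equally well: recovery correlation
plateaus around 0.86 no matter how long the optimizer runs. The recovery
tests therefore probe with sigma_in = 0.15, where best-of-ensemble
recovery reaches r > 0.95. This is a property of the data, not a tuning of
the test: system identification needs input excitation.

## What the testbed shows — and does not show

The trained networks reproduce the qualitative phenomena end to end: an
8-node circuit with inhibitory context-to-irrelevant-sensory connections
and excitatory sensory-to-choice connections is recovered from responses
alone; the conjugated connectivity `Q^T W_rec Q` matches it (r ~ 0.7-0.8);
weakening the inhibition via its rank-one image rotates the psychometric
boundary toward the irrelevant stimulus; stimulation along the latent
motion axis shifts choices while the decoder axis at matched magnitude
does not; and signed motion coherence decodes from stimulus-epoch
responses at r^2 ~ 0.50-0.54 with a < 0.05 train/test gap.

Quantitatively, the networks trained here sit at a somewhat lower
signal-to-noise point than the reference analysis: the recurrent noise
(sigma_rec = 0.15) accounts for ~6-7% of response variance, which caps the
fraction of variance any input-driven predictor can explain at ~0.93-0.94
and the leading-8-PC variance share at ~93-95%. Best-of-ensemble held-out
fit quality lands at r^2 ~ 0.77-0.86 accordingly. Networks with larger
activity (smaller noise share) would raise all three numbers together;
the hyperparameters that control that scale are not uniquely pinned down
by the published training recipe. The same applies to how completely a
network suppresses irrelevant stimuli: these networks gate almost
perfectly (irrelevant psychometric slope ~ 0), so the pooled decoder axis
carries relatively little irrelevant-stimulus variance, and the contrast
"suppressed along latent axes vs retained along the decoder axis" is
tested as an ordering rather than as a ratio-of-one.

## Synthetic populations

`generate_synthetic_population` emulates condition-averaged cortical
recordings: a planted suppression circuit is simulated over the 72
conditions, embedded through a random orthonormal map into N units scaled
to a chosen task-variance fraction (default 0.1, mimicking the low
task-relevant variance of prefrontal data), plus smooth task-irrelevant
latent dimensions and white observation noise. It exercises the same
container (`RatePopulation`) as the preprocessing path
(`preprocess_rates`: 50-ms binning, z-scoring, 40-ms Gaussian smoothing,
condition-independent mean removal, PCA to 50% cumulative variance,
two disjoint trial splits). What passing tests on these surrogates show is
that the fitting pipeline recovers planted structure under matched
assumptions; they do not establish robustness to real-data violations
(non-Poisson noise, session drift, unbalanced conditions beyond the
minimum-trial filter).

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
one primary network (700 training epochs) plus two replicates (600), a
12-init ensemble with the top 10 kept (400 fit epochs, cosine-annealed),
72 x 8 trials for fitting and 72 x 25 for decoding. The across-network
variance-ratio analysis, which the reference runs over 200 networks, is
exercised here over 3 networks with small ensembles and asserted only as
"across-network variability exceeds within-network variability".
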