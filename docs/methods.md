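# Methods

This note records the model underlying `eeggraph`, the choices made where
the design was genuinely open, and what the synthetic tests do and do not
establish.

## Analysis model

**Connectivity.** Functional connectivity between two electrodes is the
Pearson correlation of their band-limited signals within a 20-s epoch.
Correlation captures zero-lag linear coupling only; phase-lagged or
nonlinear dependence (coherence, phase-locking) is out of scope.

**Sparsity thresholding.** Comparing graph measures across subjects is
confounded by edge count, so all networks are reduced to the same density:
the top `round(density · N(N−1)/2)` edges by |r| are kept. Negative
correlations enter by magnitude — with 8 electrodes referenced to linked
ears, strong negative zero-lag correlations are as much "connectivity" as
positive ones, and the metric formulas require nonnegative weights. Ties
at the cutoff are broken by lexicographic edge index, which makes the
edge set deterministic and nested across densities. The default density
is 0.3 (8 of 28 edges): mid-range, usually keeps an 8-node network in one
or two components. Because the appropriate threshold is genuinely
unknown, analyses of real data should sweep densities (0.1–0.5) rather
than trust any single value.

**Graph measures.** Seven measures are computed in binary or weighted
mode (default weighted):

| measure | convention |
|---|---|
| global efficiency | mean 1/L over ordered pairs; 1/∞ = 0 |
| local efficiency | neighborhood subgraph excludes the center node; degree < 2 scores 0 |
| clustering | binary pattern a_ij even in weighted mode (the formula is written with a_ij); degree < 2 scores 0 |
| characteristic path | reachable pairs only; unreachable-pair count recorded; isolated node scores 0 |
| strength | row sum of the weighted (or binary) adjacency |
| betweenness | unordered pairs, endpoints excluded, unnormalized |
| assortativity | endpoint degrees (binary) or strengths (weighted); NaN for regular graphs |

Weighted path length is 1/w: a stronger correlation is a shorter
functional distance. Equal-length weighted paths are merged with a
relative tolerance of 1e-12 when counting shortest paths.

The clustering/strength asymmetry (binary pattern vs weights) is
deliberate and documented: clustering as written is a topological count,
strength is a weight sum.

**Features.** Per subject and state, the per-node values of the seven
measures over 9 epochs are concatenated (metric-major within epoch) into
a 7 × 8 × 9 = 504 vector. Three measures are network-level; their slots
hold nodal stand-ins (nodal efficiency, nodal mean distance) and
assortativity broadcast to all nodes, so every slot is well defined and
the printed feature count is preserved. A network-scalar-broadcast
alternative sits behind `nodal=False`. NaN assortativity (degree-regular
epoch networks) is imputed as 0 with a warning.

**Statistics.** Group comparisons use the two-sided Wilcoxon rank-sum
test on network-level scalars averaged over epochs within subject —
subjects, not epochs, are the exchangeable units. Exact null
distribution for tie-free samples with min(n) ≤ 8, otherwise the normal
approximation with tie correction. No multiplicity correction by default
(seven tests per state are reported as-is); Benjamini–Hochberg is
available via `fdr=True`.

**Classification.** Stratified 10-fold cross-validation with min–max
normalization fitted inside each training fold. Instances are subjects by
default (40 vectors of 504 features per state); an epochs-as-instances
mode exists but inflates accuracy whenever epochs of one subject land in
both training and test folds. The positive class is the elderly group.
KNN is implemented in-package because its tie rules are pinned down
(distance ties by training order, vote ties toward the positive class);
the SVM uses the Pearson VII universal kernel

K(x, y) = 1 / [1 + (2·√(2^(1/ω)−1)·‖x−y‖ / σ)²]^ω,  ω = σ = 1,

through a precomputed Gram matrix (RBF fallback available); the random
forest uses 100 trees with √p feature subsampling. AUC is computed from
pooled out-of-fold scores: vote fractions (KNN), decision values (SVM),
tree-vote fractions (RF).

## Synthetic cohort

The generator emulates a 20 + 20 cohort, 8 channels at 250 Hz, 5-minute
resting recordings and a 2-minute WM recording, three states. Each
channel is an independent band-limited source (one alpha- and one
beta-band sinusoid at random frequency/phase plus 0.5–45 Hz filtered
noise, unit variance), mixed through a symmetric coupling matrix, with
additive sensor noise (SD 0.5).

The coupling matrix is `c · P + η`:

- `c` — group coupling: 0.6 (middle-aged-like) minus 0.3
  (elderly-like reduction), jittered per subject (SD 0.05) so group
  distributions overlap;
- `P` — a modular profile: 1 within the anterior (FP1, FP2, C3, C4) and
  posterior (P7, P8, O1, O2) halves, 0.3 between them;
- `η` — symmetric edge noise with fixed SD 0.2, redrawn every 20 s
  (dynamic connectivity fluctuation).

Because the SD of `η` does not scale with `c`, the anatomical structure
of the weaker-coupled elderly-like group sits closer to the noise floor:
its fixed-density thresholded topology is more random, which lowers the
binary clustering coefficient and local efficiency — networks become
more random with age, rather than merely weaker. Weight-driven measures
(strength, weighted efficiency) are lowered directly by the smaller `c`.

Determinism: each (subject, group, state) gets a child seed from a
SHA-256 hash of the master seed and identity tokens, so regeneration is
bit-identical and independent of iteration order.

What the generator does **not** model, and therefore what green tests do
not establish:

- no stable per-subject connectivity fingerprint — edge noise is purely
  dynamic, so epoch-level cross-validation shows no subject-identity
  leakage here, whereas on real EEG it would;
- no 1/f spectral shape, eye-blink/EMG artifacts, or task-evoked
  dynamics (the WM state differs only in duration);
- no frequency-band-specific group effects.

Green pipeline tests establish that the implementation recovers a planted
correlation-strength/topology difference; they say nothing about whether
real aging produces such differences.

## Numerical choices

- Filters are zero-phase (forward-backward `sosfiltfilt`); the band-pass
  is a 4th-order Butterworth — a 2nd-order design leaves ~17% of a 60 Hz
  tone, too leaky next to the notch band. The first and last 2 s of each
  filtered recording are excluded from epoching (settling).
- Epoching tiles contiguously from the start when the recording is long
  enough; otherwise onsets are spaced uniformly by (T − L)/(n − 1)
  (the 2-min WM recording needs overlap to yield 9 epochs).
- ICA artifact removal is intentionally absent: synthetic input is
  artifact-free. Clean real recordings before `preprocess`.
- Zero-variance channels raise an error naming the channel rather than
  silently producing NaN correlations.
- Densities are realized to the nearest whole edge; a density that
  rounds to zero edges raises.

## Known limitations

- With N = 8 the graphs are tiny; metric distributions are coarse and
  assortativity is frequently NaN at low density (degree-regular
  subgraphs), which is imputed as 0 in feature vectors.
- The epochs-as-instances classification mode should not be used for
  inference on real data without subject-grouped folds.
- Correlation-based connectivity inherits volume-conduction ambiguity;
  nothing here disentangles genuine coupling from common sources.
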