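# Methods

## The chaotic system

The keystream generator is a 3D logistic map coupled through cross-product
terms:

    x' = r_x x (1 − x) + β y z
    y' = r_y y (1 − y) + γ x z
    z' = r_z z (1 − z) + α x y

Defaults: r_x = 3.99, r_y = 3.98, r_z = 3.97 (inside the chaotic window
(3.57, 4] of the logistic family and distinct so the three components do not
synchronize), α = β = γ = 0.01 (couplings small enough that each component
stays chaotic while still entangling the three states), burn-in 1000 steps
(discards the transient; independence from initial-condition artifacts was
checked with the Lyapunov diagnostics below). The coupling terms can push a
state slightly above 1, so each raw update is wrapped by its fractional part
and clamped into [1e-6, 1 − 1e-6]; inside (0, 1) this is the identity, so the
uncoupled map is reproduced exactly, and the clamp keeps the system away from
the absorbing fixed point at 0.

`ChaoticParams` accepts any growth rate in (0, 4] so that periodic regimes
(e.g. r = 3.2) can be studied with the Lyapunov estimator; the cipher should
only be operated in the chaotic window, where the defaults live.

Chaoticity diagnostic: the largest Lyapunov exponent along X is estimated as
the orbit average of ln |r_x (1 − 2x)| — the log-derivative of the uncoupled
update (the coupling term is constant in x). For the uncoupled map at r = 4
the exact value is ln 2 ≈ 0.6931, which the estimator reproduces to < 0.01 at
n = 10⁵; at the package defaults the estimate is strictly positive. A
literature value of 0.89 for a map of this family is treated as qualitative
(λ > 0) because it depends on unspecified coupling constants.

## Key schedule

The 64-hex-character key is decoded to its 32 raw bytes (making the key
case-insensitive and canonical) and hashed with SHA-256; the image is hashed
over its row-major channel-interleaved bytes. Seeds are the first, second and
fourth 64-bit words of SHA-256(H_K ‖ H_I), scaled by 2⁻⁶⁴ and clamped into
[1e-6, 1 − 1e-6]. Including H_I binds the keystream to the plaintext, which
is what makes one-pixel NPCR ≈ 99.6 % possible; decryption is unaffected
because the cipher record persists the derived key material rather than the
seeds.

One orbit of length W + H·W·D serves all consumers from disjoint segments:
X[0:W] → column permutation A (stable argsort, ties broken by position),
Y[0:H] → row permutation B, Z[0:D] → rotation counts C = min(⌊4z⌋, 3), and
X[W:W+HWD] → the key cube K = min(⌊256x⌋, 255) filled row-major. Disjoint
segments keep the permutation indices statistically independent of the key
bytes even though both nominally derive from X.

## Cipher structure and the 2D reduction

Per channel: expand to an H×W×D cube (all layers copies of the channel),
permute columns by A then rows by B, rotate layer k by C[k] counterclockwise
quarter-turns, XOR with K, keep layer 0. Since no step mixes depth layers,
the composition equals a 2D permute/rotate/XOR with C[0] and K[:, :, 0]; the
2D reduction is the default engine and the full-cube path is kept as a
verification oracle (the test suite asserts byte-identical ciphertexts and
records across 100 randomized instances). Rotation orientation is
counterclockwise by convention; decryption applies (4 − C[0]) mod 4 turns.
Any fixed orientation is self-consistent.

Depth policy: D = H for square images up to 256 (so the canonical 128×128
input uses a 128³ cube), D = 1 otherwise — deeper layers never reach the
output under the layer-0 collapse. Non-square layers cannot be
quarter-turned in place, so rotation is restricted to 180° (counts mod 2) and
flagged in the record. Grayscale inputs are expanded to three identical
channels internally and flagged; since the three cipher channels are then
byte-identical, the stored ciphertext keeps the single-channel shape.

The `.c3dk` record (magic `C3DK`, version, flags, channels, dimensions, A, B,
C, the key plane, SHA-256 checksum, all little-endian) stores explicit key
bytes so decryption never depends on floating-point reproducibility. The full
C vector (D bytes) is stored even though only C[0] affects the output.

## Security statistics

All Table-style texture statistics (entropy, GLCM contrast/energy/
homogeneity, SSIM, MSE, structural content, adjacent-pixel correlation) are
computed on the BT.601 luma (0.299 R + 0.587 G + 0.114 B, rounded half-up).
GLCM uses a non-symmetric horizontal offset (0, 1) with 256 levels,
normalized by pair count. SSIM is the global single-window form with the
standard 8-bit stabilizers C1 = (0.01·255)², C2 = (0.03·255)². Structural
content follows the nonstandard printed form Σorig² / Σ(orig − enc)², with
the classical Σorig² / Σenc² behind `classical=True`. Adjacent correlation
uses *all* pixel pairs in the chosen direction rather than a random sample —
reproducibility over convention. NPCR and UACI pool all channels.

The chi-square histogram-uniformity test in `evaluate` runs on the pooled raw
channel bytes rather than the luma: with a keystream shared across channels,
each channel's byte histogram can be uniform while the luma of the (R, G, B)
triple — a weighted sum of strongly dependent values — cannot be.

Key-space reporting uses exact big integers (2²⁵⁶ ≈ 1.16×10⁷⁷ at three
significant figures) and a 365-day year for brute-force time.

### What a floor-quantized chaotic keystream can and cannot achieve

Two statistics deserve an honest caveat, both rooted in the same fact: the
invariant density of a logistic orbit is arcsine-like (peaked near 0 and 1),
so the key bytes K = ⌊256x⌋ are *not* uniform (key-plane byte entropy ≈ 7.81
bits; the most common byte appears ~6× more often than under uniformity).
XORing a plaintext with such a keystream yields ciphertext bytes whose
distribution is the XOR-convolution of the plain histogram with the key
distribution:

* **UACI.** For narrow-histogram natural images (the synthetic fixtures have
  grayscale entropy 6.6–6.8, matching field photographs) the one-pixel
  avalanche UACI settles near 31.3 % rather than the 33.46 % independent-
  uniform ideal. A control with a uniform plaintext recovers 33.4 %, showing
  the diffusion layer itself is unbiased — the shortfall is a property of the
  key-byte distribution, not of the implementation. NPCR is insensitive to
  this (it only counts inequality) and sits at 99.60 % as theory predicts.
* **Histogram uniformity.** For structured plaintexts the ciphertext byte
  histogram is detectably non-uniform at 128×128 sample sizes: the chi-square
  test rejects at α = 0.001 in essentially every keyed run. The same control
  (uniform plaintext → non-rejection) isolates the cause. Reported ciphertext
  entropies near 7.62–7.74 bits (rather than ~7.999) are the entropy-scale
  signature of the same effect.

Relatedly, the *grayscale* entropy of an RGB ciphertext whose three channels
share one key plane cannot approach 8 bits: the luma of (R⊕k, G⊕k, B⊕k) is a
weighted sum of strongly dependent bytes and concentrates. Measured values on
the fixtures are 7.70–7.78 bits; per-channel byte entropy is ≥ 7.9. Tests
assert those attainable properties.

A keystream post-processing step (e.g. rank-normalizing the orbit or hashing
orbit values) would make the key bytes uniform and recover the ideals, but
would change the cipher's defining construction, so it is deliberately not
applied.

## Synthetic plant fixtures

The generator emulates crop photographs at the image-statistics level only:
a green-dominant base color, one shared smooth luminance field plus smaller
per-channel fields (Gaussian-filtered white noise, σ = 8 px), zero or more
soft-edged rotated elliptical "lesions" with a brownish intensity shift
(default peak −60 levels, hitting the green channel hardest), and mild
Gaussian speckle (σ = 2 levels). Defaults produce 128×128 RGB images with
horizontal adjacent-pixel correlation ≈ 0.99 and grayscale entropy 6.6–6.8 —
inside the 5–7 bits typical of real field photographs. The fixtures do *not*
reproduce photographic features such as specular highlights, depth-of-field
blur, sensor noise correlations, or genuine disease morphology; passing tests
demonstrate the cipher's behavior on natural-image *statistics*, not
diagnostic realism. The eight-image suite (four lesion-free, four lesioned)
regenerates bit-identically from its seed.

## Training-loss reference functions

The losses module contains pure forward functions (no gradients or training
loop): temperature-softened softmax and natural-log KL divergence, the
T²-scaled distillation loss (T = 4 by default; T² offsets the 1/T² gradient
scaling of the softening), Focal Loss −α(1 − p_t)^γ ln p_t with α = 0.25,
γ = 2 (batch form: arithmetic mean), IoU and CIoU in center-size box
convention (CIoU adds the normalized center-distance penalty ρ²/c² and the
aspect-ratio term αv, with α = v/((1 − IoU) + v) and α = 0 taken at the
IoU = 1, v = 0 degeneracy), detection loss = focal + CIoU, total loss =
(1 − α)·detection + α·distillation with α = 0.7, the piecewise-linear
OneCycleLR ramp, and patience-based early stopping (default 10). The label
convention is y = 1 ⇒ p_t = p.

## Problem sizes and numerical choices

The acceptance script uses 20 avalanche trials on 128×128 RGB fixtures
(≈ 49k pooled byte comparisons per trial; binomial σ of the 20-trial mean
NPCR ≈ 0.03 percentage points) and a 16 384-pixel entropy sample — sizes at
which the statistics above are stable to well within their tolerances. Orbit
generation is a sequential recurrence implemented in a numba-compiled kernel
(pure-Python fallback), so a 128×128 encryption (~2.1M iterations) costs
milliseconds. Stable sorts break argsort ties by position; byte quantization
clamps ⌊256x⌋ to 255 and ⌊4z⌋ to 3 at the (unreachable after clamping)
endpoint x = 1. Degenerate metric inputs raise explicit undefined-result
errors rather than returning NaN; `evaluate` maps them to JSON nulls.

## Known limitations

* Integrity is a checksum, not an authentication tag: the record detects
  corruption, not forgery.
* The cipher is a research construction; no claims are made against chosen-
  plaintext adversaries who control many (plaintext, ciphertext) pairs.
* UACI and histogram uniformity fall short of their independent-uniform
  ideals for narrow-histogram plaintexts, as quantified above.
* Only 8-bit grayscale/RGB rasters in lossless containers are supported by
  design; lossy output is refused rather than warned about.
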