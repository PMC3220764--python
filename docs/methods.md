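# Methods

## Conventions

All angles are degrees at every public boundary. Orientations are ZYZ
Euler triplets (φ, θ, ψ) with matrix M = Rz(φ)·Ry(θ)·Rz(ψ), Rz rotating x
toward y and Ry rotating z toward x; θ is canonical in [0, 180], φ and ψ
in [0, 360). At gimbal lock (θ = 0 or 180) the degenerate pair is resolved
by ψ = 0, so Euler extraction is deterministic; the round trip
euler → matrix → euler → matrix reproduces the matrix to 1e−9 even at the
lock (verified by property test). Matrices are validated orthonormal with
det +1 to 1e−10 absolute. The beam runs along +z; the specimen plane is
xy. The tilt *direction* (azimuth) reported everywhere is perpendicular to
the rotation axis — the direction the goniometer arrow points on a plot —
so an axis at azimuth a corresponds to a tilt direction a + 90°.

Symmetry operators act on the map frame, i.e. on the left of M: M and s·M
produce identical projections when s leaves the map invariant. Lab-frame
operations (goniometer and beam-induced tilts, in-plane camera rotations)
act on the right: a specimen tilt T takes the untilted orientation Mu to
Mu·Tᵀ. These two sides are what make the relating rotation

    S = Mtᵀ · s · Mu

recover T exactly once s compensates the (left) assignment degeneracy of
the two views: only the product of the two unknown operators matters, so a
single group sweep suffices.

## Operator and candidate selection

For each symmetry operator (and each untilted × tilted candidate pair when
multiple refinement runs are supplied), S is decomposed via its rotation
vector into axis **n** and angle τ. Selection minimizes the *in-plane
misfit*: the geodesic distance from S to the nearest rotation about an
in-plane axis, which has the closed form 2·arcsin(sin(τ/2)·|n_z|). This is
the quantity a constrained search over in-plane tilt hypotheses minimizes,
and the brute-force grid oracle in the tests confirms the equivalence
(the azimuth of the constrained optimum equals the azimuth of the in-plane
component of **n** exactly; the constrained optimal angle is
2·atan(tan(τ/2)·cos(oop))). Selecting instead by the bare axis inclination
|arcsin(n_z)| fails for high-order groups: a wrong operator's ~72–180°
relating rotation has a near-in-plane axis with probability ≈ sin(oop) per
operator, so with 60 icosahedral operators most particles would lock onto
a wrong branch even at 0.5° noise. The misfit criterion suppresses this by
the factor sin(τ/2) ≈ 1 for large wrong rotations; both criteria coincide
for C1 and in the noiseless limit.

The *reported* out-of-plane error remains |arcsin(n_z)| — the inclination
of the recovered axis to the specimen plane — because that is the
physically interpretable residual and the basis of the outlier rule:
particles with out-of-plane error above `factor` (default 1.5) times the
arithmetic mean over the full dataset, computed once and not re-iterated,
are flagged. Ties in selection break toward the smaller tilt angle, then
the lower operator index; a relating angle below 1e−9° is treated as the
identity and reported with azimuth 0 (and excluded from azimuthal
statistics by virtue of radius 0).

Known limitation: dihedral and icosahedral groups admit a second genuine
solution branch — a twofold about a nearly in-plane axis composes with the
true tilt into a ~180° rotation that is also about an in-plane axis. Such
picks are correct under the symmetry-constrained objective but land at
radius ≳ 50° on the plot; they are invisible inside the standard 30°/50°
plot radii and do not contaminate clustering statistics.

## Plot-plane geometry

All clustering statistics (circle fractions, the smallest radius enclosing
a target fraction, cluster centers and spreads) are computed with
Euclidean geometry in the 2-D plot plane, embedding a point as
(τ·cos α, τ·sin α). This matches how the circles are actually drawn on a
TPPP and is a tangent-plane approximation valid for the ≤ 50° radii in
use. One consequence worth knowing: the plot radius is the *full* rotation
angle of S, whose out-of-plane noise component inflates it by roughly
E[n_z²]/(2τ); when the per-image noise σ approaches the tilt angle τ the
cluster center sits visibly outside the true radius (≈ +1.3° at σ = 5°,
τ = 5°). The recovery tests account for this by comparing at the
standard-error scale of the plotted points.

`summarize` honors an explicit circle radius; otherwise it takes the
distance order statistic enclosing the target fraction (default 0.5, the
40–60% design band). The in-plane percentage uses the same angular
tolerance as the circle, as tilt-pair statistics tables do. The center and
spread reported by `summarize` are derived from the points *inside* the
circle — the cluster, not the raw mean — since a single surviving
misassignment at 150° radius would otherwise dominate both; the standalone
`cluster_center_and_spread` keeps plain all-points semantics. The mean
angular error is the mean distance to the fitted cluster center, not to
the nominal goniometer value: beam-induced motion makes nominal ≠ actual,
and conflating the two would fold a systematic shift into a precision
estimate (the CLI reports both center and nominal).

## B-factor translation

Averaging the mean-square displacement r²Δθ² of a rotational blur over a
uniform sphere of radius R = D/2 gives a Gaussian of full width X with
X² = (3/20)·D²·Δθ² (Δθ in radians); its transform decays as
exp(−π²X²/4d²), i.e. B = π²X². In degree form the constant
1/(π²·(3/20)·(π/180)²) = 2217.5 rounds to the working 2200; both forms are
exposed (`exact=True`) and agree within 1%. The numerical Fourier-pair
test transforms exp(−4x²/X²) on a fine grid and recovers B = π²X² to
0.5%. Amplitude attenuation is exp(−B/4d²). The qualitative
high (3–5 Å) / medium (6–10 Å) / low (below 12 Å) band labels interpolate
log-resolution against log-B through three published (B, resolution)
anchors — (240, 3.3), (750, 7.0), (1000, 8.7) — with band edges at 5.5 and
11 Å, in the gaps between the stated ranges; the anchors are an empirical
trend, not a law, and the thresholds are configuration.

## The synthetic generator

`simulate` draws, per micrograph pair, a nominal goniometer tilt composed
with a coherent beam-induced perturbation: an extra tilt about a random
in-plane axis, magnitude uniform in [0, beam_tilt_max] (ice films tilt by
up to ~2° under a typical 20 e/Å² exposure, with no preferred direction).
Per particle: a Haar-uniform untilted orientation (normalized Gaussian
quaternions); the tilted truth applies the pair's effective tilt in the
lab frame. Observed orientations compose the truth with an isotropic
rotation-vector Gaussian scaled so the RMS *total* rotation angle is
exactly σ — the field reports per-structure error magnitudes, not shapes,
so an isotropic Gaussian is the minimal choice. Each of the K candidates
per view emulates one independent refinement run: independently noisy,
and, on the tilted view only, replaced by a Haar-random misassignment with
probability p per candidate (the second exposure is the more
radiation-damaged and fails more often; applying p to one view also makes
the outlier fraction track p directly). All observations are reduced to a
deterministic fundamental-domain representative (lexicographically
smallest s·M), so downstream code must genuinely resolve the degeneracy.
Everything is reproducible bit-for-bit from the seed.

Two optional distortions: `domain_split_angle` composes the tilted truth,
for a random half of the particles, with an extra map-frame rotation of
fixed magnitude before noise — the "orientation locks onto a different
domain in the second image" behavior of flexible particles, which broadens
the TPPP monotonically in the split angle; `bend_gradient` adds an extra
tilt varying linearly with the particle's position across the field of
view, the tilt-and-bend signature seen when ice deforms non-rigidly.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: heavy-tailed orientation-error
distributions (real mean-error/success-fraction pairs are not jointly
reachable with a Gaussian; the tests assert the Gaussian closed forms),
defocus- and view-dependent accuracy, correlated errors between the two
exposures (radiation damage degrades the second image, so real relative
scatter can exceed √2·σ of the *first* image), CTF and magnification
errors, and any actual image formation.

## Problem sizes and numerical choices

Group generation saturates the generator set (fivefold about (0,1,t) or
(1,0,t), t the golden ratio, plus a twofold about z for the icosahedra),
re-projecting every product onto SO(3) by SVD and deduplicating at 1e−8;
orders are asserted (n, 2n, 60). Rotation angles are extracted through
quaternions (accurate near 0°, where arccos of a trace loses half the
digits). The test suite uses 10⁴ particles for the √2 scatter law (ratio
within 5%), 200 cases each for noiseless recovery (< 1e−6°) and the grid
oracle, 100 particles per cell of the 4 tilts × 3 noise levels × 4 groups
recovery grid (centers within 3 standard errors of the plotted points),
and 300 particles for the misassignment and multi-run comparisons; the
full suite runs in about a minute on one CPU, and `scripts/acceptance.py`
rebuilds its numbers in ~20 s.
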