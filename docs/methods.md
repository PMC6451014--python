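# Methods

## Substitution model

Distances are estimated under the Dayhoff empirical model: a reversible
continuous-time Markov chain on the 20 amino acids with rate matrix
Q_ab = s·S_ab·π_b (a ≠ b), built from the classic Dayhoff (1978)
exchangeabilities S and stationary frequencies π shipped as a plain-text
constant table in the PAML `.dat` layout (amino-acid order
ARNDCQEGHILKMFPSTWYV) and guarded by a checksum. The scale s is fixed so
that the mean rate −Σ_a π_a Q_aa equals 1, which puts every divergence t
in expected substitutions per site — the unit implied by "changes per
residue" scale bars. "PAM250" is the high-divergence point of this same
process; rather than reading similarities off a fixed score matrix, the
divergence of each pair is estimated by maximum likelihood, which is what
protdist's Dayhoff mode does and is the only realization that yields
distances on a per-site substitution scale suitable for metric embedding.
A Poisson-corrected estimator (−ln(1−p), equal rates across residues) and
the raw p-distance are provided as cheaper alternatives; the choice is a
flag.

P(t) = exp(Qt) is computed from the eigendecomposition of the
π-symmetrized rate matrix D^{1/2}QD^{-1/2} — exact for reversible Q and
stable at any t, unlike series expansions. Tiny negative entries from
round-off are clamped and rows renormalized.

## Pairwise ML distances

For an aligned pair, columns where either sequence has a gap or `X` are
excluded (pairwise deletion, protdist's behavior; complete deletion is
available). `X` is treated as missing rather than as a 21st state to
avoid biasing p downward. The log-likelihood ℓ(t) = Σ_ab C_ab ln(π_a
P_ab(t)), with C the 20×20 substitution-count matrix, is maximized over
t ∈ [0, 10] by bounded scalar minimization (absolute tolerance 1e-6 on
t); both interval ends are then checked explicitly, so identical pairs
return exactly 0 and saturated pairs exactly the cap. ℓ is smooth and in
practice unimodal; the test suite guards this with a brute-force grid
search oracle (step 1e-3 over the whole interval). C is canonicalized
against its transpose before optimization — reversibility makes ℓ
direction-symmetric, and the canonicalization pins down floating-point
rounding so the distance matrix is exactly invariant under taxon and
column permutations.

Saturation policy: distances are capped at d_max = 10 substitutions per
site and the pair is flagged, never dropped, so the embedding always
receives a complete matrix. Matrices read from disk are symmetrized by
averaging when the asymmetry is ≤ 1e-6 and rejected otherwise.

## Neighbor-joining

Classic Saitou–Nei agglomeration on Q(i,j) = (n−2)d_ij − r_i − r_j, with
two determinism rules: ties in Q are broken by the lexicographically
smallest pair of subtree keys (a subtree's key is its smallest leaf
label), and negative branch-length estimates are clamped to zero with the
deficit moved to the sibling branch so path lengths are preserved where
possible. On additive matrices neither rule ever fires and NJ returns the
generating tree exactly (topology and branch lengths), which the suite
checks on random trees up to 12 leaves. NJ is the built-in distance-based
companion; externally inferred ML trees enter via Newick, where numeric
internal labels in [0,1] or [0,100] are read as branch supports.

## Sammon mapping

Stress E = [1/Σd*]·Σ (d*−d)²/d* over unordered pairs. Minimization uses
Sammon's diagonal second-order update x ← x − α·(∂E/∂x)/|∂²E/∂x²| with
α = 0.3 (Sammon's recommended step factor) and step halving — up to 20
halvings per iteration — so the recorded stress trace is non-increasing
by construction. Convergence: relative stress change < 1e-9 or 500
iterations. The first start is the classical Torgerson MDS solution
(faster and more stable than a random start, and exact whenever the
matrix is Euclidean and embeddable in k dimensions); the remaining
restarts (default 10) are seeded Gaussian configurations, and the best
final stress wins. Everything is reproducible bit-for-bit from the seed.

Duplicate taxa (zero original distance) would make the 1/d* weight
singular; they are merged into one optimization point and re-attached at
the representative's coordinates afterward. A matrix with all equal
distances is valid input and relaxes toward a regular simplex, with
residual stress when k is too small to hold it.

## Tree overlay and diagnostics

Leaf coordinates are never moved by the overlay — the scene is the
embedding plus links. Internal vertices are placed either at the
unweighted centroid of their descendant leaves (default: deterministic,
parameter-free, commutes with rigid motions) or by a joint Sammon descent
on an augmented matrix (leaf–leaf entries from the original distances,
pairs involving internal nodes from patristic path lengths) with the
leaves frozen; the figures this emulates do not state how internal
vertices were placed, hence both modes.

Group spread is the RMS of pairwise embedded distances within a group;
the relative spread divides by the global RMS over all pairs and is
therefore invariant to rigid motion and global rescaling. It quantifies
dispersion ("compact" vs "widely spread"), deliberately not separation
between groups, for which no statistic is defined here. Singleton groups
are reported with undefined spread rather than dropped.

Procrustes superposition fits translation and rotation (reflection
optional) but not scale: Sammon coordinates approximate substitutions per
site, so scale is information, not nuisance.

## Simulator

Sequences evolve site-independently: the root is drawn from π, each
branch applies one categorical draw per site from P(t·m) where m is the
branch's rate multiplier (clade-wise multipliers emulate lineages with a
much higher mutational rate). Branch streams are keyed by a hash of the
branch's descendant leaf set, so editing one subtree never perturbs the
draws in another. No indels are generated: the intended inputs are
curated, essentially gapless domain alignments, and gap handling is
exercised by hand-written fixtures.

The two-group scenario defaults — 8 taxa per clade, 250-site alignment,
slow-clade root-to-leaf depth 0.5 substitutions/site, rate ratio 5 — are
domain-scale values comparable to the folate-enzyme families that
motivate the representation (alignments of a few hundred residues, a few
dozen taxa, deep divergences). What passing the end-to-end contrast shows
is that the pipeline turns a genuine rate contrast into a spread contrast
in the map; it does not show robustness to alignment error, indels,
among-site rate variation or model misspecification, none of which the
generator produces.

## Numerical and scale choices

- Embedded distances below 1e-12 are floored during descent to avoid
  division blow-ups at transiently coincident points.
- The ergodic check compares P(50) against a repeated-squaring oracle at
  1e-8; strict 1e-6 agreement with π is asserted at t = 80, since the
  Dayhoff spectral gap (~0.23) leaves a ~7e-6 residual at t = 50.
- Test and acceptance problem sizes (5,000-site pairs, 20 replicates per
  divergence; 50 random trees; 50 end-to-end spread replicates at 16
  taxa × 250 sites) are chosen so each property is measured with
  comfortable statistical margin while the whole suite runs in well under
  a minute per component.
- The `run` manifest's config digest excludes the output directory, so
  runs into different directories produce byte-identical scientific
  outputs.

## Known limitations

Only the Dayhoff family is shipped (no JTT/WAG/LG, no gamma or invariant
sites — externally inferred trees carry that sophistication in via
Newick). B/Z/J/U/O ambiguity codes are rejected at parse time rather than
translated. NJ negative-branch clamping is a display convention, not an
inference statement. The joint overlay inherits Sammon's local-minimum
sensitivity for the internal vertices; the leaves are unaffected.
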