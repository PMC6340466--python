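# Methods

This note documents the models behind each stage, the defaults and why, what
the simulator does and does not emulate, and the numerical choices a user
should know before trusting (or extending) the results.

## Codon substitution model and likelihood engine

ω estimation uses a GY-class codon model on the 61 sense codons of the
standard nuclear genetic code. Off-diagonal rates for single-nucleotide
changes are

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous],

zero for multi-nucleotide changes, with the generator scaled so one unit of
branch length equals one expected substitution per codon site under that
branch's own ω (the convention of mainstream codon-model software, so branch
lengths are comparable across fits). The model is time-reversible, so P(t)
is computed by symmetric eigendecomposition of π^½ Q π^−½ — exact, cheap,
and reused across branches.

Likelihoods come from Felsenstein pruning over compressed site patterns with
per-node rescaling against underflow. Codons containing gaps or ambiguous
bases are missing data (partial likelihood 1 over all states); a stop codon
in data passed to the engine is an error — disrupted columns must be removed
first (see alignment pre-processing).

**Models.** M0 (one ω); two-ratio (foreground/background by branch tag);
free-ratio (one ω per branch — small trees only, the parameter count grows
linearly); an arbitrary branch-label model (used for the four loss-era
categories in dating); and the site mixtures M1a (ω₀<1, ω=1), M2a (adds
ω₂≥1), M7 (beta-distributed ω), M8 (beta plus a ω_s≥1 class). The beta is
discretized into K equal-probability bins represented by their medians
(default K=10). Nested pairs are compared by 2Δ = 2(lnL₁ − lnL₂) against the
χ² upper tail (df: M0 vs two-ratio 1; M1a/M2a and M7/M8 2).

**Parameter counts** include branch lengths when they are optimized and
exclude them when fixed; only like-for-like fits should enter an LRT.

**Frequencies.** Default F1x4 estimated from the data (uniform and F3x4
selectable). The choice is not critical for the recovery experiments here
but is exposed because real opsin alignments are compositionally skewed.

**Optimization.** Bounded L-BFGS-B on (κ, ω's, mixture parameters, branch
lengths), multi-start (default 3 jittered restarts; the heavy replicate
experiments use 1, which pilot runs showed sufficient at these data sizes).
Bounds: κ ∈ [0.2, 50], ω ∈ [10⁻⁴, 20], ω_s ∈ [1, 50], beta p,q ∈
[0.005, 99], branch lengths ∈ [10⁻⁶, 30]; lnL convergence tolerance 1e-10
(ftol). A fit that never reports convergence is returned flagged, never
silently. Branch lengths are either re-optimized per model or estimated once
under M0 and fixed for subsequent labeled/site fits — the latter is the
default in the replicate experiments, mirroring common practice and cutting
cost by an order of magnitude.

**Counting estimator.** NG86-style: per-position synonymous site fractions
(changes to stops excluded from the denominator, so every codon contributes
exactly 3 sites), pathway-averaged differences for multi-hit codons
(pathways through stops excluded; if all paths hit a stop they are used
anyway rather than dropping the pair), Jukes–Cantor correction. dS = 0 or
saturation (p ≥ 3/4) yields a null ω with the reason recorded. The counting
route is the ML-free cross-check: on low-divergence pairs the two agree
within ±0.1.

**Naive per-site class posteriors** for the mixture models are conditional
probabilities at the MLEs. This is deliberately *not* Bayes empirical Bayes
(no prior integration over parameter uncertainty); it is labeled as such and
should not be used for site-level positive-selection claims.

## ORF integrity

A taxon is a pseudogene iff it carries a frameshift indel or a premature
stop. Indel polarity is defined against a reference row (default: the first
sequence whose translation is internally stop-free). Gap runs in the taxon
opposite reference bases are deletions; bases opposite reference gaps are
insertions; adjacent runs are never merged (each run is one lesion — the
conservative, per-event convention). Stops are called on the taxon's own
reading frame — gaps removed, read 5′→3′ — so everything downstream of a
frameshift is scanned in the shifted frame, which is what a ribosome would
read. Consequence: a stop planted in the original frame downstream of a
frameshift on the same sequence is *not* seen as a stop; ground-truth
recovery is exact only for lesions that do not interact this way.

The 3′-terminal stop is never a lesion, and a stop within the final 10% of
the reference ORF is reported but does not flip the status by default
(C-terminally truncated opsins can retain function; the window and whether
it flips are configurable, since real datasets contain judgment calls — a
late-exon stop that one study treats as loss, another as intact).

Shared lesions are placed by Dollo parsimony: a single origin on the stem of
the carriers' MRCA. If that clade contains non-carriers the lesion is
flagged homoplastic and left tip-assigned rather than forced to a single
origin.

## Spectral tuning

λmax for MWS/LWS pigments follows the five-site rule (sites 180, 197, 277,
285, 308, bovine rhodopsin numbering). The shipped table pins the four
published assignments exactly — SHYTA 560 nm, AHYTA 555, SHYAA 543, AHYAA
536 — and falls back to additive single-substitution shifts only for
haplotypes outside the table, flagged `additive`. The exact table is
required because measured haplotypes are not additive: the S180A and T285A
shifts (−5 and −17 nm from the printed values) would predict 538 nm for the
double mutant, not the observed 536. Fallback shifts for H197Y (−28), Y277F
(−8) and A308S (−27) come from the spectral-tuning mutagenesis literature
and are approximate.

SWS1 classification uses site 86, the dominant UV/violet switch: F86 → UV
(nominal 360 nm); any other resolved residue → violet/visible (>400 nm),
flagged as an extrapolation. The full 11-site set (46, 49, 52, 86, 90, 93,
97, 113, 114, 116, 118) is carried in the profile and configurable, since
the literature varies on the exact membership.

Residue numbering is anchored by global pairwise alignment (BLOSUM62, affine
gaps −11/−1) to a bundled reference protein — bovine rhodopsin, UniProt
P02699, mature 348-aa sequence, the community anchor for opsin site
numbering. The reference is package data and swappable; if alignment
identity falls below 15% the map is returned empty with a warning rather
than producing numerology from a non-alignment. Any codon containing a gap
or N translates to X and renders that site unresolved ('?') rather than
guessed.

## Ancestral reconstruction and convergence

Fitch parsimony (two passes, ambiguity kept as state sets, deterministic
representative = parent state if possible else alphabetically first) gives
the exhaustive-minimum score on binary trees; gaps/X are missing data and
cost nothing. Marginal ML reconstruction uses the inside–outside
computation; the default model is Poisson (equal exchangeabilities and
frequencies) because the upstream software this stage mirrors does not
document its matrix for this step, and a (Q, π) pair can be plugged in.
Reported states are posterior argmaxes with alphabetical tie-breaking; tip
states are fixed to observations.

Substitutions are enumerated wherever parent and child representatives
differ (one event per branch × site). Two caveats are inherent and worth
stating: (i) the root of a reversible model is unidentifiable, so an event
on one root-adjacent branch can legitimately be reconstructed on its sibling
with direction flipped; (ii) masked parallel changes (X→Y on a parent
branch, Y→X back on a child) are invisible to any reconstruction. The
recovery property in the test suite accounts for (i) explicitly and absorbs
(ii) in its 90% threshold.

Convergence between a branch pair partitions the sites changed on both into
convergent (same derived state) and divergent (different); the pair must be
non-nested, since on a single evolutionary path the comparison is undefined.

## Pseudogene dating

Branches are categorized against the placed lesion origins: the origin
branch is **mixed** (constraint was lost partway along it), everything
strictly below is **nonfunctional** (even if it carries its own later
lesion), ancestors whose descendant tips are all carriers are
**premutation**, the rest **functional**. ω is fitted per category with the
branch-label model; the nonfunctional-category ω̂ is not used for dating but
reported as a diagnostic (it should be ≈1; a strong deviation is flagged on
the estimate).

The mixed branch is then resolved: T from the calibrated tree (node ages in
Ma), ω_f from the functional category, ω_m from the mixed branch, T_p =
T(ω_m − ω_f)/(1 − ω_f) clamped to [0, T] with clamping flagged, loss date =
branch start age − T_f. The equation is the time-weighted average of the
two eras' dN/dS, which presumes the synonymous clock is constant across the
loss — exactly what the simulator enforces (below), and approximately true
for real data over these timescales. No analytic confidence interval is
provided; the uncertainty quoted in the tests is simulator-calibrated
(median |error| ≤ 3 My at the reference setting of a 20-My branch, loss
halfway, ω_f = 0.1, 800 codons).

Where both dating routes exist (direct formula on a known branch; category
resolution after lesion placement) they are reported side by side, not
merged.

## The simulator: what a green test establishes

Sequences evolve by exact event-by-event (Gillespie) CTMC sampling — not
transition-matrix endpoint sampling — so every substitution event is
recorded and downstream stages can be scored against the true history.
Branch-specific ω, κ, uniform or F1x4 root frequencies, seed-reproducible.

Pseudogenization: before the loss a lineage runs on the 61 sense codons at
the background ω; at the loss moment a stop codon is planted (inherited by
all descendants — it is the pseudogenizing lesion) and the chain switches to
all 64 codons with pure mutation rates (sense↔sense changes neutral, stops
tolerated). All branches share one neutral rate (default 0.01
substitutions/site/My — a fast nuclear gene), so the synonymous clock is
constant and dN scales with ω, matching the dating model's premises.

Deliberately not emulated: indel *evolution* (lesions are injected at stated
coordinates, not generated by an indel process), rate variation beyond
branch-ω, selection on codon usage, alignment error, and sequencing
artifacts. A green recovery test therefore establishes the estimators are
correct and calibrated *under the model they assume*, not that real opsin
alignments satisfy that model. Default scenario sizes follow the real
datasets this mirrors: ~400 codons (an SWS1-length coding alignment),
12-taxon trees with one high-duty-cycle-echolocator clade and cave-roosting
lineages as contrast groups, κ = 2, background ω ≈ 0.1–0.2.

## Known limitations

- Free-ratio on large trees is out of desk scale; the engine is exact but
  O(branches) in parameters — keep it to small trees.
- BEB site identification is out of scope; only the clearly-labeled naive
  class posterior is provided.
- Branch-site models (foreground ω varying by site) are not implemented.
- The λmax additive fallback is an extrapolation; its provenance flag should
  be propagated to any downstream figure.
- `place_lesions` assumes lesion signatures (kind, column, length) identify
  descent; two independent identical lesions at one column are
  indistinguishable from shared ancestry unless the tree exposes them as
  homoplastic.
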