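# Methods

This note records the models implemented in rrmbindkit, their assumptions,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate about real data.

## Contact-propensity scoring

**Model.**  RRM domains engage single-stranded RNA through a conserved set
of *master positions* on the β-sheet face.  Given contact records — one row
per residue–nucleotide contact observed at a master position — the trained
model is a table of conditional distributions

    P(n | position, residue) = (count + α) / (total + 4α),   n ∈ {A, C, G, U},

with Laplace pseudocount α = 1 by default (overridable; α = 0 is allowed but
querying a never-observed pair then raises instead of returning a silent
zero).  A window w is scored additively,

    score(w) = Σ_p log10( P(w[slot(p)] | p, res_p) / q(w[slot(p)]) ),

where slot(p) maps master positions to window offsets (two positions may
share one slot — two residues reading one base) and q is the background,
uniform 0.25 by default.  The additive form assumes position independence
given the profile; no inter-nucleotide coupling is modelled.

**Choices.**  Base-10 logs, per-window sums (no per-nucleotide averaging),
deterministic tie-breaks (lexicographic on the motif with A<C<G<U,
alphabetic on residue codes).  The master alignment is *not* re-derived:
positions and slot maps are explicit inputs.  Design searches enumerate
exhaustively (k ≤ 8, at most 4⁸ = 65 536 candidates), so rankings are exact,
not heuristic.  The protein switch uses a lexicographic objective — first
minimise the log-odds toward the nucleotide being designed away from, then
maximise it toward the target — because a single weighted combination would
need an arbitrary trade-off constant.

**Packaged fixture.**  The shipped matrices (`fixtures.py`) are synthetic.
They were hand-calibrated once so that the MSI-1-like profiles reproduce the
study's qualitative outcomes (UAG as top core motif for both domains,
CUAGU/CUAGG as top flanked motifs, CCAGG/GCAGG as the best CAG-core switch
motifs, N and M as the top substitutions at the two pyrimidine-contact
positions, with A and S as the runners-up sharing nearly the same
objective).  Absolute fixture scores carry no meaning beyond these rankings,
and nothing here reproduces any published score value.

## Consensus motifs, sites, and hairpins

Patterns are restricted regular expressions over {A,C,G,U} with alternation
and bounded repetition.  Matching is anchored at every start position and
takes the longest match there, so overlapping occurrences are all reported.
Hits overlapping by ≥ 1 nt merge into one maximal site — a UAG embedded in a
(G/A)U₁₋₃AGU hit counts once, which is what makes the single-site/two-site
oligo accounting come out right.  Reported coordinates are 1-based
inclusive; internals are 0-based half-open.

Hairpin validation accepts Watson–Crick and G–U wobble pairs, single
strands folding back on themselves only.  Structures are user inputs; no
free-energy folding is attempted.  A site is "loop" only if *every* one of
its nucleotides is unpaired, "stem" only if all are paired, else "mixed" —
under this strict rule a site whose first base sits on the innermost stem
pair is mixed even if the rest lies in the loop.

## SPR kinetic models

**1:1 Langmuir.**  Association R(t) = Req(1 − e^−(ka1·C + kd1)t) with
Req = Rmax·C/(C + KD1), dissociation R = R(t_assoc)·e^−kd1·t, KD1 = kd1/ka1.
Closed form is the default path; an ODE route (dR/dt = ka1·C·(Rmax − R) −
kd1·R) cross-checks it to < 1e-6 RU.

**Bivalent analyte.**  States AL (one protein–one RNA) and AL2 (one protein
bridging two surface RNAs):

    dAL/dt  = ka1·C·Lfree − kd1·AL − ka2·AL·Lfree + kd2·AL2
    dAL2/dt = ka2·AL·Lfree − kd2·AL2,     Lfree = Ltot − AL − 2·AL2,

response ∝ AL + AL2 (bound protein mass).  ka2 is per surface density
(RU⁻¹ s⁻¹); a conversion factor g (default 1e-8 M/RU, config) expresses
KD2 = kd2/(ka2/g) in molar equivalents.  Because the surface-to-molar
conversion of the second step is instrument-dependent, KD2 is a recovery
target only when g is held fixed between simulation and fit.  With ka2 = 0
the model reduces exactly to 1:1 (tested to 1e-6 RU), and mass balance
AL + 2·AL2 + Lfree = Ltot is conserved to ~1e-14 relative.

**Tandem competition.**  Two domains of one analyte compete for a
single-site RNA surface: states B1, B2 (anchored by domain 1 or 2) and X
(bridged across two RNAs), with bridging rates kb1/kb2 (RU⁻¹ s⁻¹) and
release at the anchoring domain's off-rate.  With bridging off and equal
domain rates the model collapses analytically to a 1:1 trace with doubled
association flux; with bridging on, the instantaneous off-rate −d lnR/dt is
monotonically nonincreasing during the wash — the biphasic fingerprint.

**Integration.**  LSODA with atol 1e-12 / rtol 1e-10.  The association
segment always ends exactly at t_assoc so the wash starts from the true
phase-boundary state.  Negative free-ligand excursions beyond 1e-6·Ltot
raise a numerical error rather than being clipped.

**Fitting.**  Global bounded least squares (scipy trust-region reflective)
across all concentrations simultaneously, rate constants on a log10 scale
within ka ∈ [1e2, 1e9] M⁻¹s⁻¹, kd ∈ [1e-5, 10] s⁻¹.  Initialisation is
multi-start: kd from the dissociation-tail slope of the strongest curve, ka
log-spaced (5 starts for 1:1; for the bivalent model, ka1/kd1 seeded from a
1:1 fit and ka2 multi-started over [1e-5, 1e-2] RU⁻¹s⁻¹).  Standard errors
come from the Jacobian at the optimum (σ² (JᵀJ)⁻¹); 95% CIs are formed in
log space and exponentiated, so they always contain the point estimate.  The
KD1 interval combines the two log-space errors in quadrature, ignoring their
covariance (conservative).  Under σ = 1 RU Gaussian noise on the standard
schedule, the measured coverage of the 95% intervals is ≈19/20 (checked in
the suite).  All-zero data raise a degenerate-fit error; single-concentration
fits are flagged as weakly identifiable rather than refused.

**Rate-distribution map.**  min_{w ≥ 0} ‖Bw − y‖² + λ‖w‖², where columns of
B are unit-amplitude 1:1 traces on a log-spaced (ka, kd) grid (default
12×12 over ka ∈ [1e4, 1e8], kd ∈ [1e-4, 1]) and the nonnegative solution
comes from NNLS on the Tikhonov-augmented system.  This construction makes
the weights exactly invariant to curve ordering and exactly linear in
response amplitude.  λ defaults to 1e-3 — small enough that a component
sitting on a grid node is recovered with ≥ 95% of the weight in its 3×3
neighbourhood.  Peaks are 8-neighbourhood local maxima above 5% of the
global maximum; because NNLS splits one broad physical component across a
few nearby nodes, maxima within two grid cells (Chebyshev) of a larger peak
are absorbed into it — about 0.7 decades on the default grid, below the
one-decade separation at which two components are considered resolved.  The
decomposition is defined from scratch here; only its qualitative peak
structure (one mode for a 1:1 interaction, two for a bivalent one) is
interpreted.

## Hairpin folding–binding equilibrium

Two-state hairpin, closed ⇌ open with K_open = [open]/[closed], protein
binding the open form only at n independent identical sites of dissociation
constant KD.  At free protein p the per-strand partition function is
Z = 1 + K_open(1 + p/KD)^n, giving fraction closed 1/Z and bound protein
per strand K_open·n·(p/KD)(1 + p/KD)^(n−1)/Z.  Free protein is the unique
root of conservation on [0, P_tot], found by Brent bracketing (xtol 1e-30);
RNA and protein conservation and back-computed K_open/KD hold to ≤ 1e-9 and
≤ 1e-6 relative.  Fluorophore physics is abstracted: the quencher is fully
efficient in the closed state, so signal ∝ (open + bound), normalised to the
zero-protein point by default (denatured-control normalisation available).
An optional closed-form-binding leak is deliberately absent — binding to the
closed state is fixed at zero, matching the conclusion that the protein
engages the single-stranded form.  Defaults (K_open = 0.2, KD = 50 nM,
RNA_tot = 400 nM) are illustrative assay-scale values: no measured
K_open/ΔG for the study hairpins exists, so no quantitative fluorescence
value is asserted anywhere — only monotonicity, conservation, limits, and
oracle agreement.

## Synthetic data and what the tests show

One integer seed fans out deterministically into independent per-generator
streams; identical seed and arguments give byte-identical output.  The
generators emulate (i) structure-derived contact tables with planted
position-specific preferences, (ii) Biacore-style injection series
(noiseless model traces + i.i.d. Gaussian RU noise + optional linear
drift), and (iii) two-state beacon titrations.  They do *not* emulate
instrument artifacts (bulk refractive-index jumps, mass-transport
limitation, surface regeneration), NNLS-confounding baseline structure,
partial hairpin intermediates, or inter-position coupling in binding sites.
Passing recovery tests therefore demonstrates correctness of the estimators
under their own generative assumptions — identifiability and numerical
health — not robustness to the systematic errors of real sensor data.

**Problem sizes.**  The standard kinetic schedule is six twofold analyte
concentrations 7.8–250 nM, 120 s association, 300 s dissociation, 0.5 s
sampling (≈5 000 points per global fit); ODE-heavy tests use three
concentrations at 1 s sampling.  Propensity recovery uses 1e4 draws per
(position, residue) pair, at which the worst-case total-variation error is
≈0.014.  Rate maps use the 12×12 default grid.

## Known limitations

* Scores are position-independent log-odds sums; cooperative or stacked
  reading of neighbouring bases is out of scope.
* The bivalent model treats the surface as well-mixed; avidity is captured
  through a single effective ka2, not through explicit surface geometry.
* KD2's molar scale depends entirely on the declared RU→M factor g.
* The hairpin model is strictly two-state at equilibrium; opening kinetics
  and partially-melted intermediates are not represented.
* Dot-bracket inputs are trusted (after validation); there is no folding
  prediction, so stem registers must come from the user.
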