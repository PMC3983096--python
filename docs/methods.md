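# Methods

## Scope and model

`qsar3d` fits linear activity models to molecular interaction fields
sampled on a lattice around a rigidly aligned congeneric series. The
statistical core is univariate PLS (NIPALS) on a mean-centred descriptor
matrix whose columns are (grid point, field kind) pairs; everything else —
alignment, field evaluation, cross-validation, external validation,
contouring — exists to feed or interrogate that regression.

## Alignment

The series is superposed on a template compound (by default the most
active training compound) through its shared rigid scaffold. The scaffold
is specified either as a SMARTS pattern or as an explicit atom-index list;
matched atoms are fitted by the Kabsch least-squares rigid superposition
(SVD of the centred covariance with a reflection-correcting sign), and the
resulting rotation + translation carries the whole molecule. Only the
matched scaffold atoms enter the fit — no flexible fitting, no
heavy-atom-neighbourhood weighting. When a SMARTS pattern matches a target
more than once, the match with the lowest post-superposition RMSD wins;
exact ties fall back to the first match in atom-index order. Collinear
scaffolds are rejected because the rotation about the line is undetermined.

## Fields

All compounds share one axis-aligned lattice: the union bounding box of the
aligned set extended by a 4 Å margin and discretised at 2 Å (both
configurable; the margin default is the package's own choice, the spacing
the field's convention).

**CoMFA.** The probe is an sp³ carbon with charge +1. Steric energies use
the Lennard-Jones 12-6 form with Tripos-style per-element parameters
(`r*`, ε; pair rules `r*ᵢₚ = r*ᵢ + r*ₚ`, `εᵢₚ = √(εᵢεₚ)`), electrostatic
energies the Coulomb form with constant 332.17 kcal·Å/(mol·e²) and a
distance-dependent dielectric `D(r) = r` (a constant dielectric is a config
option). Both fields are clamped to ±30 kcal/mol; the clamp also absorbs
the r → 0 singularities, so lattice points inside atoms never raise.
Electrostatic values at sterically clamped points are retained rather than
replaced by column means — a simpler convention than some legacy
implementations use, and a documented divergence.

**CoMSIA.** Similarity indices `A(q) = −Σᵢ w_probe·w_ik·exp(−α rᵢq²)` with
α = 0.3 (accepted range ≈ 0.2–0.4) and a probe of radius 1 Å and value +1
in every property. Atom property values `w_ik`: steric — vdW radius cubed;
electrostatic — partial charge; hydrophobic — the atom-typed Crippen logP
contribution; donor/acceptor — indicator of the flag. The Gaussian makes
the field smooth and finite everywhere; no truncation is applied.

Partial charges come from the input file (`charge_policy="from_file"`,
MOL2) or are recomputed with RDKit's Gasteiger scheme
(`charge_policy="recompute"`, the default). The Gasteiger–Hückel variant
used by commercial packages is not openly available; plain Gasteiger is the
nearest open equivalent and is documented as an approximation. Donor =
N/O bearing at least one hydrogen; acceptor = N/O not positively charged
(deliberately simple — no amide-nitrogen exclusion).

**Descriptor matrix.** Columns with standard deviation below a per-field
threshold are dropped (default 2.0 kcal/mol for CoMFA kinds — the usual
minimum-sigma column filter — and 0.0 for CoMSIA kinds; exactly constant
columns always go). Optional block scaling (`"block-standard"`, the
default) rescales each field block to unit total variance so that no block
dominates by sheer numeric range; the factors are stored and reapplied when
new compounds are featurised.

## PLS, cross-validation and component selection

PLS1 is fitted by NIPALS on centred (not column-autoscaled) data; for a
univariate response each component is a single exact deflation step, and at
full rank the fit coincides with ordinary least squares (a pinned test
property). Reported statistics:

* r² and SEE = √(RSS/(n − c − 1)) on the training fit;
* q² = 1 − PRESS/Σ(y − ȳ)² and SEP = √(PRESS/(n − c − 1)) from
  cross-validation (leave-one-out, or leave-group-out averaged over random
  partitions — 10 groups × 25 repeats by default, seeded);
* F = [r²/(1 − r²)]·[(n − c − 1)/c], reported as +∞ at r² = 1;
* per-block field contributions: block share of Σ|coefficient·column stdev|.

SEE and SEP deliberately share the √(PRESS/(n − c − 1)) form, differing
only in which residuals enter.

The component count follows the 10% rule, read as a *relative* improvement
threshold: starting at one component, c + 1 is accepted only while
q²(c+1) − q²(c) > 0.10 · max(q²(c), ε) with ε = 0.01. The floor ε keeps the
comparison meaningful when q² is near zero or negative (with a literal
relative rule any positive gain would pass there); ties and marginal gains
resolve to the smaller count. The published descriptions of this rule are
ambiguous between absolute and relative readings; the relative reading is
declared here and pinned by tests.

**Region focusing** multiplies each retained column by
(|coefficient| · column stdev)^w, normalised to unit mean weight (w = 1 by
default; w = 0 is the identity), then refits at the same component count
and reports q² before and after. This sharpens the model around lattice
regions already carrying signal, the same intent as the commercial
implementations' focusing step, realised here as plain column reweighting
rather than component rotation.

**Bootstrap** draws B = 100 row resamples with replacement, refits at fixed
c, and summarises r² and SEE as mean ± sd; resamples with constant activity
are skipped and counted.

## External validation

For a held-out test set with predictions ŷ and training-set mean activity
ȳ_train: PRESS_test = Σ(ŷ − y)², SD = Σ(y − ȳ_train)², r²_pred = 1 −
PRESS_test/SD; Pearson R; free regressions in both directions (the
literature is ambiguous about the regression direction, so both slopes and
intercepts are reported); through-origin slopes k = Σyŷ/Σŷ² and
k′ = Σyŷ/Σy² with their determination coefficients r²₀ (actual on
predicted) and r′²₀; and r²_m = r²(1 − √(r² − r²₀)), computed with r²₀ by
default (the r′²₀ variant is also reported). When the through-origin fit is
no worse than the free fit (r²₀ > r²), no penalty applies and r²_m = r².
The acceptance gate passes only if all five hold: q² > 0.5, r² > 0.6,
(r² − r²₀)/r² < 0.1, 0.85 ≤ k ≤ 1.15, r²_m > 0.5 (strict inequalities
except the k band).

Degenerate inputs: zero-variance actual activities are an error;
zero-variance predictions return r²_pred (which is 0 when the constant is
the training mean) with the correlation-based statistics as NaN, since a
correlation against a constant is undefined.

## Contour maps

For each field kind, each surviving column contributes coefficient ×
column stdev at its grid point (dropped columns contribute zero). The
"80%/20% contribution" levels are implemented as the 80th/20th
linear-interpolation percentiles of the signed nonzero std\*coeff
distribution; points at or above the favourable level form the favourable
set, points at or below the unfavourable level (and strictly below the
favourable level, which matters only when the two levels coincide) the
unfavourable set. Whether legacy software computes contribution levels by
percentile or by cumulative sum is not publicly documented; the percentile
rule is this package's declared convention, pinned by tests. Grids
round-trip through plain-text OpenDX scalar files.

## Synthetic series

The generator emulates the shape of a real congeneric SAR study: a rigid
fused-bicyclic all-carbon scaffold (10 atoms, naphthalene-like geometry)
with up to three substituent sites, each optionally carrying one
single-sphere pseudo-atom drawn from a small vocabulary (methyl, hydroxyl,
amine, fluoro, bromo, thio, ammonium — each with element, partial charge,
hydrophobicity and donor/acceptor flags). Activities are

pIC50 = baseline + Σ_sites Σ_props coef(site, prop) · w(prop) + N(0, σ²)

with property values identical to the CoMSIA atom properties (r_vdW³,
charge, hydrophobicity, donor/acceptor indicators), so the field → activity
relationship is exactly linear and recovery is provable rather than
anecdotal. Defaults: 81 compounds with 15 held out (the shape of the
packaged real study; smaller sets hold out about a quarter), baseline 5.6,
noise sd 0.2 log units, per-site vacancy probability 0.25, and planted
effects (bulk favoured at R1, negative charge at R2, lipophilicity and
donation at R3) chosen so the default draw spans well over 3 log units —
the accepted minimum activity spread for a reliable model. Compounds are
generated pre-aligned; the scenario seed makes every output byte-identical.

**Recovery measure.** The planted truth is compared with the fitted model
through a probe library: one compound per (site, substituent) pair plus the
bare scaffold. The model's predicted activity effect of each probe
(prediction minus predicted bare-scaffold activity) is compared with the
planted effect by cosine similarity. This measures recovery in the
activity basis where both vectors are identified; regressing fitted
activities on the per-site property features is less stable because the
five property columns of a site are strongly collinear over a small
vocabulary, and PLS shrinkage distorts exactly those directions.

**What the benchmark does not show.** Real series have flexible
substituents, conformational uncertainty, correlated property changes and
alignment noise; the generator has none of these, and its activities are
exactly linear in the fields by construction. Passing tests therefore
demonstrate the correctness of the machinery (fields, PLS, validation
statistics) and its statistical behaviour under noise — not that the
workflow's chemical assumptions hold for any particular real series. The
packaged 81-compound activity table exercises the validation suite on real
printed numbers, but the original 3D structures are not available in
machine-readable form, so the field/PLS stages cannot be rerun on them.

## Numerical conventions and edge cases

* q² uses the full-set mean in the denominator; predictions of left-out
  compounds come from complete refits (no shortcut updates).
* Degenerate NIPALS steps (no residual covariance with y) truncate the
  component sequence; an immediately degenerate first component is an
  error (X uncorrelated with y).
* Constant activity vectors are rejected wherever a model or a q² would be
  undefined.
* Leave-group-out with groups = n reduces exactly to leave-one-out.
* All randomness (group partitions, bootstrap resamples, scenario draws)
  flows from explicit integer seeds; reruns are bit-reproducible.
* Problem sizes in the shipped tests and the acceptance script (60-compound
  scenarios, ~1400-column matrices, 27-point oracle grids) are the
  package's documented desk-scale conditions: large enough for stable
  statistics, small enough to run interactively.

## Known limitations

* Gasteiger charges, the Crippen hydrophobicity table and the packaged
  Tripos-style LJ parameters are open approximations of the (unpublished)
  parameter sets inside commercial CoMFA/CoMSIA implementations; absolute
  field values therefore differ from legacy outputs even where the
  formulas match.
* Region focusing reweights columns; it does not rotate latent components.
* No applicability-domain estimation, y-randomisation, conformer search or
  docking-based alignment.
* Reading a synthetic series back from SDF reassigns charges and
  hydrophobicities from structure (the file cannot carry the vocabulary's
  planted values), which attenuates the planted signal relative to the
  in-memory route; recovery tests use the in-memory records.
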