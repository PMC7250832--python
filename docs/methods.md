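# Methods

## Constraint-based model and FBA

A model holds metabolites (id with compartment tag `[c]`/`[p]`/`[e]`,
optional elemental formula and charge), reactions (signed stoichiometry,
bounds in mmol·gDW⁻¹·h⁻¹, GPR rule, structural kind) and genes. The
stoichiometric matrix is assembled with rows = metabolites and columns =
reactions, so steady state is S·v = 0. Reversibility is encoded purely
by a negative lower bound; confidence scores (1–4) are metadata and
never affect solving. Boundary pseudo-reactions (exchange, sink,
demand, biomass) touch the balance checker only as exempt entries.

FBA maximizes the flux of a named objective (normally a biomass
pseudo-reaction whose flux is μ in h⁻¹) with `scipy.optimize.linprog`
(HiGHS), feasibility tolerances tightened to 1e−10 so solutions satisfy
|S·v|∞ ≤ 1e−9. Because optimal flux vectors of genome-scale LPs are
almost always degenerate, the reported vector comes from a second LP
that fixes the objective at its optimum (with a 1e−9 slack for
numerical safety) and minimizes Σ|v| via the standard positive/negative
split. The objective *value* is always taken from the first LP. This
parsimonious tie-break is a design choice — nothing in the biology
selects a unique optimum — and it is what makes flux-ratio maps
reproducible run to run; flux-level comparisons should therefore use
~1e−6 tolerances, not 1e−9.

A medium is a map from exchange-reaction ids to (lb, ub); exchanges not
listed are closed to uptake (lb = 0) but keep their secretion bound.
An anaerobic medium forces the O2 exchange lb to 0 at construction.
The medium can also pin the NGAM flux: defaults are 0.92 (oxic) and
0.15 (anoxic) mmol ATP·gDW⁻¹·h⁻¹, switchable per medium because
maintenance demand drops without aerobic respiration. The bare model
leaves the NGAM reaction free so that v = 0 remains feasible when all
exchanges are closed.

## Source screening, uptake fitting, essentiality, sweeps

* **Screening** (roles C, N, CN): candidate exchange opened to −10;
  every remaining background nutrient (oxygen included) opened to −30 so
  only the candidate limits growth; for role C the medium's carbon
  source is removed from the background, for N the ammonium, for CN
  both. "Grows" means μ > 1e−6 h⁻¹ — an absolute threshold chosen
  because the biological claim is binary growth/no-growth. Growth per
  carbon divides μ by the candidate's carbon count from its formula;
  candidates without a formula get a warning and no normalized value.
* **Inverse uptake fitting** bisects on the uptake magnitude for the
  smallest u whose FBA growth reaches the target (growth is monotone in
  u, verified by probing the endpoints); 100 iterations bound the
  interval far below the growth tolerance.
* **Gene deletion**: a deleted gene closes (0,0) every reaction whose
  GPR evaluates false without it; AND = all subunits required, OR =
  isozymes substitute, and orphan (empty) rules are never switched off.
  Essentiality is again the absolute μ < 1e−6 call, not a wild-type
  fraction.
* **Storage-demand sweeps** fix a demand flux through the PHB drain and
  re-solve; growth is monotone non-increasing by LP theory, and the
  sweep records infeasible demands as zero growth.
* **Substrate hierarchy**: all substrates offered at −10 with the O2
  exchange pinned (e.g. −5); the parsimonious tie-break makes the
  reported uptake split unique.

## Dynamic FBA

The batch loop is the static-optimization scheme: at each step the
uptake bound of every tracked extracellular metabolite is
−min(|u_fixed|, C/(X·Δt)) (kinetic bound capped by availability), FBA is
solved, then

    X ← X·e^{μΔt},   C ← C + v·X̄·Δt,   X̄ = X(e^{μΔt}−1)/(μΔt)

with X̄ → X as μ → 0. The exponential-within-step update with
average-biomass consumption was chosen (over plain Euler) because it
makes the single-substrate constant-μ batch match the closed-form
depletion time exactly up to step resolution; halving Δt changes final
biomass by well under 1%. Concentrations are clamped at 0 after each
update; an infeasible step (maintenance unsatisfiable after the
electron acceptor runs out) ends the simulation with the remaining
steps recorded as a flat stationary phase and the status noting the
time. Initial biomass is interpreted in g·L⁻¹. Product toxicity is
deliberately outside the model; an optional shutoff hook (stop growth
once a tracked metabolite exceeds a user-set concentration) exists but
is off by default.

The anaerobic reference configuration is 40 mM carbon, 20 mM nitrate,
X₀ = 0.038 g·L⁻¹, uptakes −3 and −2.82 mmol·gDW⁻¹·h⁻¹, Δt = 1 h for
200 steps.

## Transcriptome integration (GIMME) and sampling

The expression cut-off is a quantile (default: first quartile, linear
interpolation between order statistics) of all FPKM values present in
the profile; genes absent from the table are *no data*, excluded from
the quantile and never grounds for flagging. Reaction-level expression
maps AND → min (a complex is limited by its scarcest subunit) and OR →
max (isozymes add capacity), with no-data children skipped. Reactions
below the cut-off are flagged; an LP minimizes total flux through
flagged reactions subject to the objective holding ≥ 90% (configurable)
of the parent optimum; flagged reactions carrying < 1e−8 flux in that
solution are removed (bounds 0,0). The 0.9 fraction is the method's
canonical default — the reduction should specialize the model, not
cripple it. The builder re-solves the reduced model and raises if the
fraction is lost.

Sampling is artificially-centered hit-and-run: warm-up points from
per-reaction flux min/max LPs, directions drawn as (random warm-up
point − running center) projected onto the null space of S, step length
uniform on the feasible segment, with configurable warm-up discard
(default 1000 steps) and thinning (default 100). The null-space
projection of directions and recorded points keeps |S·v|∞ < 1e−6 over
arbitrarily long walks. A point polytope (all bounds pinned) is detected
and returns the point; unbounded directions are pre-clipped at ±1000.
Sampling is deterministic given the seed. Flux-ratio maps divide each
|v| by the carbon-uptake |v| (the uptake reaction maps to 1); the
reciprocal convention exists in the literature, and the flux÷uptake
direction is used consistently here.

## Reconstruction utilities

* **RBH orthologs**: best hit per query by lowest e-value (ties:
  bitscore, then identity); a pair is kept only if mutual-best and both
  directional hits pass identity ≥ 40%, coverage ≥ 80% and e < 1e−20.
  Coverage is required on both query and subject by default — the
  stricter reading — with a switch for query-only.
* **GPR curation filter**: e < 1e−5, identity > 30%, coverage of both
  proteins > 70%, all strict inequalities (boundary values rejected).
* **Draft projection**: a donor reaction survives iff its GPR rewritten
  over the target's genes is still satisfiable: unmapped genes act as
  deleted, so an AND missing a subunit fails while an OR drops the
  unmapped isozyme; orphan reactions always project. Drafts merge by
  reaction id with provenance (donor label or "both"); identical ids
  with different stoichiometry are an error, and differing rewritten
  GPRs for the same id are OR-combined.
* **Biomass coefficients**: amino-acid coefficients ∝ residue frequency
  over the whole proteome, dNTPs from both-strand genome composition
  (forcing A=T, G=C), NTPs from coding-strand composition as a
  transcript proxy (an FPKM-weighted mode exists). Residue masses are
  monomer minus water so that Σ coeff × mass closes each class's mass
  fraction ×1000 mg·gDW⁻¹ exactly. Default mass fractions (protein
  0.55, RNA 0.17, DNA 0.03, lipid 0.12, murein 0.03, ions 0.01, soluble
  pool 0.09 g·gDW⁻¹) are standard Gram-negative values used in the
  absence of measured composition and must sum to 1 ± 0.01. The lipid
  class reserves a 10% share for the sphingolipid precursor sphinganine
  (sphingolipids replace LPS in the modelled envelope); non-sequence
  classes are lumped pseudo-monomers with nominal molar masses.
* **Uptake rates**: for constant specific rate q, C(t) is linear in
  ∫X dτ with slope q, so the estimate is the OLS slope of concentration
  against the trapezoidal cumulative biomass-time, with its regression
  SE — more robust than two-point differencing and exact in the
  noise-free limit.
* **Gap report**: per-precursor maximal-demand FBA flags biomass
  components the network cannot make. Currency couples whose moiety
  returns on the product side (ATP→ADP+Pi) cannot carry a net drain and
  appear as zero by construction; the report documents this so they are
  not mistaken for gaps. Gap *filling* is curation and out of scope.

## The synthetic toy network

The generator emulates the central metabolism the analyses probe:
substrate funnels (a C4 3-HB-like acid, a C10 dicarboxylate via
β-oxidation, a C10 tetralin-like substrate whose two-step pathway
consumes O2 and reducing power through an AND-ruled dioxygenase
complex, lactate, a glutamate-like C+N source, and glucose with an
exchange but deliberately no transporter), a lumped TCA oxidation, a
glyoxylate-shunt route to the gluconeogenic precursor (gene
`aceA_toy`) with a pyruvate-side alternative (`ppsA_toy`), oxidative
phosphorylation with O2 and nitrate branches (nitrate in, nitrite out),
ammonium assimilation, an optional PHB branch with a demand drain,
NGAM, and separate aerobic/anaerobic biomass reactions. GPRs include
AND complexes, two OR isozyme pairs (configurable 0–2) and orphan
transport/maintenance steps.

Chemistry is pseudo-elemental (C, N, O plus bookkeeping tokens H for
redox pairs, P for phosphate, A for adenosine) with integer
stoichiometry; substrate formulas are derived from their funnel yields
(acetyl units, redox pairs, ATP cost — all parameters), so every
parameterization passes the elemental balance check by construction.
Default yields make the fatty-acid-like substrates the best per-carbon
sources and tetralin the most O2-expensive, so the qualitative
contrasts the analyses assert (per-carbon hierarchy, O2-limited
substrate preference, nitrate-limited anaerobic batch) hold by design.
The toy network claims no quantitative agreement with any real
organism; what passing tests show is that the *algorithms* behave
correctly on a network with the right structure, not that any specific
organism's rates are reproduced.

Synthetic FPKM profiles are log-normal with ~30% of expressed genes
pinned at a detection-floor value (the 30th percentile of the draw) and
"off" genes drawn strictly below half the floor. The floor atom means
the profile's first quartile equals the floor whenever fewer than a
quarter of the genes are off, so the strict below-quartile rule flags
exactly the constructed off genes — and nothing when the off set is
empty. This emulates an RNA-seq quantification floor; real FPKM
distributions are smoother, so on real data the first-quartile cut-off
always flags some genuinely low-expressed genes, which is why the
cut-off is exposed as a parameter for sensitivity sweeps.

Synthetic batch time courses are forward dFBA runs with additive
Gaussian noise on concentrations (clipped at zero), biomass noise-free,
deterministic per seed.

## Scenario runner and problem sizes

`gemflux.pipeline.run_scenario` chains the modules into named analyses
(screening, growth at measured uptakes, anaerobic dFBA, two GIMME
conditions, tetralin essentiality, PHB sweep, O2 hierarchy), writing
JSON + TSV reports that embed the applied bounds, solver statuses and
software version; outputs carry no timestamps so repeat runs are
byte-identical. Scenarios that only make sense against a published
full-scale model report `supplementary model not provided` when no
sheets are configured instead of failing.

Default problem sizes — 100 random ≤8-reaction networks for the
vertex-enumeration cross-check, 5000 ACHR samples on the 1-D segment,
20 noisy replicates for uptake recovery, 200 dFBA steps — keep the
whole verification battery in the seconds-to-minutes range on one CPU
while leaving the statistical checks (3·SE bands) well-powered.

## Known limitations

* The LP layer rebuilds S per solve; fine at these scales, wasteful for
  repeated genome-scale screens (a caching layer would be the next
  step).
* The ACHR implementation computes a dense null-space basis; it targets
  models up to a few thousand reactions, not millions.
* dFBA uses fixed uptake bounds (no Michaelis–Menten kinetics) and no
  product inhibition, matching the static-optimization formulation.
* The tabular dialect is deliberately single (TSV, fixed header);
  converting publisher spreadsheets to it is a one-off external step.
* SBML support covers L3+fbc bounds/objectives/GPRs and stores reaction
  kind/subsystem/confidence in notes; group/annotation extensions are
  not read.
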