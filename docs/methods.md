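# Methods

## Scope and model formalism

`ecmito` builds compartmentalized stoichiometric models (cytosol,
mitochondrial outer membrane, intermembrane space, inner membrane, matrix,
extracellular, plus a pseudo-compartment for accounting species) and solves
them as linear programs through COBRApy/GLPK. The contribution layers — PMF
coupling, protein-import reactions, cofactor incorporation, enzyme-capacity
constraints — all materialize as ordinary stoichiometry before solving, so
every protocol is a sequence of plain FBA problems.

## The proton motive force

The electrochemical gradient across the inner membrane is a pseudo-metabolite
living in the pseudo-compartment: chain complexes produce it, consumers
consume it, and it must balance at steady state like any metabolite. The
split between the membrane-potential and pH components follows the measured
average contributions in yeast mitochondria (90% Δψ, 10% ΔpH):

- net charge q moved out of the matrix per unit flux → +0.9·q PMF
  (negative q, e.g. the ADP³⁻/ATP⁴⁻ exchange, therefore *consumes* 0.9);
- electroneutral proton-coupled carriers (phosphate, pyruvate) consume 0.1
  per proton entering the matrix;
- explicitly tagged proton pumps (complex III/IV) produce 1 PMF per
  translocated proton — the fixture pins 4 and 2 per electron pair;
- the ATP synthase consumes 3 PMF per ATP;
- a sink reaction dissipates PMF freely (proton leak), enabling P/O
  titration.

Classification is automatic from metabolite charges and compartments, with
two deliberate conventions. First, species located in the inner-membrane
compartment itself (the quinone pool) are reachable from both faces and do
not count as crossing; otherwise the non-pumping NADH dehydrogenases, whose
chemistry spans the matrix/cytosol and the membrane Q pool, would classify
as translocators. Second, compartmental proton pools are *buffered*: no
chemical H⁺ ever carries crossing energetics (that is the PMF's job), so the
toy network equilibrates H⁺ freely across the outer membrane and holds the
matrix pool with an explicit buffer reaction. The magnitude of the PMF in mV
and K⁺/Mg²⁺ cycling are out of scope.

With these stoichiometries, delivering one cytosolic ATP costs
3 + 0.9 + 0.1 = 4 PMF, the fixture's theoretical maximum P/O is 6/4 = 1.5,
and transport consumes (0.9+0.1)/4 = 25% of the gradient — analytic
properties the LP reproduces exactly. The P/O assay feeds ethanol (all
electrons enter as cytosolic NADH at the external dehydrogenase, leaving
ATP synthesis and ATP/Pi transport as the only PMF drains) and divides the
synthase flux by the summed flux through the tagged electron-pair entry
points.

## Protein import

Pathway assignment is rule-based: outer membrane → TOM only; intermembrane
space with twin-CX9C/CX3C motifs → MIA disulfide relay; inner-membrane
carriers → TIM22; soluble matrix proteins → TIM23 with the PAM motor;
inner-membrane presequence proteins → conservative sorting (matrix passage
plus OXA re-insertion) when any transmembrane segment contains a proline,
stop transfer otherwise. An IMS protein with neither motif nor presequence is
an explicit error rather than a silent guess.

Energetics per import event:

- **ATP** — ⌈L/25⌉ for matrix import (one mtHsp70 cycle per 25-residue
  binding interval; ceiling because the cycles are discrete, with a linear
  mode behind a flag), where L is the full length for matrix proteins and
  the summed transmembrane length for conservative sorting. Hydrolysis is
  booked on the matrix side (ATP → ADP + Pi).
- **PMF** — 0.9 per net positive charge (K+R − D−E, histidine and termini
  excluded, floored at zero) of the region crossing electrophoretically:
  the whole sequence for matrix proteins, the presequence alone for stop
  transfer, presequence plus TM segments for conservative sorting. The
  floor-at-zero reading reconciles "total charge" with "per positive
  charge"; both the region definition and the floor are configurable.

Import reactions consume the cytosolic protein species, produce the located
species, engage the pathway machinery as kcat-coupled enzymes, and release a
cleaved presequence peptide routed to a lumped, ATP-free degradation
reaction. Machinery complexes are lumped entities whose molecular weight is
the sum of their subunits. Curated translocation rates: TOM and OXA at the
translation rate (10 s⁻¹, reflecting co-translational import), TIM23+PAM at
9 aa·s⁻¹ divided by the median proteome length, other machines defaulting to
the translation rate; carriers imported via TIM22 use the average metabolic
turnover 70.9 s⁻¹ for their *metabolic* reactions. All rates are overridable
from a user table. Alternatively, machinery turnover is estimated from
absolute proteomics as kcat = μ·Σ[E_substrates]/[E_machinery], assuming
negligible degradation (each standing substrate pool is imported once per
doubling). Missing proteomics values are imputed from mRNA levels times the
mean protein/mRNA ratio of measured subunits of the same complex.

## Cofactors and Fe/S clusters

Fe/S biosynthesis is three stages, all mitochondrial (the cytosolic pathway
is collapsed into the matrix): (1) cysteine desulfurase sulfur mobilization
and [2Fe-2S] assembly on the scaffold with an NADPH-coupled two-electron
reduction (one NADPH per step — the electron-chain stoichiometry through the
ferredoxin system is not quantitatively characterized, so a lumped
NADPH-coupled step is used); (2) ATP-driven transfer to the glutaredoxin
carrier; (3) insertion into apo-targets, or condensation of exactly two
carrier-bound [2Fe-2S] clusters (plus one NADPH) into one [4Fe-4S]. Cluster
species carry real Fe/S formulas so the stages are elementally audited; only
the kcat values measured under physiological electron donors belong in the
machinery table, since rates obtained with chemical reductants overestimate
capacity.

Incorporation reactions (apo + n·cofactor → holo, for Fe/S, lipoate, biotin,
heme a, ferroheme b, siroheme) re-point catalysis at the holo species, so
any flux through a holo-enzyme's reaction forces cluster synthesis, iron
uptake (a Δψ-driven uniport costing 1.8 PMF per Fe²⁺ in the fixture) and
sulfur supply. Cofactor demand of proteins outside the model is a linear
abundance-weighted sum appended to the biomass reaction. Heme, lipoate and
biotin chemistry upstream of incorporation is consumed from boundary
supplies in the toy fixture; a genome-scale base model provides it natively.

## Enzyme constraints

Each catalyzed reaction consumes 1/kcat of its enzyme's species per unit
flux (complex subunits all engaged; isoenzymes as duplicated reactions with
independent usage variables; reversible catalyzed reactions split into
irreversible arms so each direction consumes capacity). A draw reaction per
enzyme is the usage variable; the pool constraint Σ MW·e ≤ σ·f·P_tot is a
pool pseudo-metabolite with a capped source (defaults σ=0.53, f=0.446,
P_tot=0.46 g/gDW → 0.1087 g/gDW). kcats are ingested in s⁻¹ and converted
to h⁻¹; missing values fall back to the median of supplied kcats, logged.

The growth-rate rescaling multiplies usage coefficients by μ, divides the
pool-draw coefficient by μ, and scales the maturation-chain (import,
incorporation) protein coefficients with μ. The last point makes the
transformation an exact change of units: the optimal flux distribution at
fixed μ is identical to the unscaled formulation (verified to 1e-6 on every
exchange flux), and import/cofactor costs are proportional to the standing
enzyme amount. A printed formulation that drops the flux term is resolved in
favor of this equivalence property. The LP is badly scaled (coefficients
span 1e-7 to 1e3), so solver feasibility/optimality tolerances are pinned at
1e-9; at GLPK's defaults the simplex returns visibly unbalanced solutions.

## Simulation protocols

- **Chemostat**: fix μ, open the carbon exchange on minimal medium, apply
  the μ-rescaling, minimize substrate uptake, fix it, then minimize the
  protein-pool source flux (total enzyme mass — the parsimonious step).
  Byproduct secretion (acetate, pyruvate) is capped at measured values when
  a dataset row is supplied (upper bounds, not equalities).
- **Batch μ_max**: binary search on μ over [0, 1] h⁻¹ to 1e-4 h⁻¹, testing
  feasibility with the unscaled formulation (equivalent at fixed μ), then
  minimize uptake and enzyme usage at the optimum. Ethanol growth opens the
  ethanol exchange and closes glucose.
- **GAEC fit**: the polymerization component is computed from the biomass
  composition (per-pool polymerization ATP × mass fraction); the residual
  component is a 1-D bounded search on the biomass ATP coefficient
  minimizing the summed squared *relative* error of glucose, O₂ and CO₂
  exchange fluxes across the dataset's dilution rates (the error metric is a
  design choice; none is prescribed).
- **σ fit**: 1-D bounded search on σ ∈ (0,1], evaluated on the dataset rows
  at and above the critical dilution rate (σ only binds there); boundary
  optima are returned with a warning.

A non-growth maintenance reaction (default 0.7 mmol ATP/gDW/h) is always
present and configurable.

## The toy fixture and what it does (not) show

The bundled network is a desk-scale surrogate, not a genome-scale
reconstruction: lumped, mass/charge-balanced pathways (glycolysis,
fermentation branches, PDH+TCA, anaplerosis, a two-step ethanol assimilation
route), a respiratory chain pinned at 6 PMF per NADH pair, a three-pool
biomass (0.46/0.40/0.08 g protein/carbohydrate/lipid per gDW with round
polymerization costs of 4/1/1 mmol ATP/g, total 2.32 mmol/gDW), a default
fitted GAEC of 18 mmol ATP/gDW, and ~40 curated proteins covering all six
import routes plus Fe/S, lipoate, biotin and heme-a enzymes. Fixture kcats
were calibrated once so that oxidative phosphorylation is protein-expensive
relative to fermentation under the default pool: the chemostat then shows
zero ethanol at low dilution rates, overflow onset near μ ≈ 0.33 h⁻¹, a
declining biomass yield thereafter, and a respiratory ethanol μ_max about
seven-fold below the glucose μ_max. Pyruvate export is transporter-coupled
so overflow carbon leaves as ethanol, as in Crabtree-positive physiology.

Synthetic data generators share this model: the proteome generator emits
records spanning all pathways with import PMF costs covering 0–10; the
proteomics generator sets machinery abundances to μ·Σsubstrates/kcat with
multiplicative lognormal noise of stated CV (machinery subunits are not
booked as their own substrates); the exchange-dataset generator runs the
chemostat protocol itself at stated GAEC/σ and perturbs the fluxes. Fits on
noise-free synthetic data therefore recover the generating parameters
exactly — this validates the estimation machinery, not the realism of the
toy network. Quantities that require a genome-scale reconstruction plus
external proteomics (operational P/O near 1, the ~60% GAEC reduction, the
27% transport fraction at μ=0.1, import-machinery allocation trajectories,
proteome correlations) are documented here but not asserted; the CLI can run
those analyses when a user supplies the inputs.

## Numerical choices and limitations

Bisection bracket [0,1] h⁻¹, tolerance 1e-4 (deterministic, no randomness);
LP feasibility 1e-9; GAEC search bounds [0,60] mmol/gDW, σ bounds
[0.05,1.0]; fractions in the PMF report sum to 1 within 1e-9 and production
equals consumption at steady state. Reversible transporters carry symmetric
PMF coefficients (consume when dissipating, produce when charging) — whether
real carriers operate bidirectionally under load is not modeled. Elemental
balance is checked for reactions whose non-pseudo metabolites all carry
formulas; charge balance only within a single compartment (transport
legitimately separates charge); reactions that move real atoms into pseudo
species (cofactor incorporation) are explicitly exempt. The PAM co-chaperone
stoichiometry is taken as 1:1 with an override. Gene expression and
translation machinery, kinetic PMF modeling, and thermodynamic feasibility
are out of scope.
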