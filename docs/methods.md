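# Methods

## Model

The core object is a linear program over steady-state fluxes `f_i`
(mM/min = mmol per litre of cell volume per minute) and compartment volume
fractions `φ_c` for extra-mitochondrial enzymes (EnM), mitochondrial
enzymes (EM), ribosomes (R) and mitochondria (M).  The objective minimises
the total nutrient import cost, with each import priced at the molecular
weight of the imported species (g/mmol) as a size proxy.  Constraints:

1. *Flux balance* for every metabolite.  Reversible reactions are split
   into forward/backward irreversible copies, each with its own effective
   turnover number, before assembly.
2. *Protein balance.*  Protein is an explicit pool: the protein-synthesis
   flux must equal `(μ + k_D)(P0 + P_E + P_R)` where
   `P_E = n_PE Σ f_i/k_eff,i` is protein tied up in enzyme complexes and
   `P_R = (n_PR/v_R) φ_R` is ribosomal protein.  These enter the LP as
   linear coefficients `(μ+k_D) n_PE/k_eff,i` on every enzymatic flux and
   `(μ+k_D) n_PR/v_R` on `φ_R`, with constant right-hand side
   `(μ+k_D) P0` — the autocatalytic core of the model.
3. *Crowding links.*  `φ_EnM` and `φ_EM` equal the summed enzyme volume
   demand (`a_i f_i`, `a_i = v_E/k_eff,i`) of their reaction classes;
   `φ_R ≥ a_R f_PS`; `φ_M ≥ a_M,ATP ×` (total mitochondrial ATP
   production).  The φ_M and φ_R links are inequalities so the solver may
   carry slack organelle volume; the enzyme links are equalities.
4. *Budget.*  `φ_EnM + φ_R + φ_M + φ_P0 ≤ φ_max`, with
   `φ_P0 = P0 ×` (molar volume of the median 40,835 g/mol protein at
   0.79 mL/g) ≈ 0.116 a constant term (flag `include_P0_volume`).  `φ_EM`
   is *excluded* from the budget by default: mitochondrial enzyme volume
   is assumed to live inside the mitochondrial volume that `a_M,ATP`
   already prices (flag `count_EM_separately` reverses this).
5. *Bounds.*  Maintenance is a lower bound (≈6.0 mM/min ATP hydrolysis),
   the proliferation reaction is pinned to μ (internally 1/min; one
   "cell" unit ≡ 1 mM of biomass-pool sets), everything else is
   `0 ≤ f < ∞`.

Solved with HiGHS (scipy.optimize.linprog) at feasibility/optimality
tolerances 1e-9.  Because split reversible pairs admit free
forward+backward cycles and the optimum can be degenerate, a secondary LP
minimises `Σ f_i + Σ φ_c` subject to the optimal import cost; reported
fluxes and φ are therefore reproducible and φ sit on their binding lower
limits.  Infeasibility is returned as a status, and `μ_max` is located by
doubling + bisection (default tolerance 0.01/day).

## Parameters (defaults, mM–min–L units)

| symbol | value | meaning |
|---|---|---|
| a_R | 3.6 min/mM | ribosome crowding coeff. = v_R / (0.67 proteins/min) |
| v_R | 2.4 L/mmol | ribosome molar volume (4,000 nm³ × Avogadro) |
| v_E | 0.078 L/mmol | enzyme molar volume (98,750 g/mol × 0.79 mL/g) |
| a_M,ATP | 0.017 min/mM | midpoint of 0.0026–0.0315 (mitochondrial specific volume / ATP output rate) |
| n_PE | 2.4 | protein subunits per enzyme complex (98,750/40,835) |
| n_PR | 82 | proteins per 80S ribosome |
| P0 | 3.59 mM | non-metabolic protein concentration |
| k_D | 0.01/h | basal protein turnover |
| φ_max | 0.40 | macromolecular volume-fraction budget |
| maintenance | 6.0 mM/min | 1.55 mmol ATP/gDW/h over 4.3 mL/g |
| k_eff range | 1–100 s⁻¹ | log10-uniform sampling band |

Note: re-deriving P0 from composition data (0.015 mmol/gDW ÷ 4.3 mL/g)
gives ≈3.49 mM; the independently reported 3.59 mM is kept as the default
and the derivation is exposed as `biophysics.derive_p0` rather than
silently reconciled.  "Midpoint" is used for the a_M range statistic; it
reproduces the quoted 0.017 exactly.

`a_M,ATP` multiplies *all* mitochondrial ATP production by default,
including substrate-level phosphorylation (succinyl-CoA synthetase lump,
mitochondrial FTHFL); `a_M_scope="atp_synthase"` restricts it to a named
reaction set.  This is a genuinely open modelling choice: the coefficient
is measured as ATP output per mitochondrial mass, which is an OxPhos
capacity, but the volume it prices hosts the whole matrix enzyme
complement.

## k_eff sampling

Turnover numbers are drawn i.i.d. per irreversible reaction direction,
`log10(k_eff [s⁻¹]) ~ U[0, 2]`; replicate r of an ensemble uses seed
`base_seed + r`, making every ensemble bit-reproducible from its manifest.
Quantiles are type-7 (linear interpolation).  Infeasible replicates are
recorded and excluded from quantiles; more than 10% of them is an error by
default (the full-scale drivers relax this, since high μ is infeasible for
unlucky draws by construction).  Fresh draws are taken at every
(μ, replicate) pair.

## Networks

The package ships no external reconstruction.  Two generated networks
cover all tests and drivers:

* **Toy overflow model** (~18 reactions): lumped upper/lower glycolysis,
  LDH, lumped respiration at 32 mol ATP/mol glucose (2 glycolytic +
  30 mitochondrial), maintenance, and a proliferation sink consuming
  10,000 ATP per cell-unit.  With OxPhos paying `a_M` per ATP and
  glycolysis only enzyme volume, the optimum is pure respiration until
  the budget binds at a closed-form μ* (`synthetic.toy_switch_mu`), after
  which lactate overflow grows linearly — the crowding-induced metabolic
  switch in its minimal form.  Raising a_M lowers μ*; raising φ_max
  raises it.
* **Curated core network** (~60 reactions, synthetic stand-in for a
  genome-scale human reconstruction): the ten glycolytic steps + LDH with
  BiGG-convention formulas and charges; PHGDH/PSAT/PSPH serine synthesis;
  SHMT/MTHFD/MTHFC/FTHFL cycles in both compartments; lumped glycine
  cleavage; glutaminase/glutamate dehydrogenase and a lumped
  α-ketoglutarate → pyruvate anaplerotic exit; pyruvate dehydrogenase +
  TCA lump; respiratory chain lumps both coupled to ATP synthase (P/O 2.5
  and 1.5) and uncoupled (proton leak), so redox disposal and ATP
  synthesis are separable as they are in vivo; nicotinamide
  transhydrogenase; alanine transaminase; protein synthesis from 14
  modelled amino acids (355 residues, 4.3 ATP/residue polymerization
  cost — a field-standard value, configurable) and lumped lipid/RNA/DNA
  pools.  Every non-pseudo reaction is elementally and charge balanced by
  exact rational arithmetic.
  The pyruvate-kinase step of the net-zero variant is written
  `PEP + H2O → Pyr + Pi`: the ATP-independent dephosphorylation cannot be
  balanced with a bare proton, so water is the co-substrate.

What the stand-in does *not* emulate: pathway redundancy and degree
distribution of a genome-scale reconstruction, compartment-specific
cofactor pools (NAD(H) and most metabolites are shared pools; only
folates are compartmentalised), amino-acid catabolism, the pentose
phosphate pathway, and Recon-1's auxiliary-reaction list.  Tests passing
on it show the mechanism — crowding-priced OxPhos being displaced by the
serine/one-carbon route at high μ — not genome-scale numerics.  The
full-scale driver reproduces the qualitative structure (respiration
dominates at low μ; mitochondrial density rises then falls; FTHFL becomes
a leading ATP source in the net-zero variant at high μ; ensemble-median
μ_max ≈ 2.5/day at n = 20) but the mitochondrial-density peak sits at a
higher μ than a genome-scale model yields, because the stand-in's
biosynthetic ATP demand per unit growth is smaller.

## Pathway accounting

ATP ledgers count gross production (positive ATP coefficient × flux),
sorted descending, with the maintenance flux as reference.  Tracebacks
walk breadth-first from a seed reaction through flux-carrying producers of
each non-currency substrate (the currency list —
ATP/ADP/AMP/Pi/PPi/NAD(P)(H)/FAD(H2)/H+/H2O/CO2/O2/NH4/CoA — is
configurable), stopping at caller-supplied metabolites.  Overall reactions
are exact `Fraction` sums; multipliers are obtained as the unique positive
integer nullspace vector of the intermediate-species stoichiometric
submatrix (sympy, exact rationals), so compositions fail loudly if the
cancellation is not unique.  The composed serine-route overall reaction
carries 4 formate and 10 H+ per glucose on the product side; published
summary tables of this pathway typically omit the formate bookkeeping, so
the package asserts the cofactor coefficients (ATP, NH4, αKG, NAD(P)H,
CO2) plus exact elemental/charge balance and simply reports H+/H2O/formate.

## One-carbon cycle kinetics

The cytosolic SHMT → MTHFD → MTHFC → FTHFL loop is an ODE model in mM/min
with reversible Michaelis–Menten (convenience) rate laws, constant serine
inflow (0.05 mM/min), first-order glycine and formate drains, and
chemostatted ATP/ADP/Pi/NADP(H) pools (3.0/0.3/2.5/0.002/0.02 mM).  Total
folate (30 μM) is conserved structurally.  Rate constants follow the
scale of published folate-cycle models; they are defaults, not fitted
values, and the model's claims are qualitative: a steady state exists
(integrate-then-polish, residual ≤ 1e-10 relative; the folate conservation
is eliminated before root-finding so the reduced Jacobian is regular), it
is reached from distant initial states, and it is asymptotically stable —
all Jacobian eigenvalues besides the structural conservation zero have
negative real part — with FTHFL running in the ATP-forming direction.

## Numerical choices and degenerate inputs

* LP tolerances 1e-9 (feasibility and relative optimality); the
  brute-force vertex-enumeration oracle (standard-form basis enumeration)
  certifies the solver on networks with ≤ ~12 structural variables.
* Stiff integration: LSODA, rtol 1e-10, atol 1e-12.
* Ties among amino-acid sources at low μ depend on the import-cost vector;
  no result depends on which is chosen.
* Orphan metabolites (no producer/consumer) are dropped from the balance
  rows; empty media, zero Vmax kinetics and zero-flux ledger inputs are
  handled as degenerate-but-valid inputs.

## Problem sizes

Default analysis sizes keep every run desk-scale: ensembles of 20–100
replicates, μ grids of ~10 points, and the ~60-reaction core network
(≈80 LP variables after splitting); a single LP solves in milliseconds,
a 20-replicate μ_max ensemble in about a second.

## Known limitations

* The crowding budget is linear and static; no thermodynamic (ΔG)
  constraints, dynamic FBA, or gene–protein–reaction rules.
* Import costs are a molecular-weight proxy; transporter kinetics are not
  modelled.
* The kinetic module covers the cytosolic loop only; glycine-cleavage
  kinetics and trifunctional-enzyme channeling are out of scope.
* Genome-scale quantitative claims require the genome-scale
  reconstruction; the curated stand-in reproduces mechanisms, not every
  reported number.
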