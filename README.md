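# crowdflux

Constraint-based modelling of why rapidly proliferating human cells —
tumour cells above all — run glycolysis far beyond their ATP needs, and of
an alternative route that turns that glycolytic overflow into ATP through
serine biosynthesis, cytosolic one-carbon metabolism and the mitochondrial
glycine cleavage system.

The package is aimed at systems-biology researchers who want to run,
probe or extend a flux balance model with a **molecular crowding**
constraint: enzymes, ribosomes and mitochondria compete for a finite share
of cell volume, so every flux "pays rent" in volume fraction, and the
cheapest metabolic strategy changes with the proliferation rate.

## The model

At a fixed proliferation rate μ, the model finds fluxes `f_i ≥ 0` (mM/min)
and compartment volume fractions `φ_c` (`c ∈ {EnM, EM, R, M}`) minimising
the nutrient import bill

    min  Σ_{i∈RI} c_i f_i          (c_i = molecular weight of the imported
                                    species, g/mmol)

subject to

* **flux balance** `Σ_i S_mi f_i = b_m` for every metabolite and
  macromolecule pool;
* a **self-consistent protein balance**: the protein-synthesis flux must
  cover growth dilution and basal turnover of all protein,

      f_PS = (μ + k_D) [ P0 + n_PE Σ_i f_i / k_eff,i + (n_PR / v_R) φ_R ],

  so enzymes and ribosomes are themselves products of metabolism;
* **crowding links**: `φ_EnM = Σ_{i∈RnM} a_i f_i` with `a_i = v_E/k_eff,i`,
  `φ_R ≥ a_R f_PS` (`a_R = v_R/k_R = 3.6 min/mM`), and
  `φ_M ≥ a_M,ATP ×` (mitochondrial ATP production) with
  `a_M,ATP = 0.017 min/mM`;
* the **volume budget** `φ_EnM + φ_R + φ_M (+ P0 term) ≤ φ_max = 0.40`.

Unknown effective turnover numbers `k_eff` are sampled log10-uniformly on
1–100 s⁻¹; ensembles of LP solutions are summarised by median and 90% CI.
A pyruvate-kinase variant switch models the ATP-neutral ("net-zero")
glycolysis observed in cells expressing dimeric PKM2.  Pathway-accounting
utilities rank ATP-producing reactions, trace flux backbones, and compose
exact overall reactions; a kinetic ODE model checks that the cytosolic
one-carbon cycle really can run formate–tetrahydrofolate ligase (FTHFL) in
the ATP-forming direction at a stable steady state.

Everything runs on self-contained networks: a hand-solvable overflow toy
model and a curated ~60-reaction core reconstruction of human central
metabolism (glycolysis, serine/one-carbon/glycine-cleavage route,
glutaminolysis, lumped TCA/OxPhos, biomass).

## Worked example

ATP ledger of the net-zero-glycolysis model at a high proliferation rate
(2.4/day), uniform k_eff = 10 s⁻¹:

```text
$ crowdflux ledger --mu 2.4 --glycolysis net_zero --top 5
reaction        atp_production_mM_per_min
PGK     9.04506974274582
FTHFL_rev       8.714403183916906
FTHFLm_rev      7.722403462730867
NADHOXm 4.865395948824518
FADH2OXm        1.1463107707980404
# maintenance reference: 6.0
```

FTHFL running in reverse (`FTHFL_rev` cytosolic, `FTHFLm_rev`
mitochondrial, together 16.4 mM/min) has overtaken coupled respiration
(`NADHOXm`, the ATP-synthase lump) as the cell's main ATP source; gross
phosphoglycerate-kinase output is nearly cancelled by the hexokinase and
phosphofructokinase investment upstream.  At `--mu 0.03` the same command
shows respiration supplying essentially all maintenance ATP.

The highest feasible proliferation rate of this network and the kinetic
feasibility check:

```text
$ crowdflux mumax --glycolysis net_zero
4.1797
$ crowdflux kinetics            # excerpt
"fluxes_mM_per_min": {"SHMT": 0.05, "MTHFD": 0.05, "MTHFC": 0.05,
                      "FTHFL": 0.05},
"stable": true
```

All four cycle enzymes carry the same steady flux (one unbranched loop)
with FTHFL in the ATP-forming direction, and every non-conservation
eigenvalue of the Jacobian has negative real part.

The exact pathway compositions:

```text
$ crowdflux compose
glycolysis: 2 adp + glc_D + 2 pi -> 2 atp + 2 h2o + 2 lac_L
novel pathway: 4 adp + glc_D + 2 glu_L + 4 h2o + 6 nad + 4 nadp + 4 pi ->
               2 akg + 4 atp + 2 co2 + 4 for + 10 h + 6 nadh + 4 nadph + 2 nh4
ATP/glucose: {'glycolysis': 2.0, 'novel_pathway': 4.0}
```

The serine route doubles the ATP yield of glucose relative to standard
glycolysis (4 vs 2 mol ATP/mol glucose).

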