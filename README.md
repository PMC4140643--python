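# bindscape

**Energy-landscape topography of flexible biomolecular recognition.**

Flexible recognition — binding coupled to folding, as in intrinsically
disordered proteins — tends to lower binding *affinity* yet raise binding
*specificity*, decoupling two quantities that rigid-docking intuition says
move together.  `bindscape` quantifies this through the **intrinsic energy
landscape**: the micro-canonical density of states n(E, Q) of a
coarse-grained (C-alpha, structure-based) homodimer, sampled by
replica-exchange Langevin dynamics and reconstructed by WHAM.  From the
landscape it computes

* the energy gap **δE** (slope toward the native state), roughness
  **ΔE** (bumpiness) and entropy **S** (size of the non-native search
  space),
* the glass-trapping temperature **Tg = ΔE/√(2S)** and binding/folding
  transition temperature **Tf** (heat-capacity peak), with the
  funnel-ness ratio Tf/Tg,
* the dimensionless **intrinsic specificity Λ = δE/(ΔE·√(2S))** — gap
  against roughness, modulated by entropy: larger Λ, more funneled
  landscape, more specific recognition,
* binding kinetics via the mean first-passage time (MFPT) to the bound
  state from dissociated starts (1/MFPT is the association rate, the
  *kinetic* specificity),
* and combined binding-folding landscapes: one interfacial-binding plus
  two monomeric-folding densities of states convolved into the
  weak-coupling prediction (δE adds, ΔE² adds in quadrature, S adds),
  compared against the directly sampled global landscape.

The same dimer can be sampled with fully **flexible** monomers or with
**rigid** (frozen) ones carrying identical interfacial interactions, which
isolates what flexibility does to the landscape: entropy up, roughness
down, gap unchanged, Λ up — higher specificity at lower affinity.

## Worked example

Quantify rigid vs flexible binding for a synthetic 20-residue-per-chain
homodimer with interfacial flexibility rho = 0.3 (every pipeline stage
also works on two-chain PDB files):

```python
import numpy as np
import bindscape as bs
from bindscape.pipeline import landscape_from_ensemble

toy = bs.make_toy_homodimer(bs.ToySpec(n_residues=24, n_inter=8,
                                       rho=0.25, seed=7))
structure, cmap = toy
ff = bs.ForceField(epsilon_inter=2.0)  # the 3-state homodimer regime
for mode, seed in (("rigid_chains", 11), ("flexible", 12)):
    top = bs.build_topology(structure, cmap, ff=ff, mode=mode,
                            restraint=bs.Restraint())
    ens = bs.run_remd(top, np.geomspace(0.3, 1.5, 11),
                      n_steps=300_000, exchange_interval=1000, seed=seed)
    dos, cv, topo = landscape_from_ensemble(
        ens, energy_key="e_inter", q_key="qb", n_contacts=cmap.n_inter,
        n_energy_bins=40)
    print(mode, topo)
```

Running `python analysis/02_binding_landscapes.py` (this comparison,
averaged over two replica-exchange seeds per mode) prints:

```
toy homodimer: 24 residues/chain, 8 interfacial + 70 folding contacts, rho = 0.25
    rigid: dE=  8.39  DE= 1.25  S=  6.89  Lambda= 1.82  Tb=0.979  (31 s)
 flexible: dE=  7.82  DE= 0.81  S= 11.13  Lambda= 2.05  Tb=0.683  (102 s)
```

Read: freezing the monomers shrinks the non-native search space
(S 11.13 → 6.89) and roughens the interfacial landscape
(ΔE 0.81 → 1.25) while the energy gap stays within ~7 % (identical
interfacial contacts); flexibility therefore *raises* the intrinsic
specificity (Λ 1.82 → 2.05) while *lowering* the binding transition
temperature, i.e. the affinity (Tb 0.979 → 0.683).  These are the
qualitative signatures reported for real homodimers, reproduced here on a
toy at desk scale.

The numbered scripts under `analysis/` run the full study: `01` validates
the closed-form topography measures against the published five-homodimer
reference tables, `02` the rigid-vs-flexible binding landscapes, `03` the
binding kinetics (MFPT ratio), `04` the combined-vs-global
binding-folding comparison across an interfacial-flexibility series.
Each writes its tables under `results/`.

There is also a CLI for file-based workflows:

```
bindscape --outdir out synth --residues 20 --inter 10 --rho 0.3 --seed 7
bindscape --outdir out remd out/toy_dimer.pdb --mode flexible \
          --n-temps 12 --t-min 0.25 --t-max 1.2 --seed 12
bindscape --outdir out topo out/dos_binding.tsv --label binding
```

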