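#!/usr/bin/env python
"""Combined vs directly sampled global binding-folding landscapes.

A series of toy homodimers shares one interface geometry and differs only
in interfacial flexibility rho (the fraction of interfacial residues that
also hold folding contacts).  For each toy, three independent landscapes
are sampled — rigid interfacial binding (identical across the series, so
computed once), isolated monomer folding, and the full coupled (global)
binding-folding landscape — and the weak-coupling combination (one
binding + two folding landscapes: gaps add, roughness in quadrature,
entropies add) is compared with the global landscape through the
intrinsic-specificity measure Lambda.  The global landscape is evaluated
on the composition strata (native = all three component basins native;
non-native = all three partial) so that the comparison is exact in the
weak-coupling limit.  The relative difference
(Lambda_glob - Lambda_comb)/Lambda_glob should be positive (the coupled
landscape is more funneled) and grow with rho.

Writes results/combined_vs_global.tsv.
"""

import sys
import time
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import bindscape as bs
from bindscape.combine import combine_topography, combined_global_gap
from bindscape.pipeline import add_global_strata, landscape_from_ensemble
from bindscape.synthetic import extract_monomer

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

RHO_SERIES = (0.0, 0.10, 0.15, 0.20)
N_RES, N_INTER = 20, 6


def make(rho):
    return bs.make_toy_homodimer(
        bs.ToySpec(n_residues=N_RES, n_inter=N_INTER, rho=rho, seed=7))


# rigid binding: same interfacial map for every rho -> computed once
toy0 = make(0.0)
top_r = bs.build_topology(toy0.structure, toy0.cmap, mode="rigid_chains",
                          restraint=bs.Restraint())
t0 = time.time()
ens_b = bs.run_remd(top_r, np.geomspace(0.25, 1.0, 10), 250_000, 1000,
                    seed=21)
_, _, topo_b = landscape_from_ensemble(
    ens_b, energy_key="e_inter", q_key="qb", n_contacts=toy0.cmap.n_inter,
    n_energy_bins=40, label="binding_rigid")
cap_b = float(np.median(ens_b.field("e_inter", 0.2)[-1]))
print(f"shared rigid binding landscape: dE={topo_b.delta_E:.2f} "
      f"DE={topo_b.Delta_E:.2f} S={topo_b.S:.2f} "
      f"Lambda={topo_b.Lambda:.3f} ({time.time() - t0:.0f} s)")

rows = ["rho\tLambda_binding\tLambda_folding\tLambda_combined"
        "\tLambda_global\trelative_gap"]
gaps = []
for rho in RHO_SERIES:
    t0 = time.time()
    toy = make(rho)
    st, cm = toy
    top_f = bs.build_topology(st, cm, mode="flexible",
                              restraint=bs.Restraint())
    mono, mmap = extract_monomer(st, cm)
    top_m = bs.build_topology(mono, mmap, mode="flexible")
    ens_m = bs.run_remd(top_m, np.geomspace(0.4, 1.6, 10), 250_000, 1000,
                        seed=22)
    _, _, topo_f = landscape_from_ensemble(
        ens_m, energy_key="e_contact_intra", q_key="qf1",
        n_contacts=mmap.n_intra, n_energy_bins=40, label="folding_isolated")
    cap_f = float(np.median(ens_m.field("e_contact_intra", 0.2)[-1]))
    lam_glob = []
    for gseed in (23, 37):  # average two seeds of the noisiest landscape
        ens_g = bs.run_remd(top_f, np.geomspace(0.25, 1.6, 12), 300_000,
                            1000, seed=gseed)
        add_global_strata(ens_g)
        _, _, topo_g = landscape_from_ensemble(
            ens_g, energy_key="e_contact", q_key="q_strata", n_contacts=2,
            n_energy_bins=40, energy_cap=cap_b + 2 * cap_f, label="global")
        lam_glob.append(topo_g.Lambda)
    comb = combine_topography(topo_b, topo_f)
    lg = float(np.mean(lam_glob))
    gap = combined_global_gap(comb.Lambda, lg)
    gaps.append(gap)
    rows.append(f"{rho}\t{topo_b.Lambda:.4f}\t{topo_f.Lambda:.4f}"
                f"\t{comb.Lambda:.4f}\t{lg:.4f}\t{gap:.4f}")
    print(f"rho={rho:.2f}: Lambda_comb={comb.Lambda:.3f} "
          f"Lambda_glob={lg:.3f} gap={gap:+.3f} ({time.time() - t0:.0f} s)")

rs = spearmanr(RHO_SERIES, gaps).statistic
print(f"\nSpearman rank correlation of the gap with rho: {rs:+.2f}")
print("positive gaps: the coupled global landscape is more funneled than "
      "the weak-coupling combination;")
print("an increasing trend means stronger binding-folding coupling "
      "degrades the factorized description.")
(OUT / "combined_vs_global.tsv").write_text("\n".join(rows) + "\n")
print(f"wrote {OUT / 'combined_vs_global.tsv'}")
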