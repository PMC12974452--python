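# hydroshell

Tools for asking how a protein's hydration shell responds to solution pH.
Given atomic models of the same assembly solved under several pH conditions,
MD-style trajectories of water around the protein, and λ-coordinate traces
from constant-pH simulations, `hydroshell` answers four questions that come
up when studying pH-driven (de)solvation of a macromolecule such as the
apoferritin 24-mer:

1. **Which water sites are conserved across conditions?** Water oxygens from
   superposed models are clustered by single-linkage agglomeration at a
   1.0 Å cutoff. A site seen in one condition is *lone*, in ≥2 conditions
   *persistent*, and in all conditions *most persistent*. Sites are annotated
   with the nearest residue (3.6 Å cutoff) and the categories compared via
   their nearest water–water distance distributions with exact two-sample
   Kolmogorov–Smirnov statistics, D = sup|F̂₁ − F̂₂|.
2. **Where does trajectory water density concentrate?** Water oxygens in
   aligned 1-ns sampling windows are voxelized on a 0.5 Å grid within 5 Å of
   the protein as mass density ρ = 18.015 u · ⟨count⟩ / V_voxel (kg/L),
   smoothed with a 7-point face-neighbor stencil; local maxima with
   ρ ≥ 6 kg/L are hydration sites, with sub-Å peaks merged (ε = 1 Å,
   min-samples 1) and residues assigned by per-frame closest-heavy-atom vote.
3. **How long do waters stay bound?** The continuous survival probability
   S(t) of waters inside a 3.6 Å shell around a residue is averaged over time
   origins and integrated (trapezoid) to the residence time
   τ = ∫ S(t) dt, per window and averaged over windows.
4. **When do titratable residues deprotonate?** λ samples below 0.2 count as
   protonated, above 0.8 as deprotonated; the fraction
   S_deprot = n_deprot/(n_prot + n_deprot) per pH is fitted with
   S(pH) = 1/(1 + 10^(n·(pKa − pH))) to estimate pKa and Hill n.

Supporting operations cover PDB/mmCIF I/O, symmetry-aware solvent chain
assignment (occupancy 0.5/0.33/0.25 on two-/three-/fourfold axes),
asymmetric-unit extraction, Kabsch superposition, per-residue bound-water
tables, Shrake–Rupley accessible surface area, desolvation-trend regression,
and ion-to-center geometry for channel metals. A seeded synthetic-data
generator plants ground truth for every stage, so the whole pipeline is
testable without downloads.

## Worked example

```bash
python examples/residence_times.py
```

```
per-window residence times (ps): [7.3, 10.7, 11.5, 8.5, 10.6, 9.7, 6.5, 11.5, 9.8, 9.4]
tau = 9.54 ± 0.53 ps (planted 10 ps)
τ is the integral of the continuous survival probability S(t): how long a
water stays in the 3.6 Å shell without leaving.
```

The script plants a single bound-water site next to a glutamate with a 10-ps
mean lifetime, cuts ten 1-ns windows from a 10-ns toy trajectory, and
integrates each window's survival curve: the per-window spread gives the
standard error, and the mean recovers the planted lifetime. The other
examples each exercise one capability the same way — `conserved_waters.py`
(persistence classes across five pH conditions), `desolvation_trend.py`
(waters released per pH unit with OLS slope and r), `hydration_sites.py`
(12 planted density peaks recovered over a 1 kg/L bulk), `titration_pka.py`
(pKa 4.5 and 8.9 recovered from λ traces), and `surface_hydration.py`
(bound-water counts vs accessible surface area).

A thin CLI wraps the pipelines for shell use:

```bash
hydroshell synth ensemble --seed 1 --out demo/
hydroshell run structure -m pH3.5=demo/pH3.5.pdb -m pH4=demo/pH4.pdb \
    -m pH5=demo/pH5.pdb -m pH7=demo/pH7.pdb -m pH9=demo/pH9.pdb --out report/
```

Each run writes a TSV/JSON report bundle plus a manifest with the config
snapshot and input/output checksums.

## Layout

- `src/hydroshell/` — the library: `core` (models, I/O, superposition),
  `persistence`, `hydration`, `residence`, `residue_stats`, `metals`,
  `titration`, `trajectory`, `synth`, `pipeline`, `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and limitations.
- `tests/` — pytest suite with independent oracles for every operation.
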