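# gelswap

Structural and solution-state analysis of 3D domain-swapped protein dimers,
built around the gelsolin G2 **Gly167Arg** case — the amyloidosis-associated
variant whose second domain dimerizes by exchanging its N-terminal β1 strand
between subunits.

The package is for structural biologists and biophysicists who need to

* **detect and quantify domain swapping** in a two-chain coordinate file:
  which terminal segment is exchanged, where the hinge loop lies, and
  whether any inter-chain contact falls outside the open-monomer
  (*O*-)interface of the Eisenberg classification;
* **measure the interface**: per-subunit buried interaction area by the
  open-minus-closed SASA subtraction, total interaction surface as ΔSASA on
  complexation, and the intermolecular H-bond / salt-bridge inventory;
* **compare conformations**: masked Cα Kabsch superposition, backbone φ/ψ
  with Ramachandran classification (including the positive-φ region only
  glycine tolerates), metal-coordination spheres, and per-frame r.m.s.d.
  series over multi-model files;
* **analyze the monomer ⇌ dimer transition in solution**: gel-filtration
  peak quantification, the linear DLS calibration between the monomer
  (R_H = 2.0 nm) and dimer (3.0 nm) radii, pseudo-first-order kinetics
  f(t) = f∞ − (f∞ − f₀)e^(−kt), the mass-action 2M ⇌ D equilibrium
  (K_d = [M]²/[D]), and melting temperatures as first-derivative maxima of
  thermal-denaturation traces.

Every analysis stage has a synthetic-data generator with recorded ground
truth, so the entire pipeline is testable offline.

## Worked example

Generate a toy swapped dimer with known ground truth (8-residue exchanged
segment, 4-residue hinge) and characterize it:

```bash
gelswap --quiet simulate swap --out-prefix demo --seed 3
gelswap --quiet swap-report demo.pdb
```

```json
{
  "interface": {
    "n_c_interface_contacts": 0,
    "n_intermolecular_hbonds": 0,
    "n_o_interface_contacts": 16,
    "n_salt_bridges": 0
  },
  "is_swapped": true,
  "per_chain": {
    "A": {
      "buried_interaction_area_A2": 298.1,
      "hinge": [9, 12],
      "n_hinge": 4,
      "n_swapped": 8,
      "swapped_segment": [1, 8],
      "total_interaction_surface_A2": 299.9
    }
  }
}
```

(chain B omitted for brevity). Both chains donate residues 1–8 to the
partner core — matching the generator's ground truth — the hinge is 9–12,
and every inter-chain contact involves a swapped segment or hinge, so the
C-interface count is zero: the signature of a genuine domain swap. The
buried and complexation areas are small because the toy is a minimal
three-atom-per-residue backbone.

Fit a noisy DLS time course generated at a dimerization rate of 2.1 h⁻¹:

```bash
gelswap --quiet simulate dls --out-prefix dlsdemo --seed 5 --k 2.1 --noise 0.05
gelswap --quiet kinetics-fit dlsdemo.csv
```

```json
{
  "fit": {
    "f0": 3.1e-16,
    "f_inf": 0.512,
    "k_per_h": 1.823,
    "k_se": 0.393,
    ...
  }
}
```

A single 12-point series at this noise level recovers k = 1.8 ± 0.4 h⁻¹ —
the generating value lies within one standard error; averaging replicates
(as `scripts/acceptance.py` does) converges on the true rate. A melt trace
generated at T_m = 45.6 °C with 1% noise comes back as `"tm_c": [45.53]`
via `gelswap melt-fit`.

On the real structures (network available), `gelswap swap-report 5o2z.pdb
--reference 1kcq.pdb` reports the swapped strand 158–166, hinge 167–171,
and the interface areas and H-bond inventory for the deposited dimer.

## Layout

| module | contents |
| --- | --- |
| `gelswap.structure` | coordinate model, PDB/mmCIF I/O, selections, sequence mass |
| `gelswap.swap` | contact maps, swap detection, O/C-interface classification, monomer reconstruction |
| `gelswap.interfaces` | Shrake–Rupley SASA, buried/complexation areas, H-bonds and salt bridges |
| `gelswap.conformation` | Kabsch superposition, φ/ψ + Ramachandran, metal coordination, trajectory r.m.s.d. |
| `gelswap.kinetics` | peak integration, DLS calibration, first-order kinetics, mass-action K_d |
| `gelswap.melt` | T_m extraction, two-state and biphasic melt generators |
| `gelswap.synthetic` | toy swapped assemblies, chromatogram and DLS generators with ground truth |
| `gelswap.reports` / `gelswap.cli` | report bundles, provenance, `gelswap` subcommands |

See `docs/methods.md` for the models, conventions and numerical choices.
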