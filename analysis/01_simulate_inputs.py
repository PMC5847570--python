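#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Builds the toy trimer:monomer complex (full system sizes: 3 x 152
residue trimer, 267-residue two-domain monomer), its 3:3 and 3:2
scattering curves, a SEC-SAXS frame series with the two complexes
co-eluting, triplicate HDX uptake tables for both partners with the
interface segments protected, a one-site ITC titration at the reported
fitted values, and a tight-binding inhibition series.  Everything lands
under scratch/inputs/ in the external file formats.
"""

import json
from pathlib import Path

import numpy as np

from dutstl import io, saxs, synth
from dutstl.io import StructureModel

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

print("== building toy complex (3x152 trimer + 3x267 monomer) ==")
truth, trimer, monomer = synth.make_toy_complex(synth.ToyComplexSpec(seed=SEED))
io.write_structure(OUT / "trimer.pdb", trimer)
io.write_structure(OUT / "monomer.pdb", monomer)
io.write_structure(OUT / "complex33_truth.pdb", truth.realize())
truth32 = StructureModel.concatenate([truth.core] + truth.copy_models()[:2])
io.write_structure(OUT / "complex32_truth.pdb", truth32)

s = synth.default_s_grid(n=120, s_max=0.30)
c33 = saxs.debye_curve(truth.realize(), s)
c32 = saxs.debye_curve(truth32, s)
print(f"ground-truth Rg: 3:3 {saxs.guinier_fit(c33).rg:.1f} A, "
      f"3:2 {saxs.guinier_fit(c32).rg:.1f} A")

io.write_scattering_dat(OUT / "region1.dat",
                        synth.simulate_saxs(truth, s, noise=(0.01, 0.5), seed=SEED))
io.write_scattering_dat(OUT / "region2.dat",
                        synth.simulate_saxs(truth32, s, noise=(0.01, 0.5), seed=SEED + 1))

print("== SEC-SAXS run: 3:3 leading edge + 3:2 main peak ==")
frames = synth.simulate_sec_saxs_run([c33, c32], [20.0, 34.0], [3.0, 4.0],
                                     [0.6, 1.0], n_frames=60, buffer_level=50.0,
                                     noise=(0.05, 0.5), seed=SEED)
run_dir = OUT / "secsaxs"
run_dir.mkdir(exist_ok=True)
for k, fr in enumerate(frames):
    io.write_scattering_dat(run_dir / f"frame{k:04d}.dat", fr)

print("== HDX experiments (protection on the interface segments) ==")
tspec = synth.HdxSimSpec(protein="enzyme", length=152)
free, bound, _ = synth.simulate_hdx_experiment(tspec, [(34, 50), (89, 110)],
                                               seed=SEED)
io.write_peptide_uptake_table(OUT / "enzyme_free.csv", free)
io.write_peptide_uptake_table(OUT / "enzyme_bound.csv", bound)
mspec = synth.HdxSimSpec(protein="inhibitor", length=267)
mfree, mbound, _ = synth.simulate_hdx_experiment(mspec, [(98, 113)], seed=SEED + 1)
io.write_peptide_uptake_table(OUT / "inhibitor_free.csv", mfree)
io.write_peptide_uptake_table(OUT / "inhibitor_bound.csv", mbound)

print("== ITC titration and inhibition assay at the published fits ==")
io.write_itc_table(OUT / "itc.csv", synth.simulate_itc_titration(seed=SEED))
conc, v = synth.simulate_inhibition_assay(seed=SEED)
(OUT / "inhibition.csv").write_text(
    "i_conc_m,v_over_v0\n"
    + "\n".join(f"{c:.6g},{x:.6g}" for c, x in zip(conc, v)) + "\n")

manifest = {"seed": SEED,
            "interfaces": {"enzyme": [[34, 50], [89, 110]],
                           "inhibitor": [[98, 113]]},
            "itc": {"n": 1.27, "kd_um": 0.23, "dh_cal_mol": -8000.0},
            "inhibition": {"ki_nm": 6.7, "amplitude": 0.70, "e_nm": 50.0}}
(OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
print(f"wrote input bundle to {OUT}")
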