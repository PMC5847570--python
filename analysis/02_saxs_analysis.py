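#!/usr/bin/env python
"""Primary SAXS analysis of the synthetic curves.

Reproduces the benchmark-table workflow on the generated data: Guinier
Rg/I(0), P(r) inversion (real-space Rg, Dmax), Porod volume and the
molecular-mass estimators, then splits the SEC-SAXS frame series into
its two self-consistent regions and verifies the leading region is the
larger (3:3) species.  Writes results/saxs_report.json.
"""

import json
from pathlib import Path

from dutstl import io, saxs

BASE = Path(__file__).resolve().parent.parent / "results"
INP = BASE.parent / "scratch" / "inputs"

report = {}
for label, dmax in (("region1", 180.0), ("region2", 160.0)):
    curve = io.read_scattering_dat(INP / f"{label}.dat")
    g = saxs.guinier_fit(curve)
    pr = saxs.invert_pr(curve, dmax)
    vp = saxs.porod_volume(curve, pr.i0_real)
    est = saxs.mm_estimates(vp=vp)
    report[label] = {
        "rg_guinier_A": round(g.rg, 2), "rg_real_A": round(pr.rg_real, 2),
        "i0_guinier": g.i0, "dmax_A": dmax, "ift_chi2": round(pr.chi2, 3),
        "porod_volume_A3": round(vp), "mm_from_vp_da": round(est.mm_from_vp),
    }
    print(f"{label}: Rg(Guinier) {g.rg:.1f} A, Rg(real) {pr.rg_real:.1f} A, "
          f"Vp {vp:.0f} A^3, IFT chi2 {pr.chi2:.2f}")

print("== SEC-SAXS frame pooling ==")
frames = [io.read_scattering_dat(p)
          for p in sorted((INP / "secsaxs").glob("frame*.dat"))]
# at this signal-to-noise the default frame-similarity threshold also
# resolves the concentration gradient inside the main peak; 3.0 pools
# each species into one region
regions = saxs.select_secsaxs_regions(frames, [(0, 9), (52, 59)],
                                      similarity_chi2=3.0)
report["secsaxs"] = []
for label, idxs, avg in regions:
    g = saxs.guinier_fit(avg)
    report["secsaxs"].append({"label": label, "first": idxs[0],
                              "last": idxs[-1], "rg_A": round(g.rg, 2)})
    print(f"{label}: frames {idxs[0]}-{idxs[-1]}, pooled Rg {g.rg:.1f} A")
assert len(regions) == 2, "expected two co-eluting regions"
lead, main = (r["rg_A"] for r in report["secsaxs"])
print(f"leading-edge Rg {lead} > main-peak Rg {main}: {lead > main} "
      "(3:3 elutes ahead of 3:2)")

(BASE / "saxs_report.json").write_text(json.dumps(report, indent=1))
print(f"wrote {BASE / 'saxs_report.json'}")
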