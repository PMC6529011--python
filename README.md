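# vasomorph

Quantitative histomorphometry of intra-organ arterial trees, and numerical
classification of hypertensive arterial remodeling.

## The problem

Terminal arteries (ED ≈ 10–50 μm) are the main site of peripheral-resistance
regulation, and hypertension reshapes their walls. On routine histological
sections each artery appears as an annulus measured by two calibrated
lengths — external diameter (ED) and internal (lumen) diameter (ID) — from
which everything else derives:

    WTh  = (ED − ID)/2          wall thickness
    WLR  = WTh/ID               wall-to-lumen ratio (reported in %)
    MCSA = π(ED² − ID²)/4       media cross-sectional area
    LCSA = π·ID²/4              lumen cross-sectional area

Averaging these over a whole bed is statistically hollow (dimensions are
non-Gaussian with CVs of 40–70%) and, worse, averaged arrows cannot identify
*how* a bed remodeled: treating arteries as thick-walled cylinders whose ED
and ID move independently, exactly **19 distinct remodeling conformations**
(direction 5-tuples over ED, ID, WTh, MCSA, WLR) are geometrically
realizable and catalogued — 8 with ED increased, 2 with ED constant, 9 with
ED decreased — and every scalar index in common use (WLR direction, MCSA
direction, the remodeling index RI and growth index GI) takes the same value
on many of them.

vasomorph implements the replacement workflow:

1. **filter** to the 10–50 μm window and near-circular sections
   (long/short axis < 1.50);
2. **bin** into 5 μm ED intervals, with per-interval statistics and
   normality diagnostics, and build ordered **complex profiles** that retain
   the caliber-frequency structure;
3. **fit** the tapering regressions `ID = a·ED + b` and `WTh = c·ED + d` on
   interval means, with ROUT outlier removal and an exponential alternative;
4. derive **hemodynamic indices** — Poiseuille relative resistance
   `RR = 1/(π r⁴)`, its terminal aggregate TRR over ED 10–20 μm, and the
   terminal capacity/media volume from frequency-weighted areas or
   truncated-cone caliber limits;
5. **classify remodeling**: direction signatures against the 19-variant
   catalogue, and **3D line-congruence** — each variant spans a
   transformation surface from the control tapering line in (ED, ID, WTh)
   space (deviations limited to +300% widening/thickening and −99%
   narrowing/thinning), and a hypertensive line is congruent with a variant
   when it lies along one member line of that family over its whole length.

A seeded synthetic-bed generator (truncated-exponential caliber law, linear
taper, ~2 μm micrometer rounding, an outlier subpopulation, forward
application of any variant) makes every stage testable without animal data.

## Worked example

```python
from vasomorph.synthio import SyntheticSpec, generate_bed, fit_bed, apply_variant
from vasomorph.hemodynamics import hemo_summary
from vasomorph.variants import signature_from_fits, classify_signature
from vasomorph.congruence3d import test_congruence

ctrl_bed = generate_bed(SyntheticSpec(n=300, seed=41, organ="brain"))
ctrl, intervals = fit_bed(ctrl_bed, ed_range=(10, 50))
print(ctrl.id_fit.equation("ID", "ED"), ctrl.r2_id)

remo_bed = apply_variant(ctrl_bed, 9, 0.3, control_fit=ctrl)   # forward model
remo, _ = fit_bed(remo_bed)
sig = signature_from_fits(ctrl, remo, ref_ed=30.0)
print(sig.arrows(), classify_signature(sig))
print(test_congruence(ctrl, remo).congruent)
```

prints

```
control: ID = 0.4452·ED + 1.0768  r2 = 0.999
         WTh = 0.2774·ED - 0.5384  r2 = 0.999
TRR = 1.879e-03 um^-4   TC(cone) = 29495   TMV = 100357
remodeled: ID = 0.3130·ED + 0.7570  r2 = 0.999
signature: =↓↑↑↑ -> numerical class 9
congruent variants: [9]  best t = 0.3
```

Reading the output: the control bed tapers with lumen slope 0.445 (r² ≈ 1
on 5 μm interval means); its terminal relative resistance is 1.9×10⁻³ μm⁻⁴.
After forward remodeling by variant #9 (caliber fixed, lumen encroached,
wall thickened — the classic hypertensive pattern), the detected direction
signature is (ED =, ID ↓, WTh ↑, MCSA ↑, WLR ↑), which the catalogue numbers
9, and the 3D congruence test finds the hypertensive line congruent with
variant #9's transformation surface and no other.

The same pipeline runs from a shell:

```bash
vasomorph simulate --out beds.csv --n 300 --variant 9 --t 0.3 --seed 41
vasomorph run --input beds.csv --out results/
vasomorph classify "=↓↑↑↑"
```

## Module map

| module | contents |
| --- | --- |
| `vasomorph.geometry` | annulus metrics, measurement validation, protocol filters |
| `vasomorph.profiles` | 5 μm interval binning, complex profiles, normality diagnostics |
| `vasomorph.regression` | taper fits, ROUT outlier removal, ANCOVA line comparison, exponential alternative |
| `vasomorph.hemodynamics` | RR curves, TRR, terminal capacity and media volume |
| `vasomorph.variants` | 19-variant catalogue, feasibility oracle, signature classification, RI/GI critique |
| `vasomorph.congruence3d` | variant transformation surfaces, 3D line congruence, 2D shift tables |
| `vasomorph.synthio` | seeded synthetic beds and forward remodeling |
| `vasomorph.cli` | `vasomorph` console script and `run_pipeline` |

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
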