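# coroflow

Reduced-order, steady-state coronary hemodynamics on centerline anatomy:
non-invasive **fractional flow reserve (FFR)** simulation with
patient-specific resistance outlet boundary conditions, **virtual stent
deployment**, and the full **agreement / diagnostic-accuracy statistics**
used to validate simulated FFR against the invasive reference.

## Who this is for

FFR — the ratio Pd/Pa of distal coronary to aortic pressure under maximal
(adenosine) hyperemia — is the gold standard for deciding whether a coronary
stenosis causes ischemia (FFR ≤ 0.80). Computing it from imaging instead of
a pressure wire, and predicting its value *after* a hypothetical stent, is
the basis of virtual PCI planning. `coroflow` is aimed at researchers who
need a transparent, fast, fully scriptable model of that workflow: method
developers, students of coronary physiology, and anyone who needs a
well-tested synthetic test bed for FFR validation statistics.

## The model

Coronary trees are represented as rooted collections of branches, each an
ordered centerline with lumen radius samples `(s, r)` (circular
cross-sections). The steady pressure drop along a vessel carrying flow Q
combines a Poiseuille term integrated over the radius profile with
Borda–Carnot (Bernoulli) expansion losses at lumen expansions:

    ΔP = ∫ 8μ / (π r(s)⁴) · Q ds  +  Σ (ρ/2) Q² (1/A_min − 1/A_down)²

Boundary conditions follow standard coronary physiology:

* inlet static pressure `P_in = MBP − 6.8 mmHg`, with
  `MBP = DBP + (SBP − DBP)/3` (the offset models the systemic effect of
  adenosine);
* resting total coronary flow from left-ventricular mass by allometric
  scaling, `Q_rest = c · m^0.75` (default c = 2.6 mL·min⁻¹·g⁻³/⁴);
* hyperemia as microvascular resistance falling to **0.21×** its resting
  value, i.e. a target inflow `Q_hyp = Q_rest / 0.21`;
* per-outlet lumped resistances `R_i` to a shared venous reference `P0`,
  apportioned by Murray's law (`d³`) over outlet diameters and rescaled
  uniformly, with under-relaxation, until total outflow matches `Q_hyp`.

Virtual stenting clips the diseased span `[P*, D*]`, lays circular sections
of the stent diameter every 3 mm, and blends them with the adjacent lumen by
cubic B-spline interpolation. Stents can also be auto-sized from the
lumen-area curve A(s): the throat S is the area minimum, the landing points
P and D are the points of maximal |change of slope| of A on either side, the
stent length is D − P and its diameter the mean lumen diameter at P and D.

Because clinical CT geometries behind FFR studies are rarely released, the
package ships a seeded synthetic-anatomy generator (Murray-law trees,
cosine-shaped stenoses, pseudo-invasive FFR with configurable bias and
noise) that serves as the test bed for everything above.

## Worked example

```bash
coroflow generate --out tree.json --seed 7 --stenosis-severity 70
# wrote tree.json (11 branches, 6 outlets, 70%DS lesion on v1)

coroflow simulate tree.json --sbp 127 --dbp 74 --lv-mass 114 \
    --site v1:19.6 --auto-stent v1
```

The report (abridged) reads:

```json
{
 "inlet_pressure_mmHg": 84.87,
 "hyperemic_inflow_mL_min": 431.6,
 "pre":  {"sites": [{"branch_id": "v1", "s": 19.6, "ffr": 0.784, "ischemic": true}]},
 "stents": [{"branch_id": "v1", "s_proximal": 1.01, "s_distal": 19.12,
             "length": 18.11, "diameter": 2.82}],
 "post": {"sites": [{"branch_id": "v1", "s": 19.6, "ffr": 0.966, "ischemic": false}]}
}
```

Reading: at 127/74 mmHg the hyperemic inlet pressure is MBP − 6.8 =
84.87 mmHg and the calibrated hyperemic inflow 431.6 mL/min
(= 2.6·114^0.75 / 0.21). The 70 %DS lesion drops distal FFR to 0.784 —
below the 0.80 ischemia threshold. The auto-sizer brackets the lesion
(18.1 mm, 2.8 mm stent); after virtual deployment the simulated FFR
recovers to 0.966: no residual ischemia.

The same machinery runs whole validation cohorts:

```bash
coroflow cohort --n 25 --seed 0 --bias 0.024 --noise-sd 0.066 --out cohort_run
```

which writes the synthetic cohort, an agreement report (Pearson r,
Bland–Altman bias and 95% limits of agreement, sensitivity / specificity /
PPV / NPV / accuracy at the 0.80 threshold) and publication-style plots.

## Layout

| module | contents |
| --- | --- |
| `coroflow.tree` | centerline tree model, JSON/CSV dialects, VTK export |
| `coroflow.synthetic` | Murray-law tree generator, stenoses, validation cohorts |
| `coroflow.physiology` | patient record, MBP, allometric flow, outlet BCs |
| `coroflow.solver` | 1-D loss model, network solve, flow calibration |
| `coroflow.stenting` | stent deployment, auto-sizing, lesion classification |
| `coroflow.assessment` | FFR readout, ischemia threshold, %DS measurement |
| `coroflow.stats` | Pearson, Bland–Altman, diagnostics, ICC/COV |
| `coroflow.pipeline` / `coroflow.cli` | case & cohort orchestration, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
numerical choices, and known limitations.
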