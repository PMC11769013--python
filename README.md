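# cardiobox

A percentile-based 9-box reference grid for canine echocardiography.

Interpreting a dog's echocardiogram means comparing seven linear cardiac
dimensions — left atrial diameter in diastole (AID) and the M-mode pairs
IVSd/IVSs, LVIDd/LVIDs and PLVWd/PLVWs — against weight-dependent reference
tables. This package implements a graphical alternative: each dimension is
first made weight-independent by allometric scaling,

```
normalised value = value (cm) / weight (kg) ** b
```

with a fitted exponent *b* per parameter, and then placed in one of nine
contiguous value intervals ("boxes") whose limits come from reference
percentiles:

* **boxes 4–6 (normal, grey)** split the healthy population's
  [P1, P99] interval into three equal-width boxes;
* **boxes 1–3 (below normal)** split [total minimum, healthy P1] into three
  equal-width boxes, where "total" pools healthy and cardiac animals so the
  grid absorbs the full range seen in practice;
* **boxes 7–9 (above normal)** cover [healthy P99, total maximum]; by
  default the box-8/9 boundary is the total population's P99 and the
  box-7/8 boundary is the midpoint of the healthy and total P99
  (`Strategy.TABLE_CONSISTENT`, the rule the published limit grid actually
  follows); an equal-thirds alternative (`Strategy.PROSE_EQUAL_THIRDS`) is
  also provided.

A clinician then reads one marker per parameter on a 7×9 grid instead of
fourteen numbers against a table. The package ships the reference
percentile grid derived from 802 healthy and 2967 total dogs under 20 kg,
builds box limits from it (or from your own reference population), classifies
patients, renders SVG/text charts, and can simulate reference populations
whose quantiles match the shipped grid for testing and calibration.

The allometric exponents themselves are configuration: they are fitted
constants from the veterinary literature and are deliberately not bundled.

## Worked example

```python
import cardiobox as cb

ref = cb.load_packaged_reference()          # 802 healthy / 2967 total dogs
limits = cb.build_all(ref)                  # TABLE_CONSISTENT strategy

lim = limits[cb.Parameter.LVIDD]
print("LVIDDn boundaries:", " ".join(f"{b:.3f}" for b in lim.boundaries))

profile = cb.NormalizedProfile("rex", {
    cb.Parameter.AID: 0.94, cb.Parameter.IVSD: 0.41, cb.Parameter.LVIDD: 1.83,
    cb.Parameter.PLVWD: 0.40, cb.Parameter.IVSS: 0.58, cb.Parameter.LVIDS: 1.14,
    cb.Parameter.PLVWS: 0.62,
})
boxed = cb.classify_profile(profile, limits)
for a in boxed.assignments:
    print(f"{a.parameter.normalized_name:>7}  value={a.value:.2f}  box={a.box}  {a.zone.value}")
print(cb.render_text(boxed))
```

prints

```
LVIDDn boundaries: 0.680 0.827 0.973 1.120 1.310 1.500 1.690 2.075 2.460 3.040
   AIDn  value=0.94  box=6  NORMAL
 IVSSDn  value=0.41  box=5  NORMAL
 LVIDDn  value=1.83  box=7  ABOVE_NORMAL
 PLVWDn  value=0.40  box=5  NORMAL
  IVSSn  value=0.58  box=5  NORMAL
 LVIDSn  value=1.14  box=7  ABOVE_NORMAL
 PLVWSn  value=0.62  box=5  NORMAL
        1  2  3 { 4  5  6 } 7  8  9 
  AIDn [ ][ ][ ]{[ ][ ][*]}[ ][ ][ ]
IVSSDn [ ][ ][ ]{[ ][*][ ]}[ ][ ][ ]
LVIDDn [ ][ ][ ]{[ ][ ][ ]}[*][ ][ ]
PLVWDn [ ][ ][ ]{[ ][*][ ]}[ ][ ][ ]
 IVSSn [ ][ ][ ]{[ ][*][ ]}[ ][ ][ ]
LVIDSn [ ][ ][ ]{[ ][ ][ ]}[*][ ][ ]
PLVWSn [ ][ ][ ]{[ ][*][ ]}[ ][ ][ ]
```

The ten LVIDDn boundaries are the continuous box edges (b0..b9); the
ventricle is mildly dilated in both diastole and systole (box 7, just above
the normal range) while walls and atrium are normal. `cb.render_svg`
produces the same chart as an SVG document with the grey normal zone and
one marker per row.

The same pipeline is available from the shell:

```
cardiobox fixtures --which table1 --out ref.csv
cardiobox build-limits --reference ref.csv --out limits.json
cardiobox classify --patients patients.csv --limits limits.json --out boxes.csv
cardiobox render --boxes boxes.csv --limits limits.json --out chart.svg
cardiobox simulate --config sim.json --out population.csv
```

`classify` accepts pre-normalised columns (`AIDn`, `LVIDDn`, ...) directly,
or raw centimetre columns (`AID`, `LVIDD`, ...) plus `weight_kg` together
with an exponent file `--exponents b.json` of the form
`{"AID": 0.33, "IVSD": 0.25, ...}`.

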