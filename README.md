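# nammold

Semi-automated design of intraoral molding plate series for presurgical
nasoalveolar molding (NAM), with synthetic neonatal cleft anatomy and
landmark morphometrics.

## The problem

Newborns with a unilateral cleft lip and palate (CLP) are often treated
before lip surgery with a series of removable intraoral molding plates that
passively guide the growth of the two alveolar segments toward a harmonic
arch and narrow the cleft. Designing each plate by hand in general-purpose
CAD software takes a specialist on the order of an hour per series; the
workflow implemented here automates the geometric steps so a whole series
can be derived from a **single digitized maxillary cast**:

1. **Crest detection** — the edentulous alveolar crest is extracted from the
   cast mesh as per-angular-bin maximum-height surface points in an
   estimated occlusal frame, split into greater/smaller segments at the
   cleft.
2. **Arch ellipse** — the dental arch form is fitted to the crest points by
   the direct least-squares conic fit constrained to ellipses (Fitzgibbon's
   constraint, Halir–Flusser formulation), with a geometric
   orthogonal-distance residual. The ellipse is the *guiding track*: cleft
   bridging and growth both follow it.
3. **Bridging** — the cleft is virtually closed by a strip swept along the
   fitted ellipse arc between the two segment margins.
4. **Plate construction** — the covered anatomy is shelled into a plate:
   the intaglio (tissue-facing) surface reproduces the cast exactly, the
   outer surface is a rolling-ball offset at the wall thickness; a retention
   pin (Boolean union) and a ventilation hole (Boolean difference) are
   added, then Taubin smoothing with the intaglio held in place.
5. **Series generation** — plate *k* targets the arch ellipse scaled by
   `(1+g)^(k·Δt)` (g = monthly relative growth fraction, Δt in months) and
   a residual cleft gap shrinking linearly to zero, so successive plates
   implement growth-guided expansion and progressive cleft closure without
   rotating the segments.

Treatment outcome is quantified with the standard ten-landmark scheme of
the neonatal maxilla (A, P, SA/SA′, L/L′, T/T′, SD/SD′, with MT the T–T′
midpoint), seven inter-landmark distances, seven-column cohort summaries,
and exact Wilcoxon tests (signed-rank by sign-flip enumeration, rank-sum by
rank-assignment enumeration) suited to the very small n of pilot cohorts.

Because no real cast data are distributable, the package ships a first-class
synthetic-anatomy module: a parametric implicit model of a neonatal cleft
maxilla (elliptic arch wall, palatal vault, posterior palatal channel, cast
pedestal) with exact ground truth for every landmark, the arch ellipse and
the crest polylines, calibrated so its default distances fall inside
published neonatal unilateral-CLP ranges.

## Worked example

```bash
nammold synth --cleft-width 10 --seed 1 -o casts/
nammold detect casts/maxilla.stl -o detection.json
nammold series casts/maxilla.stl detection.json --growth 0.02 --plates 6 -o series/
nammold measure casts/maxilla.landmarks.json
```

The `detect` step prints:

```
crest segments: 2; ellipse a=20.11 b=18.89 mm; rms residual 0.179 mm; gap span 32.9 deg
```

meaning both alveolar segments were found, the arch ellipse has semi-axes
20.1 × 18.9 mm with a crest-to-ellipse RMS distance of 0.18 mm, and the
cleft interrupts the arch over a 32.9° arc. `detection.json` is a
human-editable intermediate: a clinician can correct the crest or ellipse
and re-run the downstream steps. `series/` then contains `plate_01.stl` …
`plate_06.stl` plus a manifest with per-plate target and re-measured arch
axes and residual gap widths. `measure` prints the seven distances:

```
A - MT: 27.8 mm
L - L': 32.7 mm
SA - SA': 10.0 mm
T - T': 35.4 mm
SD - SD': 18.5 mm
A - P: 6.0 mm
SA - SD: 7.3 mm
```

— the synthetic cast was generated with a 10 mm cleft, and the measured
SA–SA′ distance recovers it. `nammold stats pre.csv post.csv` produces the
paired pre/post summary rows, box-plot statistics and exact signed-rank
p-values for a cohort.

## Layout

| module | role |
| --- | --- |
| `nammold.mesh_io` | STL/OBJ and landmark file I/O, cleaning, validation reports |
| `nammold.synthetic_anatomy` | parametric cleft-maxilla generator with ground truth, paired cohorts |
| `nammold.ridge_detection` | occlusal frame, crest extraction, direct ellipse fit |
| `nammold.plate_builder` | bridging, shelling, pin/hole Booleans, smoothing |
| `nammold.growth_series` | series planning and growth-guided generation |
| `nammold.morphometrics` | landmarks, distances, summaries, exact Wilcoxon tests |
| `nammold.cli` | `nammold` command: synth / detect / plate / series / measure / stats |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical design choices.
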