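# vtcwm

White-matter connectivity profiles of ventral-temporal cortex (VTC)
functional regions: a tested, reusable pipeline for extracting functionally
defined sub-bundles from tractograms, building endpoint-density connectivity
profiles over a cortical parcellation, classifying cytoarchitecture /
category / age from those profiles, quantifying connections to
eccentricity bands in early visual cortex, and measuring how connectivity
develops with age — exercised end to end on a synthetic cohort generator
with planted statistical structure.

## The scientific problem

Category-selective regions in VTC (face-, word-, body-, and place-selective
fROIs) sit in consistent anatomical locations, and one candidate scaffold is
the organization of their white-matter connections. Three organizing
principles compete: **category** (regions with the same selectivity share
connections), **cytoarchitecture** (regions in the same cytoarchitectonic
area FG2/FG3/FG4 share connections), and **eccentricity** (connections to
early visual cortex follow the foveal-to-peripheral map). Deciding between
them requires machinery to

1. intersect a whole-brain tractogram with a surface-defined fROI by radial
   search (3 mm) at the gray/white interface and keep the sub-bundle of
   streamlines terminating there;
2. turn each sub-bundle into a *connectivity profile*: the endpoint density
   over 169 retained atlas parcels of the fROI's hemisphere (seed-region
   parcels excluded to avoid counting looping fibers), an
   `fROIs x sessions = 880`-row matrix on the default cohort;
3. embed profiles with PCA and classify cytoarchitecture (FG2/FG3/FG4),
   category (faces/words/bodies/places), and age group with
   leave-one-subject-out multinomial logistic regression and winner-take-all
   readout (`accuracy ~ chance` tested per session, df 87);
4. count each fROI's streamlines to the three EVC eccentricity bands
   (0–5°, 5–10°, 10–20°) and model the central-5° percentage as
   `cytoarchitecture x category x age group` (sequential SS; residual
   df 504 with the place/FG3 aliasing), with paired post-hoc tests and a
   `log10(age) + (1 | subject)` random-intercept model fitted by REML;
5. regress each parcel's endpoint density on `log10(age in days)` (slope
   maps), and compare developmental similarity between fROI pairs via a
   1000-iteration bootstrap (66 of 88 profiles per iteration) of slope
   vectors, `FisherZ(r) ~ same_category + same_cytoarchitecture`.

Because per-subject raw data of this kind is not generally redistributable,
the package ships a first-class synthetic generator
(`vtcwm.synthetic`) that produces the cohort (88 sessions: 23 newborn /
23 three-month / 21 six-month / 21 adult, 21 longitudinal infants), a
parcellated two-hemisphere surface with fROI / cytoarchitecture /
eccentricity-band labels, and tractograms whose endpoint distributions
cluster strongly by cytoarchitecture, weakly by category, and drift with
log10(age). Every downstream stage is tested against this planted truth;
see `docs/methods.md` for what the generator does and does not emulate.

## Worked example

The numbered scripts under `analysis/` run the pipeline stage by stage into
a results directory:

```sh
python analysis/01_simulate_cohort.py  --results results --seed 1
python analysis/02_build_profiles.py   --results results --seed 1
python analysis/03_classify_profiles.py --results results --seed 1
python analysis/04_eccentricity_bands.py --results results
python analysis/05_development_slopes.py --results results --seed 1
python analysis/06_report.py           --results results
```

which prints (seed 1):

```
retained sessions: 88 ({'newborn': 23, '3mo': 23, '6mo': 21, 'adult': 21})
longitudinal subjects: 21; mesh vertices: 3240; retained parcels per hemisphere: 169
profile matrix: 880 rows x 169 parcels
mean retained profile mass: 0.500 (the seed-side half of each sub-bundle's
endpoints lies in the excluded seed parcels)
PCA: elbow at 3 components, top 10 explain 93.9% of variance
cytoarchitecture: 100.0% +/- 0.0% (chance 33.3%, t(87) = inf, d = inf)
category: 89.9% +/- 8.8% (chance 25.0%, t(87) = 69.37, d = 7.39)
age_group: 9.8% +/- 17.5% (chance 25.0%, t(87) = -8.14, d = -0.87)
FG2: 63.60% +/- 2.67% of EVC connections in the central 5 degrees
FG3: 26.64% +/- 2.13% of EVC connections in the central 5 degrees
FG4: 44.21% +/- 2.48% of EVC connections in the central 5 degrees
cytoarchitecture main effect: F(2,504) = 7275.1, eta2 = 0.96
bootstrap: 66 of 88 profiles per iteration, 15 fROI pairs x 1000 iterations = 15000 correlations
mean slope correlation: 0.44 within an area vs 0.09 across areas
```

Reading these numbers: profiles classify perfectly by cytoarchitectonic
area and well by category, while the (weakly planted) age signal does not
survive the 3-component elbow — the qualitative ordering cytoarchitecture >
category > age is the planted structure coming back out. The central-5°
percentages recover the per-area band proportions the generator plants
(63.57 / 26.58 / 43.97), and fROIs in the same cytoarchitectonic area have
markedly more similar developmental slope maps than fROIs in different
areas. The same run is available as one command, `vtcwm all --seed 1`, and
each stage as a CLI subcommand (`vtcwm simulate | extract | profile |
classify | eccentricity | develop | report`).

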