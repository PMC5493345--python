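# catchcurve

Catch-curve inference of fishing pressure across fishery management regimes.

`catchcurve` estimates **total instantaneous mortality** *Z* from
length-frequency samples of benthic shellfish, compares *Z* across
management regimes, sites and years, and decomposes it against a no-take
natural-mortality reference — the workflow used to infer illegal fishing in
open-access artisanal fishing grounds from dive-survey length data.

The motivating system is the central-Chile benthic fishery: fishing grounds
under territorial use rights (TURFs, here "management areas", MA) sit in a
landscape of open access areas (OAA), next to a single fully protected
no-take (NT) reserve. For the muricid gastropod *Concholepas concholepas*
("loco", whose extraction is banned in open access areas) and keyhole
limpets (*Fissurella* spp.), mortality in excess of the no-take reference
measures fishing pressure — and, where fishing is banned, illegal take.

## Method

1. **Ageing.** Measured lengths are converted to ages with the von
   Bertalanffy growth model, L(a) = L∞(1 − e^(−K(a−t0))), inverted as
   a(L) = t0 − ln(1 − L/L∞)/K. Growth coefficients: K = 0.433 /yr (loco),
   K = 0.160 /yr (keyhole limpets); L∞ and t0 come from configuration.
2. **Catch curve.** Ages are binned into 0.2-yr classes; observations at the
   right end beyond a run of ≥ 4 zero-count classes are discarded; the age
   of full recruitment is the maximizer of a cubic smoothing spline fitted
   to the class frequencies; on the descending limb, ordinary least squares
   of ln C on age A (`ln C = −Z·A + B`) estimates Z as the negated slope.
3. **Comparison.** Slope differences between groups (regimes, sites,
   management areas, years) are tested by ANCOVA: the group × age
   interaction of the full linear model on the stacked limbs (Type II sums
   of squares), with single-df contrasts for pairwise post-hoc tests, a
   year-trend regression for the annual MA series, and a pooled Student
   t-test between species.
4. **Decomposition.** Z = M + F with M proxied by the no-take estimate;
   F̂ = Z − M with percent differences reported as integers.

Because the study's raw length records are not public, the package ships an
age-structured **cohort simulator**: equilibrium age structure with density
∝ s(a)·e^(−Z·a), logistic selectivity s, von Bertalanffy mean growth and
multiplicative individual length variability, plus a fixture generator that
mirrors the study design (3 regimes × 3 sites × 5 management areas ×
years 1999–2013 with the published per-cell sample sizes).

## Worked example

```python
from catchcurve.simulate import study_fixture_spec, make_study_fixture
from catchcurve import run_regional

spec = study_fixture_spec(seed=7, n_per_cell=2000, snapshot_only=True)
records = make_study_fixture(spec)          # synthetic comparative survey
report = run_regional(records, seed=7)

loco = report["species"]["loco"]
for regime in ("NT", "MA", "OAA"):
    fit = loco["fits"][regime]
    print(f"{regime:>3}: Z = {fit.z:.2f}  (95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f})")
print("percent vs no-take:", loco["percent_vs_nt"])
print("OAA F = Z - M =", round(loco["decomposition"]["OAA"].f_est, 2), "1/yr")
print("inferred illegal fishing:", loco["inferred_illegal_fishing"])
```

prints

```
 NT: Z = 0.66  (95% CI 0.58-0.74)
 MA: Z = 0.86  (95% CI 0.77-0.94)
OAA: Z = 1.34  (95% CI 1.16-1.52)
percent vs no-take: {'MA': 30, 'OAA': 103}
OAA F = Z - M = 0.68 1/yr
inferred illegal fishing: True
```

The fixture generates loco mortality Z = 0.98 (NT), 1.39 (MA), 1.88 (OAA):
the estimated ordering NT < MA < OAA is recovered, open-access mortality far
exceeds the no-take reference, and — since loco extraction is banned in open
access areas — the positive estimated fishing mortality there is reported as
inferred illegal fishing. Absolute Ẑ sits below the generating values: the
regression catch curve is conservatively biased on realistic data (see
`docs/methods.md`), which is why the pipeline's conclusions rest on
between-regime contrasts rather than absolute rates.

The same workflow is scriptable from the shell:

```sh
catchcurve simulate --out records.csv --seed 7 --n-per-cell 2000 --snapshot-only
catchcurve all --input records.csv --out results/ --seed 7
```

writing `fits.csv`, `comparisons.csv`, `decomposition.csv` and `report.json`
per analysis under `results/`.

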