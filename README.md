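# qpcrcurve

Tools for quantitative PCR standard-curve analysis: curve fitting and
validation, Poisson-based detection and quantification limits, inverse
prediction of test-sample concentrations with uncertainty, and **varPCR** —
absolute copy-number estimation from the variance of replicate Cq values.
Built for assay developers and bioanalytical statisticians who work with
replicate-level Cq tables rather than raw fluorescence curves.

## The model

The standard curve is the log-linear response

```
Cq(N) = k · log10(N) + m,        E = 10^(−1/k) − 1
```

with slope `k` (cycles per decade), intercept `m` (the Cq of a single
double-stranded target molecule) and PCR efficiency `E`. Replicate Cq
variation has two sources: Poisson variation in the number of target
molecules `x ~ Poisson(N)` actually pipetted into each reaction (an aliquot
with x = 0 is negative), and Gaussian technical noise on the Cq scale.

From the Poisson term alone follow closed-form performance limits:

- **LOD** — 95 % of aliquots are positive when N = −ln(0.05) ≈ **3
  molecules**, whatever the assay;
- **LOQ** — the linear-scale RSD implied by aliquoting,
  `RSD = sqrt((1+E)^(SD(Cq)²) − 1)` applied to the zero-truncated Poisson
  Cq spread, falls to the common 25 % criterion at **26 molecules** (E = 1);
- **varPCR** — inverting that same RSD(N) relationship at the *observed*
  replicate Cq SD estimates the absolute copy number without any standard
  curve, complementing the dPCR occupancy readout N = −ln(f_negative) when
  most or all partitions are positive.

Validation follows routine practice: efficiency CIs from the delta-method
SE, standardized-residual and Grubbs outlier screening, polynomial F-tests
for the linear dynamic range, Working–Hotelling bands, and ±1-cycle QC
rules. Inverse prediction uses the standard calibration SE

```
SE(log10 N) = (SEy.x/|k|) · sqrt(1/b + 1/n + (Cq − C̄q)²/(k²·Sxx)).
```

See `docs/methods.md` for assumptions, defaults, and numerical details.

## Worked example

Simulate a high-replication validation series (2-fold dilutions, 2048 down
to 1 expected copy per reaction; 128/64/32 replicates per level), then
analyze it:

```console
$ qpcrcurve simulate --preset extreme --seed 11 --out demo.csv
$ qpcrcurve loq demo.csv                 # dynamic range at 25% RSD
$ qpcrcurve lod demo.csv --seed 1 --n-boot 500
$ qpcrcurve fit demo.csv --min-copies 32 --out fit.json
```

With seed 11 this prints (abridged): LLOQ 64 with no ULOQ inside the tested
range; LOD 2.86 copies, 95 % CI [2.17, 3.53] — consistent with the
theoretical limit of 3; and the curve fitted above the quantification
limit,

```
k = -3.363 [-3.402, -3.323]   m = 34.12   E = 0.983 [0.967, 0.999]
```

recovering the simulation truth (E = 1, m = 34). Concentrations of test
samples measured in triplicate:

```console
$ printf 'sample_id,cq\nS1,25.10\nS1,25.28\nS1,25.16\n' > test.csv
$ qpcrcurve predict test.csv --curve fit.json
sample_id,ci_min_log10,log10_conc,ci_max_log10,ci_min,conc,ci_max,...
S1,2.585,2.659,2.733,384.8,456.2,540.8,...
```

i.e. S1 holds 10^2.66 ≈ 456 copies per reaction, CI [385, 541] — symmetric
in log scale, upward-skewed in linear scale (columns rounded here; the CLI
prints full precision). Absolute quantification from Cq variance alone, on
the 64 replicates of the 64-copy level (pulled out of `demo.csv`):

```console
$ qpcrcurve varpcr level64.csv --seed 2
{
  "n_hat": 42.0,   "ci": [30.7, 67.5],   "branch": "high",  ...
}
```

The CI covers the truth; the low point estimate shows the documented
downward bias of variance-based quantification when technical Cq noise
(0.15 cycles in this simulation) adds to the aliquoting variance it
inverts. `qpcrcurve validate` bundles fit, residual screening, Grubbs,
linearity F-tests and the efficiency acceptance rule into one JSON report;
`qpcrcurve --help` lists all subcommands.

Everything is available as a library too — `qpcrcurve.fit_standard_curve`,
`qpcrcurve.theoretical_loq`, `qpcrcurve.varpcr_estimate`, … — operating on
pandas DataFrames in the CSV schema `level_id,copies,replicate,cq` (empty
`cq` = negative reaction).

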