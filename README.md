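# fiberdiff

Mesoscale fiber-diffraction analysis toolkit for amyloid-type assemblies:

- **Scattering model** — cylindrically averaged equatorial intensity of solid
  cylinders arranged on a two-level hierarchy of circular lattices
  (`I(Q) = scale · f²(Q) · Φ²(n0, r0, Q) · Φ̃²(n1, r1, Q)`), with Gaussian
  radius polydispersity and a brute-force azimuthal-quadrature oracle that
  checks the closed-form Bessel sums against the literal structure.
- **Model fitting** — deviation R-factor minimization over enumerated lattice
  occupancies `(n0, n1)` with seeded multistart refinement of the continuous
  parameters; crystallinity (excess intensity above a minima-pinned polynomial
  background).
- **1D/2D reduction** — background estimation, multi-Gaussian peak fitting
  (spacings, integral widths, Scherrer-type coherence lengths `L = 2π/ΔQ`),
  sector and azimuthal integration of 2D detector patterns, mutual-orientation
  extraction (one vs two fiber populations by F-test), multi-distance merging.
- **H-D exchange kinetics** — band-integrated peak intensity versus time, fit
  by a three-parameter exponential (exchange time τ, residual asymptote).
- **Synthetic data** — seed-deterministic generators for equatorial profiles,
  oriented 2D patterns, powder rings and decay curves, each with a
  machine-readable truth record, plus four named sample scenarios.

Conventions: momentum transfer `Q` [Å⁻¹] is the public reciprocal coordinate
(`d = 2π/Q`); azimuth is measured from the fiber/field axis ("up"), so the
equator lies at ±90°; all file formats are plain text.

## CLI

One executable with subcommands (run `fiberdiff --help` for the full list):

```sh
# Q <-> d conversion
fiberdiff convert --q 1.312

# synthetic data for a named scenario (WT, A2V, WT_A2V, WT_1to6A2V)
fiberdiff simulate-profile --scenario WT --out wt.tsv --noise 0.02 --seed 1
fiberdiff simulate-pattern --scenario WT --out-prefix wt --seed 1
fiberdiff simulate-decay  --scenario WT --out decay.tsv --noise 0.02 --seed 1

# reduce a 2D pattern: sector profile + orientation report
fiberdiff process-pattern --matrix wt.mat.txt --geom wt.geom.txt \
    --sector equator --q-band 0.035,0.055 \
    --out-profile eq.tsv --out-report orient.json

# fit the hierarchical cylinder-lattice model by R-factor minimization
fiberdiff fit-model --profile wt.tsv --out fit.json --n0 1,2,3,4,5,6 --n1 1,2,3 --seed 1

# crystallinity, powder peaks, exchange kinetics
fiberdiff crystallinity --profile wt.tsv --q-window 0.01,0.25
fiberdiff powder-peaks --profile powder.tsv --n-peaks 2
fiberdiff fit-decay --tsv decay.tsv --out decay.json
```

Every run logs the tool version, a configuration hash and the seed to stderr.

### File formats

- Profiles: TSV with `# Q[1/A]  I  [sigma]` header; `#` lines are comments.
- Patterns: `<name>.mat.txt` whitespace intensity matrix plus
  `<name>.geom.txt` with `wavelength_A`, `distance_mm`, `pixel_mm`,
  `beam_row`, `beam_col` and optional `axis_deg`.
- Config: YAML/JSON mirroring `AnalysisConfig`; CLI flags override.

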