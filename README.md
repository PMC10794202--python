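# domresp

Thermal (and general environmental) responses of dissolved organic matter
(DOM) at the molecular and compositional level.

Ultrahigh-resolution mass spectrometry (FT-ICR MS) resolves a DOM sample
into thousands of assigned molecular formulas, each with its own intensity
and intrinsic traits. `domresp` quantifies how such an assemblage responds
to an environmental gradient — water temperature in the motivating
microcosm experiments — for researchers in aquatic biogeochemistry and
carbon-cycle science who work with molecule × sample intensity tables.

## The indicators

**MER** (molecule-specific environmental response): for molecule *i* with
relative abundance *I<sub>i</sub>* across samples, the Spearman rank
correlation ρ<sub>i</sub> between *I<sub>i</sub>* and the covariate.
Positive / negative MERs mark warm-accumulating / warm-depleting
molecules. A majority rule retains only molecules detected in more than a
third of the samples used for fitting.

**iCER** (compositional-level environmental response) of one sample:

    iCER = Σ(MER_i · I_i) / Σ(I_i)

the relative-abundance-weighted mean of the MERs present in the sample.
iCER = 0 means warm-accumulating and warm-depleting molecules balance.
MERs and iCERs are computed on statistically independent data: each of 999
replicates splits the samples 80:20, fits MERs on the 80% partition and
scores iCER on the held-out 20%, and per-sample values are averaged across
replicates.

Around this core the package provides: the molecular-trait machinery
(NOSC = −((−Z + 4a + b − 3c − 2d + 5e − 2f)/a) + 4 over element counts
a–f; GFE = 60.3 − 28.5·NOSC in kJ (mol C)⁻¹; DBE, modified aromaticity
index, Kendrick defect, element ratios) and the seven van Krevelen
compound classes; the |MER| removal continuum; inter- and intra-regional
MER transferability; headspace greenhouse-gas release rates
(R = dc/dt · V/M_v · M_w/m); and a synthetic-data generator that emulates
the 480-microcosm field design and the 84-microcosm laboratory design
with planted, recoverable response structure.

## Worked example

```python
from scipy.stats import spearmanr
from domresp import (SynthScenario, generate, compute_mer_table,
                     icer_pipeline, sensitivity_analysis)

frame, truth = generate(SynthScenario(design="field", seed=42))
mers = compute_mer_table(frame)                    # water_temp_C by default
result = icer_pipeline(frame, n_reps=199, seed=42)
icer = result.variant("significant_only")["icer"]
sens = sensitivity_analysis(result, frame.samples)
```

which prints, when summarized:

```
samples: 480, molecules: 300
retained molecules: 300 (occupancy >= 160)
MER range: -0.86 to 0.82; significant: 90.7%
per-sample iCER: mean -0.009; Spearman(iCER, temperature) = 0.977
mean iCER-temperature slope: 0.0388 per degree C; nutrient trend: -2.36e-05 per mg N/L (-0.1% per mg N/L)
```

The MER range spans strong depleting to strong accumulating molecules;
the per-sample iCER tracks the planted temperature structure almost
perfectly (rank correlation 0.98), and — because this scenario plants no
temperature × nutrient interaction — the warming sensitivity of iCER
shows no trend across nutrient levels.

The same stages are available as a command-line tool:

```sh
domresp synth --design field --seed 42 --out-dir data/
domresp mer   --molecules data/molecules.csv --intensity data/intensity.csv \
              --metadata data/metadata.csv --out mer.csv
domresp icer  --molecules data/molecules.csv --intensity data/intensity.csv \
              --metadata data/metadata.csv --reps 999 --seed 42 --out icer.csv
```

Subcommands `traits`, `continuum`, `transfer`, `gas` and `link` cover the
remaining analyses; every run writes a JSON manifest (parameters, input
checksums, version) beside its output.

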