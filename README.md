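# riverdom

Seasonal analysis of dissolved organic matter (DOM) and its coupling to
the surface-water microbiome, for river-basin field campaigns that pair
3D fluorescence spectroscopy with 16S amplicon surveys.

`riverdom` takes a stack of excitation–emission matrices (EEMs), an OTU
count table with taxonomy, and a water-chemistry table, and runs the
full chemometric/ecological chain:

1. **EEM preprocessing** — blank subtraction, optional absorbance-based
   inner-filter correction, excision of first/second-order Rayleigh and
   Raman scatter, and normalisation to Raman units from the integrated
   water Raman peak of a blank at Ex 350 nm (Em 371–428 nm).
2. **PARAFAC** — non-negative trilinear decomposition
   `X[i,x,m] ≈ Σ_f A[i,f]·C[x,f]·B[m,f]` by alternating least squares
   with random restarts, treating excised cells as missing.  Validation
   by the core consistency diagnostic (CORCONDIA) and split-half
   resampling with Tucker-congruence matching; per-sample component
   intensity reported as Fmax and percent abundance; components typed
   protein-like vs humic-like from their peak positions.
3. **Fluorescence indices** — FI = I(370/470)/I(370/520),
   BIX = I(310/380)/I(310/430), and a bounded humification index
   HIX = A(435–480)/(A(435–480)+A(300–345)), with source labels
   (terrestrial/mixed/autochthonous; endogenous; humification level).
4. **2D correlation spectroscopy** — synchronous Φ = ỸᵀỸ/(m−1) and
   asynchronous Ψ = ỸᵀNỸ/(m−1) maps over a perturbation-ordered series
   (N the Hilbert–Noda matrix), with sequential-order inference from
   Noda's sign rules and cycle detection.
5. **Microbiome summaries** — taxonomy aggregation, Shannon and
   bias-corrected Chao1 diversity, rarefaction curves, and
   taxa-versus-component Spearman heatmap data (exact permutation
   p-values at small n).
6. **Co-occurrence network** — OTU/DOM-component graph with edges at
   |r| > 0.5 and p < 0.05, seasonal summary statistics, and keystone
   detection (high degree, low betweenness).
7. **Path model** — composite path analysis of the humification
   hypothesis (microbes → protein-like / humic-like DOM → humification
   ratio) with standardized OLS coefficients and a DOT diagram export.

Because raw field data for such campaigns is often unavailable, the
package ships a first-class synthetic-data generator
(`riverdom.synthetic`) that produces seeded, ground-truthed datasets:
trilinear EEM mixtures with realistic fluorophore peak positions,
scatter ridges and noise; multinomial OTU tables with planted
taxon–component links; and chemistry tables driven by the same latent
scores.  All recovery tests run against this ground truth.

## Worked example

```python
from riverdom import (EEMStack, compute_fmax, corcondia, fit_parafac,
                      generate_eem_dataset, split_half_validate)
from riverdom.parafac import classify_components
from riverdom.synthetic import recovery_fluorophores

eems, truth = generate_eem_dataset(
    n_samples=20, fluorophores=recovery_fluorophores(),
    scatter=False, seed=1)                      # 1% noise by default
stack = EEMStack(eems)
model = fit_parafac(stack, n_components=3, n_starts=4, seed=0)
model.corcondia = corcondia(model, stack)
sh = split_half_validate(stack, 3, seed=0)
fmax, percent = compute_fmax(model)
```

which prints

```
explained variance : 0.9896
CORCONDIA          : 99.98
split-half validated: True (min congruence 0.9998)
mean % abundance   : {'C1': 34.67, 'C2': 32.79, 'C3': 32.55}
           em_peak         class
component
C1           305.0  protein-like
C2           345.0  protein-like
C3           455.0    humic-like
```

CORCONDIA near 100 and split-half congruence near 1 confirm the
three-component trilinear model; the emission peaks at 305/345 nm mark
the two protein-like (tyrosine/tryptophan-type) components and 455 nm
the humic-like one, and each contributes roughly a third of the total
fluorescence in this balanced simulation.

The whole chain runs from the command line too:

```bash
riverdom run-all --out results_run --seed 1     # synthetic end-to-end run
riverdom simulate --out data --n-samples 20 --seed 1
riverdom parafac --manifest data/manifest.csv --n-components 3 --out pf
```

`run-all` writes per-stage CSV artifacts plus a deterministic
`report.json` (identical config and seeds give a byte-identical
payload).

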