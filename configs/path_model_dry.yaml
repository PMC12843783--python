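# Dry-season path model: microbial community -> DOM blocks -> humification.
# Indicators: component Fmax columns (D1..D6) and phylum relative abundances.
composites:
  Microbes: [Proteobacteria, Actinobacteriota, Cyanobacteria, Firmicutes,
             Bacteroidota, Verrucomicrobiota]
  Protein: [D1, D4, D5, D6]
  MicrobialHumic: [D2]
  Humic: [D3]
paths:
  - [Microbes, Protein]
  - [Microbes, MicrobialHumic]
  - [Microbes, Humic]
  - [Protein, MicrobialHumic]
  - [MicrobialHumic, Humification]
  - [Humic, Humification]
ratio_composite:
  name: Humification
  numerator: [D1, D4, D5, D6]
  denominator: [D2, D3]
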