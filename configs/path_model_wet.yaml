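# Wet-season path model: protein and humic blocks both act on humification.
composites:
  Microbes: [Proteobacteria, Actinobacteriota, Cyanobacteria, Firmicutes,
             Bacteroidota, Verrucomicrobiota]
  Protein: [W2, W5, W6]
  MicrobialHumic: [W1]
  Humic: [W3, W4]
paths:
  - [Microbes, Protein]
  - [Microbes, MicrobialHumic]
  - [Microbes, Humic]
  - [Protein, Humification]
  - [MicrobialHumic, Humification]
  - [Humic, Humification]
ratio_composite:
  name: Humification
  numerator: [W2, W5, W6]
  denominator: [W1, W3, W4]
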