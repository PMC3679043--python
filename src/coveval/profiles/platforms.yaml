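# Built-in platform presets. Parameters are qualitative stand-ins chosen to
# reproduce the characteristic behaviours of three platform archetypes:
#   illumina_like  - narrow coverage distribution, mild GC bias at both extremes
#   solid_like     - pronounced dropout of GC-rich fragments, short fragments
#   cg_like        - nearly flat GC response but broad (overdispersed) coverage
# gc_response is a piecewise-linear weight w(g) over fragment GC fraction g.
illumina_like:
  gc_response:
    knots:   [0.0, 0.15, 0.30, 0.55, 0.70, 0.85, 1.0]
    weights: [0.35, 0.80, 1.00, 1.00, 0.80, 0.40, 0.15]
  fragment_length_mean: 400
  fragment_length_sd: 40
  read_length: 100
  duplicate_rate: 0.02
  dispersion: 0.03
  repeat_mappability: 0.45

solid_like:
  gc_response:
    knots:   [0.0, 0.15, 0.30, 0.45, 0.60, 0.75, 1.0]
    weights: [0.20, 0.60, 1.00, 0.90, 0.35, 0.08, 0.02]
  fragment_length_mean: 230
  fragment_length_sd: 25
  read_length: 50
  duplicate_rate: 0.04
  dispersion: 0.12
  repeat_mappability: 0.40

cg_like:
  gc_response:
    knots:   [0.0, 0.15, 0.30, 0.70, 0.85, 1.0]
    weights: [0.30, 0.85, 1.00, 1.00, 0.90, 0.60]
  fragment_length_mean: 350
  fragment_length_sd: 35
  read_length: 35
  duplicate_rate: 0.03
  dispersion: 0.25
  repeat_mappability: 0.25
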