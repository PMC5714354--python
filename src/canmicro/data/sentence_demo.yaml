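# Six-node sentence-parsing network for "I hit the thief with the club".
#
# Word-representing microcircuits are grouped into syntactic modules;
# the two 'with' nodes (verb-modifier vs object-modifier) compete through
# asymmetric mutual inhibition, and a noisy inhibitory context signal on
# the verb-modifier selects the object-modifier reading when present.
#
# All connection gains below are hand-tuned calibration artifacts chosen
# to reproduce the qualitative parsing outcomes; none is a measured or
# published quantity.  scripts/calibrate_demo.py sweeps them.

params: {}          # Table-1 defaults, three-population architecture

nodes:
  - {name: I,       module: S}
  - {name: hit,     module: V}
  - {name: thief,   module: O}
  - {name: with_v,  module: V-mod}
  - {name: with_o,  module: O-mod}
  - {name: club,    module: O}

edges:
  # excitatory pre-activation along the expected word order
  - {source: I,      target: hit,    sign: excitatory, gain: 5.0}
  - {source: hit,    target: thief,  sign: excitatory, gain: 5.0}
  - {source: hit,    target: with_v, sign: excitatory, gain: 5.0}
  - {source: thief,  target: with_o, sign: excitatory, gain: 5.0}
  - {source: with_v, target: club,   sign: excitatory, gain: 3.0}
  - {source: with_o, target: club,   sign: excitatory, gain: 3.0}
  # asymmetric mutual inhibition between the competing modifiers
  - {source: with_v, target: with_o, sign: inhibitory, gain: 20.0}
  - {source: with_o, target: with_v, sign: inhibitory, gain: 4.0}

# afferent word information: rectangular drives per recognized word
schedule:
  - {node: I,      onset: 1.0, duration: 1.0, intensity: 120.0}
  - {node: hit,    onset: 2.2, duration: 1.0, intensity: 120.0}
  - {node: thief,  onset: 3.4, duration: 1.0, intensity: 120.0}
  - {node: with_v, onset: 4.6, duration: 1.0, intensity: 120.0}
  - {node: with_o, onset: 4.6, duration: 1.0, intensity: 120.0}
  - {node: club,   onset: 5.8, duration: 1.0, intensity: 120.0}

context_target: with_v
context_levels: {high: 150.0, low: 0.0}
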