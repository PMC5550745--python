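# Archetype presets for the synthetic silhouette generator.
#
# The four entries emulate the canonical microglial morphologies seen in
# IBA1-stained tissue: ramified (surveillant), hypertrophied (reactive,
# rod-like polarized soma with shortened thick processes), bushy
# (de-ramified, few stout processes around a swollen soma) and amoeboid
# (reactive elongated blob).  Length scales are micrometres; two-element
# lists are [mean, sd] of a normal draw; n_primary is an inclusive integer
# range.  soma_axis_ratio elongates the soma (1 = circular).
# thickness_jitter sets the per-step membrane roughness of branches;
# together with branch density it calibrates the outline box-counting
# dimension of ramified cells into the range reported for microglia
# (about 1.2-1.45).
ramified:
  soma_radius_um: [3.2, 0.2]
  n_primary: [6, 6]
  branch_length_um: [14.0, 1.0]
  branch_thickness_um: [0.7, 0.06]
  secondary_branch_prob: 1.0
  tortuosity: 0.18
  taper: 0.004
  soma_axis_ratio: [1.1, 0.03]
  thickness_jitter: 0.3
hypertrophied:
  soma_radius_um: [4.2, 0.25]
  n_primary: [4, 5]
  branch_length_um: [8.5, 0.8]
  branch_thickness_um: [1.4, 0.12]
  secondary_branch_prob: 0.5
  tortuosity: 0.10
  taper: 0.004
  soma_axis_ratio: [1.5, 0.06]
  thickness_jitter: 0.3
bushy:
  soma_radius_um: [5.5, 0.25]
  n_primary: [3, 4]
  branch_length_um: [3.5, 0.5]
  branch_thickness_um: [2.4, 0.2]
  secondary_branch_prob: 0.15
  tortuosity: 0.10
  taper: 0.004
  soma_axis_ratio: [1.15, 0.04]
  thickness_jitter: 0.25
amoeboid:
  soma_radius_um: [7.5, 0.35]
  n_primary: [0, 1]
  branch_length_um: [2.5, 0.5]
  branch_thickness_um: [2.5, 0.3]
  secondary_branch_prob: 0.0
  tortuosity: 0.10
  taper: 0.004
  soma_axis_ratio: [2.8, 0.12]
  thickness_jitter: 0.2
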