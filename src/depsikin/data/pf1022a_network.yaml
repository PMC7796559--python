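# Exchange network for the PF1022A worked example in CDCl3.
# Site A: Hα of the Mle pair in the symmetric (all-trans) conformer.
# Sites B, C: Hα of Mle6 / Mle26 in the asymmetric (one-cis) conformer.
# Magnetic fractions are the relative 1H intensities of the three
# resonances; B and C do not exchange directly.
mixing_time_s: 0.1
site_labels: [A, B, C]
conformer_of_site:
  A: symmetric
  B: asymmetric
  C: asymmetric
magnetic_fractions:
  A: 1.0
  B: 1.5
  C: 1.5
symmetry_pairs:
  - [[A, B], [A, C]]
  - [[B, A], [C, A]]
forbidden_pairs:
  - [B, C]
c2_symmetric: true
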