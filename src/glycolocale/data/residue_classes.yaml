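# Residue property classes used to classify the X of N(X-P)S/T sequons.
# Classes may overlap (a residue can be both bulky and hydrophobic).
# Editable: swap in alternative conventions by changing the memberships below.
#
# Defaults:
#   acidic / basic  - universal convention (His counted basic).
#   hydrophobic     - positive Kyte-Doolittle hydropathy, plus W (aromatic
#                     tryptophan is near-universally counted hydrophobic; KD
#                     scores it mildly negative only for its indole NH).
#   hydrophilic     - complement of hydrophobic.
#   bulky           - upper half (top 10) of the Zimmerman bulkiness scale.
#   small           - conventional small-residue set.
acidic: [D, E]
basic: [K, R, H]
hydrophobic: [A, C, F, I, L, M, V, W]
hydrophilic: [D, E, G, H, K, N, P, Q, R, S, T, Y]
bulky: [W, V, I, L, F, Y, P, M, T, K]
small: [G, A, S, C, T, P, N, D]
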