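# Per-residue property scales used for property-level enrichment.
# Each scale has all 20 canonical residues and a provenance note naming the
# literature scale it mirrors.  Values are editable stand-ins: swap in an
# alternative table without touching code.
aromaticity:
  provenance: "binary indicator of an aromatic ring (F, W, Y, H)"
  values: {A: 0, C: 0, D: 0, E: 0, F: 1, G: 0, H: 1, I: 0, K: 0, L: 0,
           M: 0, N: 0, P: 0, Q: 0, R: 0, S: 0, T: 0, V: 0, W: 1, Y: 1}
polarity:
  provenance: "mirrors Zimmerman, Eliezer & Simha (1968) polarity"
  values: {A: 0.00, C: 1.48, D: 49.70, E: 49.90, F: 0.35, G: 0.00, H: 51.60,
           I: 0.13, K: 49.50, L: 0.13, M: 1.43, N: 3.38, P: 1.58, Q: 3.53,
           R: 52.00, S: 1.67, T: 1.66, V: 0.13, W: 2.10, Y: 1.61}
net_charge:
  provenance: "formal side-chain charge at pH 7 (D,E -1; K,R +1; others 0)"
  values: {A: 0, C: 0, D: -1, E: -1, F: 0, G: 0, H: 0, I: 0, K: 1, L: 0,
           M: 0, N: 0, P: 0, Q: 0, R: 1, S: 0, T: 0, V: 0, W: 0, Y: 0}
hydrophobicity:
  provenance: "mirrors Kyte & Doolittle (1982) hydropathy"
  values: {A: 1.8, C: 2.5, D: -3.5, E: -3.5, F: 2.8, G: -0.4, H: -3.2,
           I: 4.5, K: -3.9, L: 3.8, M: 1.9, N: -3.5, P: -1.6, Q: -3.5,
           R: -4.5, S: -0.8, T: -0.7, V: 4.2, W: -0.9, Y: -1.3}
flexibility:
  provenance: "mirrors Bhaskaran & Ponnuswamy (1988) average flexibility"
  values: {A: 0.36, C: 0.35, D: 0.51, E: 0.50, F: 0.31, G: 0.54, H: 0.32,
           I: 0.46, K: 0.47, L: 0.37, M: 0.30, N: 0.46, P: 0.51, Q: 0.49,
           R: 0.53, S: 0.51, T: 0.44, V: 0.39, W: 0.31, Y: 0.42}
surface_exposure:
  provenance: "negated Janin (1979) interior preference (high = exposed)"
  values: {A: -0.3, C: -0.9, D: 0.6, E: 0.7, F: -0.5, G: -0.3, H: 0.1,
           I: -0.7, K: 1.8, L: -0.5, M: -0.4, N: 0.5, P: 0.3, Q: 0.7,
           R: 1.4, S: 0.1, T: 0.2, V: -0.6, W: -0.3, Y: 0.4}
beta_frequency:
  provenance: "mirrors Chou & Fasman (1978) beta-sheet conformational frequency"
  values: {A: 0.83, C: 1.19, D: 0.54, E: 0.37, F: 1.38, G: 0.75, H: 0.87,
           I: 1.60, K: 0.74, L: 1.30, M: 1.05, N: 0.89, P: 0.55, Q: 1.10,
           R: 0.93, S: 0.75, T: 1.19, V: 1.70, W: 1.37, Y: 1.47}
coil_frequency:
  provenance: "Chou & Fasman (1978) turn frequencies as a coil-propensity stand-in"
  values: {A: 0.66, C: 1.19, D: 1.46, E: 0.74, F: 0.60, G: 1.56, H: 0.95,
           I: 0.47, K: 1.01, L: 0.59, M: 0.60, N: 1.56, P: 1.52, Q: 0.98,
           R: 0.95, S: 1.43, T: 0.96, V: 0.50, W: 0.96, Y: 1.14}
disorder_propensity:
  provenance: "mirrors the TOP-IDP scale of Campen et al. (2008)"
  values: {A: 0.06, C: 0.02, D: 0.192, E: 0.736, F: -0.697, G: 0.166,
           H: 0.303, I: -0.486, K: 0.586, L: -0.326, M: -0.397, N: 0.007,
           P: 0.987, Q: 0.318, R: 0.180, S: 0.341, T: 0.059, V: -0.121,
           W: -0.884, Y: -0.510}
order_propensity:
  provenance: "negated TOP-IDP scale (high = order-promoting)"
  values: {A: -0.06, C: -0.02, D: -0.192, E: -0.736, F: 0.697, G: -0.166,
           H: -0.303, I: 0.486, K: -0.586, L: 0.326, M: 0.397, N: -0.007,
           P: -0.987, Q: -0.318, R: -0.180, S: -0.341, T: -0.059, V: 0.121,
           W: 0.884, Y: 0.510}
bulkiness:
  provenance: "mirrors Zimmerman, Eliezer & Simha (1968) bulkiness"
  values: {A: 11.50, C: 13.46, D: 11.68, E: 13.57, F: 19.80, G: 3.40,
           H: 13.69, I: 21.40, K: 15.71, L: 21.40, M: 16.25, N: 12.82,
           P: 17.43, Q: 14.45, R: 14.28, S: 9.47, T: 15.77, V: 21.57,
           W: 21.67, Y: 18.03}
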