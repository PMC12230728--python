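# Default PAM catalog.  Edit or extend freely: each entry needs a unique
# name, an IUPAC pattern, and the PAM's placement relative to the spacer
# (three_prime = downstream, SpCas9-style; five_prime = upstream, Cas12a-style).
- name: NGG
  pattern: NGG
  orientation: three_prime
- name: NAG
  pattern: NAG
  orientation: three_prime
- name: NRG
  pattern: NRG
  orientation: three_prime
- name: NG
  pattern: NG
  orientation: three_prime
- name: NNGRRT
  pattern: NNGRRT
  orientation: three_prime
- name: NNNNGATT
  pattern: NNNNGATT
  orientation: three_prime
- name: TTTN
  pattern: TTTN
  orientation: five_prime
- name: TTTV
  pattern: TTTV
  orientation: five_prime
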