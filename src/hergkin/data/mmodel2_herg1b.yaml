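# Looped five-state scheme (direct C1 <-> I edge), hERG1b, room temperature.
# The I -> C1 reverse rate is not stored: it is derived from microscopic
# reversibility of the {C1, O, I} loop at load/simulation time.
scheme: mmodel2
isoform: hERG1b
temperature_K: 296.15
rates:
  ae:  {alpha: 1.19e-2, beta: 2.17e-2}
  be:  {alpha: 1.82e-2, beta: -3.79e-2}
  ain: {alpha: 9.29e-2, beta: 0.0}
  bin: {alpha: 1.09e-1, beta: 0.0}
  aa:  {alpha: 1.55e-1, beta: 9.60e-3}
  bb:  {alpha: 7.82e-2, beta: -3.54e-2}
  bi:  {alpha: 1.79e-2, beta: -2.15e-2}
  ai:  {alpha: 5.11e-2, beta: 2.09e-2}
  ci:  {alpha: 9.32e-7, beta: 1.621e-5}
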