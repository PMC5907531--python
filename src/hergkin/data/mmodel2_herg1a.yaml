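# Looped five-state scheme (direct C1 <-> I edge), hERG1a, room temperature.
# The I -> C1 reverse rate is not stored: it is derived from microscopic
# reversibility of the {C1, O, I} loop at load/simulation time.
scheme: mmodel2
isoform: hERG1a
temperature_K: 296.15
rates:
  ae:  {alpha: 3.77e-3, beta: 3.29e-2}
  be:  {alpha: 2.44e-2, beta: -6.77e-2}
  ain: {alpha: 3.59e-2, beta: 0.0}
  bin: {alpha: 1.65e-2, beta: 0.0}
  aa:  {alpha: 8.80e-2, beta: 1.02e-2}
  bb:  {alpha: 5.11e-3, beta: -4.44e-2}
  bi:  {alpha: 9.26469e-3, beta: -2.347e-2}
  ai:  {alpha: 1.74e-2, beta: 2.87e-2}
  ci:  {alpha: 1.02e-9, beta: 7.99e-6}
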