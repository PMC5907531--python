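# Linear five-state scheme, hERG1a homotetramer, room temperature.
# alpha in ms^-1, beta in mV^-1.
scheme: mmodel1
isoform: hERG1a
temperature_K: 296.15
rates:
  ae:  {alpha: 3.39e-2, beta: 1.04e-2}
  be:  {alpha: 4.82e-2, beta: -6.91e-2}
  ain: {alpha: 2.20e-2, beta: 0.0}
  bin: {alpha: 1.36e-2, beta: 0.0}
  aa:  {alpha: 4.94e-3, beta: 4.31e-2}
  bb:  {alpha: 2.06e-4, beta: -3.76e-2}
  bi:  {alpha: 7.41e-2, beta: 2.80e-2}
  ai:  {alpha: 6.63e-3, beta: -3.89e-2}
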