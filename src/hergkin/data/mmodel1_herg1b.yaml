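# Linear five-state scheme, hERG1b homotetramer, room temperature.
# alpha in ms^-1, beta in mV^-1.
scheme: mmodel1
isoform: hERG1b
temperature_K: 296.15
rates:
  ae:  {alpha: 4.71e-2, beta: 9.36e-3}
  be:  {alpha: 7.43e-2, beta: -5.05e-2}
  ain: {alpha: 5.01e-2, beta: 0.0}
  bin: {alpha: 2.95e-2, beta: 0.0}
  aa:  {alpha: 1.71e-2, beta: 3.05e-2}
  bb:  {alpha: 1.61e-3, beta: -3.44e-2}
  bi:  {alpha: 7.41e-2, beta: 1.88e-2}
  ai:  {alpha: 2.80e-2, beta: -3.06e-2}
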