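scenario,fire_size_ha
actual,74034
actual,76379
actual,78883
actual,79492
actual,82179
actual,82263
actual,82428
actual,83019
actual,83339
actual,86471
counterfactual,93697
counterfactual,97847
counterfactual,99808
counterfactual,100588
counterfactual,103237
counterfactual,105645
counterfactual,105974
counterfactual,108534
counterfactual,111411
counterfactual,112049
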