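species_class,factor,ci_low,ci_high
medium_light_brown,6.747,6.701,6.792
large_light_brown,2.302,2.244,2.359
large_dark,0.561,0.545,0.577
giraffe,3.011,2.936,3.083
elephant,0.659,0.657,0.662
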