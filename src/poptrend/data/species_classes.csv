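species,mass_kg,class,rmax,rmax_source,preferred_method
impala,55,medium_light_brown,0.401,table,ground
tiang,127,medium_light_brown,0.299,formula,ground
gazelle,,medium_light_brown,,,ground
kob,,medium_light_brown,,,ground
red hartebeest,,medium_light_brown,,,ground
topi,,medium_light_brown,,,ground
warthog,,medium_light_brown,,,ground
roan,250,large_light_brown,0.242,formula,ground
blue wildebeest,230,large_light_brown,0.247,table,ground
eland,450,large_light_brown,0.150,table,ground
kudu,,large_light_brown,,,ground
lichtenstein hartebeest,,large_light_brown,,,ground
waterbuck,,large_light_brown,,,ground
plains zebra,,large_light_brown,,,ground
buffalo,400,large_dark,0.208,formula,aerial
sable,,large_dark,,,aerial
giraffe,702,giraffe,0.175,table,aerial
elephant,2873,elephant,0.112,table,aerial
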