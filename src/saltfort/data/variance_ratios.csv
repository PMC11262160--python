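nutrient,age_class,ratio
zinc,child,0.47
zinc,adult,0.61
folate,child,0.72
folate,adult,0.89
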