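nutrient,life_stage,status,ear,ul,units,source
zinc,child_1_3y,none,3.6,7,mg/d,ear=study (low bioavailability); ul=IOM default
zinc,woman_15_49y,none,9.9,40,mg/d,ear=study low end of WRA range; ul=IOM default
zinc,woman_15_49y,pregnant,13.7,40,mg/d,ear=study high end of WRA range; ul=IOM default
zinc,woman_15_49y,lactating,11.8,40,mg/d,ear=midpoint of WRA range (package default); ul=IOM default
zinc,man_19_45y,none,12.7,40,mg/d,ear=study; ul=IOM default
folate,child_1_3y,none,120,300,ug_dfe/d (ul: ug folic acid/d),ear=study; ul=IOM folic-acid default
folate,woman_15_49y,none,320,1000,ug_dfe/d (ul: ug folic acid/d),ear=study low end of WRA range; ul=IOM folic-acid default
folate,woman_15_49y,pregnant,520,1000,ug_dfe/d (ul: ug folic acid/d),ear=study high end of WRA range; ul=IOM folic-acid default
folate,woman_15_49y,lactating,450,1000,ug_dfe/d (ul: ug folic acid/d),ear=IOM lactation EAR (package default); ul=IOM folic-acid default
folate,man_19_45y,none,320,1000,ug_dfe/d (ul: ug folic acid/d),ear=study; ul=IOM folic-acid default
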