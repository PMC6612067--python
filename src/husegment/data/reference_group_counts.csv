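# Reference group sizes with within-year death and next-year persistence
# numerators per high-utilizer group, from the same published cohort as
# reference_top5_conditions.csv. Used for percentage-arithmetic cross-checks.
group,n,persist_n,death_n
NonHU,322905,7108,4625
Cost,14647,774,1460
LOS,217,19,20
SOC,26179,3819,90
LOS_SOC,44,11,0
Cost_LOS,6008,651,1626
Cost_SOC,12892,3244,247
Cost_LOS_SOC,5270,1863,654
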