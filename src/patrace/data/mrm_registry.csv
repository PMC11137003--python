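analyte,backbone_formula,derivative,adduct,q1,q3,neutral_loss,is_name,is_amount_nmol,known_discrepancy,note
propionate,C3H6O2,3NPH,[M-H]-,208,165,43,D5_propionate,0.6,0,
13C3_propionate,[13C]3H6O2,3NPH,[M-H]-,211,167,44,D5_propionate,0.6,0,
D5_propionate,C3HD5O2,3NPH,[M-H]-,216,170,46,,,1,printed Q1 is +3 vs the computed 3-NPH acylhydrazide of D5 propionic acid (213)
acetate,C2H4O2,3NPH,[M-H]-,194,151,43,M5_acetate,6.0,0,
M5_acetate,[13C]2HD3O2,3NPH,[M-H]-,199,155,44,,,0,
butyrate,C4H8O2,3NPH,[M-H]-,222,179,43,D7_butyrate,0.6,0,
D7_butyrate,C4HD7O2,3NPH,[M-H]-,229,186,43,,,0,
pentanoate,C5H10O2,3NPH,[M-H]-,236,193,43,D9_pentanoate,0.6,0,
D9_pentanoate,C5HD9O2,3NPH,[M-H]-,245,202,43,,,0,
hexanoate,C6H12O2,3NPH,[M-H]-,250,207,43,D11_hexanoate,0.6,0,
D11_hexanoate,C6HD11O2,3NPH,[M-H]-,261,218,43,,,0,
propionyl-CoA,C24H40N7O17P3S,,[M+H]+,824,317,507,D9_pentanoyl-CoA,0.0001,0,
methylmalonyl-CoA,C25H40N7O19P3S,,[M+H]+,868,361,507,D9_pentanoyl-CoA,0.0001,0,
D9_pentanoyl-CoA,C26H35D9N7O17P3S,,[M+H]+,861,354,507,,,0,
carnitine,C7H15NO3,methyl_ester,[M+H]+,176,85,91,D9_carnitine,0.4,0,
acetylcarnitine,C9H17NO4,methyl_ester,[M+H]+,218,99,119,D9_carnitine,0.4,0,
propionylcarnitine,C10H19NO4,methyl_ester,[M+H]+,232,99,133,D9_carnitine,0.4,0,
D9_carnitine,C7H6D9NO3,methyl_ester,[M+H]+,185,85,100,,,0,printed as 179 or 185; only 185 is consistent with +9 on the methyl ester
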