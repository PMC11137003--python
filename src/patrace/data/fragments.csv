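metabolite,backbone_formula,derivatives,tracers
glucose,C6H12O6,,H:2
glucose_13C,C6H12O6,,C:6
valine,C5H11NO2,TBDMS;TBDMS,C:5;N:1
KIV,C5H8O3,methoxime;TBDMS,C:5
3HIB,C4H8O3,TBDMS;TBDMS,C:4
threonine,C4H9NO3,TBDMS;TBDMS;TBDMS,C:4;N:1
2KB,C4H6O3,methoxime;TBDMS,C:4
glutamate,C5H9NO4,TBDMS;TBDMS;TBDMS,N:1
propionylcarnitine,C10H19NO4,methyl_ester,C:3
citrate,C6H8O7,TBDMS;TBDMS;TBDMS;TBDMS,C:6
propionate,C3H6O2,3NPH,C:3
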