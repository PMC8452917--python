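patient_id,vessel,lesion_type,L_mm,D_mm,DS_percent,stent_name
P1,LAD,Bifurcation,28,3.5,60,Boston Scientific Synergy
P2,RCA,Tandem,14,4,60,Biosensors Biomatrix Neoflex
P2,RCA,Tandem,28,4,95,Biosensors Biomatrix Neoflex
P2,RCA,Tandem,32,3,80,Boston Scientific Synergy DES
P3,LAD,Focal,28,3,90,Neich Combo SDS
P3,LCX,Focal,31,2.25,75,Alvimedica Cre8
P4,LAD,Focal,18,2.5,80,Neich Combo SDS
P5,LAD,Focal,16,3,70,Boston Scientific Synergy DES
P6,LAD,Bifurcation,46,3,80,Alvimedica Cre8
P6,D2,Bifurcation,15,2.5,85,POBA with Kaneka Ikazuchi Zero Balloon
P6,LCX,Focal,46,2.5,95,Alvimedica Cre8
P7,LAD,Bifurcation,20,3,60,Alvimedica Cre8
P8,LAD,Focal,20,3,75,Alvimedica Cre8
P9,LAD,Focal,15,3.5,50,Abbott Vascular Xience Alpine
P10,LAD,Focal,19,3,60,MERIL Biomime DES
P11,RCA,Bifurcation,23,3.5,70,DESyne X2 (Elixir medical corporation)
P12,LAD,Bifurcation,48,2.5,81,Abbott Xience Xpedition DES
P13,RCA,Ostial,14,3.5,90,BIoFreedom DES
P14,LAD,Tandem,38,2.5,90,Bonston Scientific Synergy DES
P14,LAD,Tandem,12,3.5,75,Bonston Scientific Synergy DES
P15,LAD,Focal,38,3,93,Bonston Scientific Synergy DES
P16,LAD,Bifurcation,24,2.5,72,Bonston Scientific Synergy DES
P17,LAD,Bifurcation,23,3.5,75,Xience Sierra DES
P18,LAD,Tandem,30,2.75,83,Medtronic Resolute ONYX DES
P18,LAD,Tandem,30,2.25,75,Medtronic Resolute ONYX DES
P19,LCX,Ostial,20,3,80,Boston Scientific Agent DES
P19,LAD,Tandem,20,3,70,Bonston Scientific Synergy II DES
P19,LAD,Tandem,20,2.5,80,Bonston Scientific Synergy II DES
P20,LAD,Focal,38,3.5,80,Orbus COMBO DES
P20,LCX,Focal,12,2.25,90,Bonston Scientific Synergy II DES
P21,LAD,Ostial,28,3,70,Abbott Xience Sierra DES
P22,LAD,Bifurcation,18,2,80,Abbott Xience ALPINE DES
P23,RCA,Tandem,48,3,77,Bonston Scientific Synergy DES
P23,RCA,Tandem,28,3,77,Bonston Scientific Synergy DES
P24,LAD,Focal,38,2.5,70,Synergy DES
P25,LAD,Bifurcation,18,3.5,81,Abbott Xience Sierra DES
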