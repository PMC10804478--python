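case_id,age,sex,max_diameter,pathological_type,diagnosis,multiplicity
case01,60,M,29.9,CD,primary,multiple
case02,66,M,10,CD,recurrent,multiple
case03,52,F,10.9,CD,recurrent,single
case04,57,F,25.7,CD,primary,single
case05,57,F,25.2,PD,recurrent,multiple
case06,63,M,14.8,PD,recurrent,multiple
case07,56,M,11.9,CD,recurrent,single
case08,62,M,24.3,PD,primary,multiple
case09,57,M,24.3,CD,recurrent,multiple
case10,65,M,21.2,CD,recurrent,multiple
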