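# Predicted no-effect concentrations in soil used for PEC/PNEC screening.
substance,pnec_ug_kg,citation
nano-TiO2,1000,"soil PNEC for nano-TiO2, 1000 ug per kg soil"
CNT,176,"soil PNEC for carbon nanotubes, 176 ug per kg soil"
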