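name,population,prevalence,exposure_freq
Scotland,5222100,229,9.5
Northeast,2606625,193,9.8
Northwest,6935736,191,9.4
Yorkshire and Humber,5301252,109,10.9
Wales,3006430,146,9.5
East Midlands,4481431,160,12.1
West Midlands,5455179,152,11.1
East,5831845,152,13.3
London,7825177,115,14.5
Southeast,8523074,111,12.5
Southwest,5273726,118,11.6
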