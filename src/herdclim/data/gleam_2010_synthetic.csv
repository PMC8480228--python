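system,income_group,mt_ch4_2010
feedlot,high,1.051282051282051
feedlot,upper_middle,0.6
feedlot,lower_middle,0.3
feedlot,low,0.1
mixed,high,8.0
mixed,upper_middle,12.0
mixed,lower_middle,18.0
mixed,low,9.0
extensive,high,6.0
extensive,upper_middle,12.0
extensive,lower_middle,16.0
extensive,low,17.0
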