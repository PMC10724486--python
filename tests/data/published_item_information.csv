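item_id,max_info,theta_at_max,info_at_zero
EDANX27,4.15,0.1,3.92
EDANX53,6.64,-2.3,6.53
EDANX05,7.49,-2.3,7.33
EDANX12,4.31,0.3,3.09
EDANX55,3.83,0.7,2.30
EDANX01,6.03,2.0,3.81
EDANX02,4.22,1.1,3.26
EDANX33,4.92,1.3,4.75
EDANX08,1.93,1.7,1.82
EDANX47,1.38,-0.6,1.14
EDANX18,1.97,-0.4,1.68
EDANX26,2.11,-0.4,1.70
EDANX07,1.88,1.7,1.44
EDANX30,1.76,-1.5,1.72
EDANX46,2.98,-1.6,2.91
EDANX51,3.44,-1.0,2.61
EDANX54,2.14,-0.5,1.75
EDANX41,1.94,1.4,1.69
EDANX03,1.42,0.9,1.27
EDANX48,2.89,-1.6,2.50
EDANX09,4.67,-1.7,2.96
EDANX39,1.54,-0.1,1.53
EDANX40,1.88,1.5,1.73
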