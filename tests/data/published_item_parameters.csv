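item_id,a,b1,b2,b3,b4
EDANX27,4.05,-2.52,-1.12,0.12,1.21
EDANX53,5.16,-2.33,-1.13,0.06,1.34
EDANX05,5.47,-2.29,-1.17,0.05,1.46
EDANX12,4.13,-2.68,-0.84,0.33,1.66
EDANX55,3.88,-2.31,-0.50,0.71,1.95
EDANX01,4.90,-1.63,-0.30,0.93,2.01
EDANX02,4.08,-1.75,-0.27,1.04,2.07
EDANX33,4.37,-1.60,0.04,1.29,2.13
EDANX08,2.68,-1.55,0.10,1.58,2.63
EDANX47,2.28,-2.01,-0.54,1.06,3.21
EDANX18,2.76,-1.81,-0.37,1.06,2.66
EDANX26,2.86,-1.92,-0.42,0.98,2.58
EDANX07,2.62,-1.48,0.37,1.63,2.62
EDANX30,2.60,-2.87,-1.48,0.10,1.66
EDANX46,3.39,-2.48,-1.52,0.00,1.38
EDANX51,3.66,-2.08,-0.98,0.32,1.67
EDANX54,2.87,-1.98,-0.49,0.79,2.30
EDANX41,2.69,-1.72,0.24,1.39,2.66
EDANX03,2.30,-2.43,-0.49,0.89,2.23
EDANX48,3.32,-2.57,-1.59,-0.22,1.28
EDANX09,4.23,-2.42,-1.68,-0.33,1.13
EDANX39,2.37,-2.94,-1.67,-0.23,0.88
EDANX40,2.70,-1.55,0.22,1.57,3.21
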