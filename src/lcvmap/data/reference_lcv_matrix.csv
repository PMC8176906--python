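landcover,Flat land,Slope,Shoulder,Channel,Summit
Barren land,1.00,1.59,1.93,2.52,3.02
Developed,1.43,1.68,2.18,2.43,3.45
Agriculture,2.86,3.27,4.54,4.54,5.79
Grassland,4.20,4.79,5.96,6.38,7.98
Forest,5.63,5.96,7.64,8.23,9.41
Open water,5.88,6.64,8.14,8.39,10.00
Wetland,6.21,6.46,7.73,8.57,10.00
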