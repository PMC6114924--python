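# Approximate global historical series compiled from public statistics (rounded):
# H = world population (billion individuals); A = intensive agricultural land
# (arable + permanent crops, billion ha). Values are coarse (2-3 significant
# figures) and serve as the calibration window for the packaged baseline.
# units: year CE; H in billion individuals; A in billion ha
year,H,A
1960,3.03,1.36
1965,3.34,1.38
1970,3.70,1.40
1975,4.07,1.42
1980,4.46,1.44
1985,4.87,1.46
1990,5.33,1.48
1995,5.74,1.50
2000,6.14,1.52
2005,6.54,1.53
2010,6.96,1.55
2015,7.38,1.56
2016,7.46,1.56
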