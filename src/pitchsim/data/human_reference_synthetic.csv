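# Synthetic placeholder human reference curves (NOT authoritative data).
# The package compares model results against user-supplied reference curves;
# the published values are not redistributed here.  These rows are smooth
# synthetic stand-ins with the canonical qualitative shape (low thresholds up
# to the ~6th-8th lowest harmonic, then an order-of-magnitude rise; small
# positive pitch shifts growing with component shift) so that the similarity
# machinery can be exercised end to end.  Replace with digitized values for
# real comparisons.
experiment,condition,n_low,component_shift,nominal_f0,harmonic,ratio,ref_freq,value
A,sine,5,,,,,,0.4
A,sine,8,,,,,,1.0
A,sine,11,,,,,,4.0
A,sine,14,,,,,,7.0
A,sine,20,,,,,,9.0
A,sine,30,,,,,,10.0
A,random,5,,,,,,0.5
A,random,8,,,,,,1.5
A,random,11,,,,,,6.0
A,random,14,,,,,,12.0
A,random,20,,,,,,15.0
A,random,30,,,,,,16.0
C,low_harmonics,,0,,,,,0.0
C,low_harmonics,,8,,,,,1.6
C,low_harmonics,,16,,,,,3.2
C,low_harmonics,,24,,,,,4.8
C,mid_harmonics,,0,,,,,0.0
C,mid_harmonics,,8,,,,,0.8
C,mid_harmonics,,16,,,,,1.6
C,mid_harmonics,,24,,,,,2.4
C,high_harmonics,,0,,,,,0.0
C,high_harmonics,,8,,,,,0.3
C,high_harmonics,,16,,,,,0.6
C,high_harmonics,,24,,,,,0.9
E,pure,,,,,,80,0.8
E,pure,,,,,,160,0.4
E,pure,,,,,,320,0.2
E,transposed_4000,,,,,,80,4.0
E,transposed_4000,,,,,,160,5.0
E,transposed_4000,,,,,,320,7.0
E,transposed_6350,,,,,,80,4.5
E,transposed_6350,,,,,,160,5.5
E,transposed_6350,,,,,,320,8.0
E,transposed_10080,,,,,,80,5.0
E,transposed_10080,,,,,,160,6.0
E,transposed_10080,,,,,,320,9.0
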