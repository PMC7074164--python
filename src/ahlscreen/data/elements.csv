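# Isotope masses (Da) and natural abundances, IUPAC/CODATA values.
# One row per stable isotope; monoisotopic mass of an element = lightest isotope.
symbol,mass_number,mass,abundance
H,1,1.00782503207,0.999885
H,2,2.01410177785,0.000115
C,12,12.0,0.9893
C,13,13.00335483780,0.0107
N,14,14.00307400480,0.99636
N,15,15.00010889840,0.00364
O,16,15.99491461960,0.99757
O,17,16.99913170000,0.00038
O,18,17.99916100000,0.00205
Br,79,78.91833710000,0.5069
Br,81,80.91629060000,0.4931
Cl,35,34.96885268000,0.7576
Cl,37,36.96590259000,0.2424
S,32,31.97207100000,0.9499
S,33,32.97145876000,0.0075
S,34,33.96786690000,0.0425
S,36,35.96708076000,0.0001
P,31,30.97376163000,1.0
Na,23,22.98976928000,1.0
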