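# Hansen solubility parameters (MPa^0.5) and molar volumes (cm^3/mol):
# group-contribution values alongside COSMO cavity molar volumes.
# Hand-transcribed fixture; rows flagged ambiguous=1 admit more than one
# digit grouping in the source table and are excluded from consistency checks.
name,delta_t,delta_d,delta_p,delta_h,volume_fh,volume_cosmo,ambiguous
1-Propanol,24.5,16,6.8,17.4,75.2,52.64,0
2-Propanol,23.5,15.8,6.1,16.4,76.8,52.64,0
Acetic Acid,21.4,14.5,8,13.5,57.1,43.38,0
Acetone,20,15.5,10.4,7,74.0,49.92,0
Acetonitrile,24.4,15.3,18,6.1,52.6,38.41,0
Ethanol,26.5,15.8,8.8,19.4,58.5,40.33,0
Ethyl Acetate,18.1,15.8,5.3,7.2,98.5,68.14,0
Heptane,15.3,15.3,0,0,147.4,94.24,0
Hexane,14.9,14.9,0,0,131.6,82.11,0
Methanol,29.6,15.1,12.3,22.3,40.7,29.09,0
Methyl Acetate,18.7,15.5,7.2,7.6,79.7,56.13,0
Octanol,21,17,3.3,11.9,157.7,112.43,0
Water,47.8,15.6,16,42.3,18.0,15.2,0
2-Phenylacetamide,27.89,22.54,16.38,1.2,53.63,98.25,0
4-Methylphthalic anhydride,32.45,27.18,17.7,1.02,66.0,103.50,0
Aceclofenac,28.02,26.64,8.65,0.79,121.83,213.03,0
Acetaminophen,28.24,23.37,15.75,1.85,60.07,104.32,0
Acetylsalicylic acid,29.06,27.45,9.46,1.15,70.63,116.83,0
Atenolol,21.38,20.23,6.88,0.81,161.3,190.11,0
Atropine,27.78,26.84,7.11,1.03,103.07,195.58,0
Benzamide,35.25,25.7,24.05,1.76,36.53,86.76,0
Camphor,20.59,19.29,7.21,0.29,106.7,111.53,0
Capecitabine,24.65,22.83,9.26,0.83,205.94,225.47,0
Cefixime,30.18,27.82,11.67,0.86,190.56,264.81,0
Cephalexin,33.22,29.67,14.91,0.99,111.46,219.59,0
Cimetidine,27.39,22.85,15.1,0.61,162.3,176.03,0
Deferiprone,22.59,19.64,11.09,1.25,83.97,95.13,0
Flurbiprofen,24.56,23.03,8.49,0.86,82.33,164.03,0
Hydroquinone,43.64,31.25,29.89,5.87,23.84,75.95,0
Isoniazid,44.85,27.74,35.19,1.89,45.53,93.62,0
Lamotrigine,40.17,29.09,27.67,1.23,90.26,147.47,0
Meclofenamic acid,25.08,23.52,8.69,0.78,106.43,177.91,0
Pentoxifylline,23.76,21.49,10.14,0.41,87.2,184.38,1
Pindolol,23.46,21.41,9.55,0.92,129.37,177.38,0
p-Nitrobenzamide,36.71,26.8,25.05,1.28,55.33,104.25,0
Vinpocetine,32.28,31.84,5.28,0.43,108.8,235.71,0
Benzocaine,27.88,26.5,8.64,0.91,77.33,115.91,0
Borneol,19.15,18.54,4.68,0.93,106.67,115.13,0
Carvedilol,25.27,24.45,6.32,0.91,46.27,274.61,1
Ibuprofen,18.35,18.09,3.07,0.5,140.43,154.87,0
Isoborneol,20.06,19.48,4.72,0.94,105.67,114.97,0
Salicylic acid,30.52,25.83,16,2.94,41.2,90.21,1
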