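wavenumber,direction,assignment
1740,down,C=O stretching (lipids); ester C=O stretching vibration in phospholipids
1729,down,C=O stretching
1715,down,C=O stretching in thymine
1653,down,Amide I band
1640,down,Amide I band
1628,down,Amide I band
1622,down,Peak of nucleic acids due to the base carbonyl stretching and ring breathing mode
1570,down,Amide II band
1546,down,Amide II band
1512,down,In-plane CH bending vibration from the phenyl rings
1503,down,In-plane CH bending vibration from the phenyl rings
1485,down,C8-H coupled with a ring vibration of guanine; CH deformation
1240,down,Asymmetric PO2- stretching; phosphate band; amide III (C-N stretching mode of proteins)
1220,down,PO2- asymmetric stretching vibrations of nucleic acids; phosphate II in B-form DNA
1086,down,Symmetric phosphate stretching modes of PO2-
1062,down,C-O stretching in deoxyribose
1033,down,"C-C stretching in skeletal cis conformation, CH2OH stretching, C-O stretching coupled with C-O bending"
1018,down,"C-O stretching, C-C stretching, OCH bending in ring"
1005,down,Ring stretching vibrations mixed strongly with CH in-plane bending
993,down,"C-O stretching in ribose, C-C stretching"
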