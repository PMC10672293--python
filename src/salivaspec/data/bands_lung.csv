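wavenumber,direction,assignment
1740,up,C=O stretching (lipids); ester C=O stretching vibration in phospholipids
1722,up,C=O stretching vibration
1704,up,C=O stretching vibration
1660,down,Amide I band
1649,down,"Unordered random coils and turns of Amide I; C=O, C=N, N-H of adenine, thymine, guanine, cytosine"
1633,down,"C=C stretching uracyl, C=O stretching"
1620,down,Peak of nucleic acids due to the base carbonyl stretching and ring breathing mode
1565,down,C-C stretching (ring base)
1554,down,C-O stretching; predominantly alpha-sheet of Amide II
1544,down,Amide II band
1480,down,Polyethylene methylene deformation modes; Amide II band
1240,up,Asymmetric PO2- stretching; phosphate band; Amide III (C-N stretching mode of proteins)
1222,up,Phosphate stretching bands from phosphodiester groups of cellular nucleic acids
1094,up,Symmetric PO2- stretching
1078,up,Symmetric PO2- stretching; glycogen absorption due to C-O and C-C stretching and C-O-H deformation motions
1066,up,C-O stretching of phosphodiester and ribose
1020,up,C-O stretching associated with glycogen
1005,up,Ring stretching vibrations mixed strongly with CH in-plane bending
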