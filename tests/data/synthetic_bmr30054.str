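# SYNTHETIC stand-in for BMRB entry 30054 (Sp-PT duplex): not the deposition.
# Hand-built minimal NMR-STAR shift loop carrying only the published 31P
# shifts of the modified-site guanines G3/G17, for offline parser use.
data_synthetic_30054

save_assigned_chemical_shifts
   _Assigned_chem_shift_list.ID   1
   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Comp_index_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Atom_type
      _Atom_chem_shift.Atom_isotope_number
      _Atom_chem_shift.Val

      1   3  SSG  P  P  31  0.47
      2  17  SSG  P  P  31  0.54
   stop_
save_
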