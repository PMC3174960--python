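data_TRIP
_entry.id TRIP

_cell.entry_id TRIP
_cell.length_a 1
_cell.length_b 1
_cell.length_c 1
_cell.angle_alpha 90
_cell.angle_beta 90
_cell.angle_gamma 90

_symmetry.entry_id TRIP
_symmetry.space_group_name_H-M 'P 1'
_symmetry.Int_Tables_number 1

_refine.entry_id TRIP
_refine.ls_d_res_high 1.20
_refine.ls_R_factor_R_work 0.154

_reflns.entry_id TRIP
_reflns.d_resolution_high 1.20


loop_
_entity.id
_entity.type
A polymer

loop_
_entity_poly.entity_id
_entity_poly.type
_entity_poly.pdbx_strand_id
_entity_poly.pdbx_seq_one_letter_code
A polypeptide(L) A ?



loop_
_chem_comp.id
_chem_comp.type
ALA .
LEU .
SER .

loop_
_struct_asym.id
_struct_asym.entity_id
Axp A



loop_
_atom_type.symbol
C
N
O


loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.pdbx_formal_charge
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA Axp A . ? 0 0 0 1 15 ? 1 A 1
ATOM 2 C CA . ALA Axp A . ? 1.458 0 0 1 15 ? 1 A 1
ATOM 3 C C . ALA Axp A . ? 2.009 1.422 0 1 15 ? 1 A 1
ATOM 4 O O . ALA Axp A . ? 2.923 1.744 0.76 1 15 ? 1 A 1
ATOM 5 N N . SER Axp A . ? 1.436 2.274 -0.843 1 16 ? 2 A 1
ATOM 6 C CA . SER Axp A . ? 1.839 3.673 -0.912 1 16 ? 2 A 1
ATOM 7 C C . SER Axp A . ? 1.637 4.372 0.429 1 16 ? 2 A 1
ATOM 8 O O . SER Axp A . ? 2.515 5.093 0.903 1 16 ? 2 A 1
ATOM 9 N N . LEU Axp A . ? 0.482 4.137 1.044 1 17 ? 3 A 1
ATOM 10 C CA . LEU Axp A . ? 0.181 4.708 2.351 1 17 ? 3 A 1
ATOM 11 C C . LEU Axp A . ? 1.194 4.256 3.398 1 17 ? 3 A 1
ATOM 12 O O . LEU Axp A . ? 1.144 4.61 4.576 1 17 ? 3 A 1
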