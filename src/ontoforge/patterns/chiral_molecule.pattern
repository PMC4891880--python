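?chiralMolecule: INDIVIDUAL
BEGIN
ADD ?chiralMolecule instanceOf (Molecule and has_chemical_properties some Chirality)
END;
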