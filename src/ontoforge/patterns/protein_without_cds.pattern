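?protein: INDIVIDUAL
?cds: INDIVIDUAL = create(?protein.RENDERING+_CDS)
?transcript: INDIVIDUAL
BEGIN
ADD ?protein instanceOf Polypeptide,
ADD ?protein derives_from ?cds,
ADD ?cds instanceOf CDS,
ADD ?cds part_of ?transcript,
ADD ?transcript instanceOf Transcript
END;
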