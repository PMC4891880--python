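?histopathologyReport:INDIVIDUAL,
?finding:INDIVIDUAL,
?size:CONSTANT,
?number:CONSTANT
BEGIN
ADD ?histopathologyReport instanceOf HistopathologyReport,
ADD ?histopathologyReport hasFinding ?finding,
ADD ?histopathologyReport number ?number,
ADD ?histopathologyReport maxsize ?size
END;
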