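# State-level modality totals and bed requirement as published for planning.
# These exceed group-level recomputation from the packaged incidence and
# fraction tables (the published figures were derived at a finer site
# resolution that is not public); they are supplied as explicit overrides,
# never silently substituted for computed totals.
surgery: 74860
chemo: 117172
rt: 94808
beds: 2892
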