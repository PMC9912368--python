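qualification	isced_level
College or University degree	5
NVQ or HND or HNC or equivalent	5
Other professional qualifications eg: nursing, teaching	4
A levels/AS levels or equivalent	3
O levels/GCSEs or equivalent	2
CSEs or equivalent	2
None of the above	1
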