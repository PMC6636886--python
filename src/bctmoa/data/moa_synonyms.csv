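label,moa_id
self-efficacy,4
environmental context/resources,11
"memory, attention, and decision processes",10
attitude toward the behavior,17
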