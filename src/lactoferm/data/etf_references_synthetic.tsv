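ref_id	known_cluster
EtfB_lactate_awo0871_like	lactate_cluster
EtfB_lactate_melsdenii_like	lactate_cluster
EtfB_rbo_ckluyveri_like	rbo_cluster
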