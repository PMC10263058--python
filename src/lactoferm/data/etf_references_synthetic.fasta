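>EtfB_lactate_awo0871_like synthetic stand-in reference
QNVRNYLMIIKWTYLWYNLAHEVGEWAQNMPRGTDIIMFRPVDSKIPPKTQLWWVNDKWW
RDTWCACLFWNWDLFWQDWEGCRHLWFDVRPSKNEVSIWVNRLCRWYIQHRSQQWYYWWQ
>EtfB_lactate_melsdenii_like synthetic stand-in reference
QNDRNYLMIIKYTYLWYNLAHHVGECHQNRVRGTDIIMFRCFDSANEPKFQLWWVNDWWW
RDTWCQLLGCLWDTFYQDWEGCRHLWFHVSPSKVEHSIWVNRQCRWYDFHRWQQWYYWWY
>EtfB_rbo_ckluyveri_like synthetic stand-in reference
INKDKYGWSARAEMHNAGMIEYIEEFACCHHFASCVEYIRRLPHSLGGIKWDPDCCLAHI
QEFFWAGTEDHKHTVKTAQELNWQMEGYALMSMNAIFLHPKCKACCLVIEFACNKHRHAS
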