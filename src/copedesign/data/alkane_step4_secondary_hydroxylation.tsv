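enzyme	hexan-1-ol	2-methyl-1-propanol	dihydrofuran-2(3H)-one
1FZI	-46.861	-33.517	-29.305
6D7K	-49.145	-27.987	-11.258
6VK6	-44.197	-41.865	-26.201
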