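enzyme	tridecane-1-ol	2,6,10,14-tetramethylpentadecan-1-ol	cyclopentanol
1FZI	-110.404	-106.555	-28.650
1MHZ	-109.605	-146.983	-28.647
3B9N	-51.817	-112.476	-16.685
6D7K	-88.037	-58.433	-49.200
6VK6	-103.004	-132.869	-31.266
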