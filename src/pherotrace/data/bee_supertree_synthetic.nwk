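(('Colletes cunicularius',('Lasioglossum malachurum','Lasioglossum zephyrum')),('Osmia rufa',('Megachile rotundata',('Amegilla dawsoni',('Centris analis',('Apis mellifera',(('Bombus terrestris',('Bombus impatiens','Bombus hypnorum')),(('Melipona bicolor','Melipona scutellaris'),('Scaptotrigona depilis',('Friesella schrottkyi','Schwarziana quadripunctata'))))))))));
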