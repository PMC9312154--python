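ln0000	unlabeled
ln0001	irrelevant
ln0002	irrelevant
mi0000	related
mi0001	unlabeled
mi0002	unlabeled
mr0000	irrelevant
mr0001	unlabeled
mr0002	unlabeled
mr0003	related
mr0004	unlabeled
mr0005	related
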