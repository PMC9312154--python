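ln0000	related
ln0001	unlabeled
ln0002	unlabeled
ln0003	irrelevant
ln0004	unlabeled
ln0005	unlabeled
ln0006	unlabeled
ln0007	related
ln0008	irrelevant
ln0009	unlabeled
ln0010	unlabeled
ln0011	unlabeled
ln0012	unlabeled
ln0013	unlabeled
ln0014	irrelevant
ln0015	irrelevant
ln0016	unlabeled
ln0017	irrelevant
ln0018	unlabeled
ln0019	related
mi0000	unlabeled
mi0001	related
mi0002	irrelevant
mi0003	irrelevant
mi0004	unlabeled
mi0005	related
mi0006	irrelevant
mi0007	unlabeled
mi0008	irrelevant
mi0009	related
mi0010	unlabeled
mi0011	unlabeled
mi0012	irrelevant
mi0013	irrelevant
mi0014	unlabeled
mi0015	unlabeled
mi0016	unlabeled
mi0017	irrelevant
mi0018	unlabeled
mi0019	unlabeled
mr0000	irrelevant
mr0001	related
mr0002	irrelevant
mr0003	irrelevant
mr0004	related
mr0005	irrelevant
mr0006	irrelevant
mr0007	related
mr0008	irrelevant
mr0009	unlabeled
mr0010	unlabeled
mr0011	irrelevant
mr0012	unlabeled
mr0013	unlabeled
mr0014	irrelevant
mr0015	unlabeled
mr0016	unlabeled
mr0017	related
mr0018	unlabeled
mr0019	unlabeled
mr0020	unlabeled
mr0021	irrelevant
mr0022	unlabeled
mr0023	irrelevant
mr0024	irrelevant
mr0025	unlabeled
mr0026	irrelevant
mr0027	unlabeled
mr0028	irrelevant
mr0029	unlabeled
mr0030	unlabeled
mr0031	unlabeled
mr0032	unlabeled
mr0033	unlabeled
mr0034	unlabeled
mr0035	irrelevant
mr0036	irrelevant
mr0037	unlabeled
mr0038	unlabeled
mr0039	unlabeled
mr0040	unlabeled
mr0041	irrelevant
mr0042	unlabeled
mr0043	irrelevant
mr0044	irrelevant
mr0045	irrelevant
mr0046	unlabeled
mr0047	unlabeled
mr0048	related
mr0049	unlabeled
mr0050	unlabeled
mr0051	unlabeled
mr0052	unlabeled
mr0053	unlabeled
mr0054	irrelevant
mr0055	irrelevant
mr0056	unlabeled
mr0057	unlabeled
mr0058	irrelevant
mr0059	related
mr0060	unlabeled
mr0061	unlabeled
mr0062	unlabeled
mr0063	unlabeled
mr0064	related
mr0065	irrelevant
mr0066	related
mr0067	unlabeled
mr0068	unlabeled
mr0069	unlabeled
mr0070	unlabeled
mr0071	unlabeled
mr0072	unlabeled
mr0073	unlabeled
mr0074	unlabeled
mr0075	unlabeled
mr0076	unlabeled
mr0077	irrelevant
mr0078	unlabeled
mr0079	unlabeled
mr0080	irrelevant
mr0081	unlabeled
mr0082	related
mr0083	irrelevant
mr0084	unlabeled
mr0085	unlabeled
mr0086	unlabeled
mr0087	unlabeled
mr0088	irrelevant
mr0089	unlabeled
mr0090	unlabeled
mr0091	unlabeled
mr0092	unlabeled
mr0093	irrelevant
mr0094	unlabeled
mr0095	unlabeled
mr0096	unlabeled
mr0097	irrelevant
mr0098	unlabeled
mr0099	unlabeled
mr0100	irrelevant
mr0101	unlabeled
mr0102	unlabeled
mr0103	related
mr0104	irrelevant
mr0105	irrelevant
mr0106	irrelevant
mr0107	unlabeled
mr0108	unlabeled
mr0109	unlabeled
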