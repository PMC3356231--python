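# Controlled vocabulary for the 19 discrete morphological characters of flower,
# fruit, and leaf used in the composite-terminal simultaneous analysis.
# Shipped as reference vocabulary only; scoring specimens is out of scope.
character_id	character	state	state_label
1	Hastula shape	0	rounded
1	Hastula shape	1	triangular, apiculate
2	Degree of panicle branching	0	two orders
2	Degree of panicle branching	1	three orders
3	Inflorescence length	0	shorter than petioles
3	Inflorescence length	1	equal
3	Inflorescence length	2	longer than petioles
4	Petiole fiber density	0	scarce to moderate
4	Petiole fiber density	1	abundant
5	Abaxial leaf blade folds	0	glaucous
5	Abaxial leaf blade folds	1	cottony, mealy indumentum
6	Abaxial leaf blade cover	0	green
6	Abaxial leaf blade cover	1	silvery-gray
7	Leaf blade shape	0	nearly circular
7	Leaf blade shape	1	diamond
8	Leaf blade with waxy, glaucous bloom	0	absent
8	Leaf blade with waxy, glaucous bloom	1	present
9	Leaf blade surface	0	flat
9	Leaf blade surface	1	nearly flat, undulate
10	Leaf tips	0	drooping
10	Leaf tips	1	stiff
11	Lepidia density	0	absent
11	Lepidia density	1	incompletely covered
11	Lepidia density	2	completely covered
12	Rachillae tomentum	0	glabrous
12	Rachillae tomentum	1	velutinous
12	Rachillae tomentum	2	floccose, lanate
13	Rachillae viscosity	0	absent
13	Rachillae viscosity	1	present
14	Style - ovary ratio	0	equal
14	Style - ovary ratio	1	style longer
14	Style - ovary ratio	2	style shorter
15	Outer calyx venation	0	absent
15	Outer calyx venation	1	conspicuous
15	Outer calyx venation	2	present near opening with finer lines
16	Calyx indumentum	0	glabrous
16	Calyx indumentum	1	tomentose
16	Calyx indumentum	2	viscous
17	Fruit ridges	0	absent
17	Fruit ridges	1	present
18	Fruit shape	0	globose
18	Fruit shape	1	ellipsoid
18	Fruit shape	2	ovoid
18	Fruit shape	3	obovoid
18	Fruit shape	4	oblate
19	Fruit length	0	< 3 cm
19	Fruit length	1	> 3 cm
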