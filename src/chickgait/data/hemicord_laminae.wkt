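# synthetic schematic chick lumbar hemicord template (micrometres)
outline	POLYGON ((0 0, 700 0, 880 250, 900 450, 860 800, 750 1150, 550 1400, 320 1600, 0 1600, 0 0))
I	POLYGON ((320.0 1600.0, 435.0 1500.0, 0.0 1500.0, 0.0 1600.0, 320.0 1600.0))
II	POLYGON ((435.0 1500.0, 550.0 1400.0, 0.0 1400.0, 0.0 1500.0, 435.0 1500.0))
III	POLYGON ((550.0 1400.0, 630.0 1300.0, 0.0 1300.0, 0.0 1400.0, 550.0 1400.0))
IV	POLYGON ((630.0 1300.0, 750.0 1150.0, 0.0 1150.0, 0.0 1300.0, 630.0 1300.0))
V	POLYGON ((750.0 1150.0, 797.1 1000.0, 0.0 1000.0, 0.0 1150.0, 750.0 1150.0))
VI	POLYGON ((797.1 1000.0, 844.3 850.0, 0.0 850.0, 0.0 1000.0, 797.1 1000.0))
VII	POLYGON ((110.0 400.0, 110.0 850.0, 844.3 850.0, 860.0 800.0, 900.0 450.0, 895.0 400.0, 110.0 400.0))
VIII	POLYGON ((400.0 400.0, 400.0 0.0, 0.0 0.0, 0.0 400.0, 400.0 400.0))
IX	POLYGON ((410.0 400.0, 895.0 400.0, 880.0 250.0, 700.0 0.0, 410.0 0.0, 410.0 400.0))
X	POLYGON ((100.0 850.0, 100.0 400.0, 0.0 400.0, 0.0 850.0, 100.0 850.0))
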