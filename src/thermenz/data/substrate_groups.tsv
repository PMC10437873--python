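group	scheme	family
chitin	CAZY	GH5
chitin	CAZY	GH7
chitin	CAZY	GH8
chitin	CAZY	GH18
chitin	CAZY	GH19
chitin	CAZY	GH20
chitin	CAZY	GH46
chitin	CAZY	CBM5
peptidoglycan	CAZY	GH22
peptidoglycan	CAZY	GH23
peptidoglycan	CAZY	GH24
peptidoglycan	CAZY	GH25
peptidoglycan	CAZY	GH102
peptidoglycan	CAZY	GH103
peptidoglycan	CAZY	GH108
peptidoglycan	CAZY	CBM50
peptidoglycan	CAZY	CE4
peptidoglycan	MEROPS	S11
peptidoglycan	MEROPS	M23
peptidoglycan	MEROPS	S13
peptidoglycan	MEROPS	S66
peptidoglycan	MEROPS	M15
peptidoglycan	MEROPS	M74
peptidoglycan	MEROPS	M14
peptidoglycan	MEROPS	C51
starch_glycogen	CAZY	GH3
starch_glycogen	CAZY	GH13
starch_glycogen	CAZY	GH14
starch_glycogen	CAZY	GH15
starch_glycogen	CAZY	GH27
starch_glycogen	CAZY	GH31
starch_glycogen	CAZY	GH38
starch_glycogen	CAZY	GH57
starch_glycogen	CAZY	GH72
starch_glycogen	CAZY	GH77
starch_glycogen	CAZY	GH89
starch_glycogen	CAZY	GH119
starch_glycogen	CAZY	GH126
starch_glycogen	CAZY	AA13
starch_glycogen	CAZY	GT35
starch_glycogen	CAZY	CBM20
trehalose	CAZY	GH37
trehalose	CAZY	GH65
xylan	CAZY	GH3
xylan	CAZY	GH5
xylan	CAZY	GH7
xylan	CAZY	GH8
xylan	CAZY	GH10
xylan	CAZY	GH11
xylan	CAZY	GH43
xylan	CAZY	GH67
cellulose	CAZY	GH1
cellulose	CAZY	GH3
cellulose	CAZY	GH5
cellulose	CAZY	GH8
cellulose	CAZY	GH9
cellulose	CAZY	GH10
cellulose	CAZY	GH16
cellulose	CAZY	GH43
cellulose	CAZY	GH51
cellulose	CAZY	GH74
cellulose	CAZY	GH116
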