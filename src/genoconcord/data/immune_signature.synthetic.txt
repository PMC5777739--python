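>immune_signature_synthetic
SYNIMM001
SYNIMM002
SYNIMM003
SYNIMM004
SYNIMM005
SYNIMM006
SYNIMM007
SYNIMM008
SYNIMM009
SYNIMM010
SYNIMM011
SYNIMM012
SYNIMM013
SYNIMM014
SYNIMM015
SYNIMM016
SYNIMM017
SYNIMM018
SYNIMM019
SYNIMM020
SYNIMM021
SYNIMM022
SYNIMM023
SYNIMM024
SYNIMM025
SYNIMM026
SYNIMM027
SYNIMM028
SYNIMM029
SYNIMM030
SYNIMM031
SYNIMM032
SYNIMM033
SYNIMM034
SYNIMM035
SYNIMM036
SYNIMM037
SYNIMM038
SYNIMM039
SYNIMM040
SYNIMM041
SYNIMM042
SYNIMM043
SYNIMM044
SYNIMM045
SYNIMM046
SYNIMM047
SYNIMM048
SYNIMM049
SYNIMM050
SYNIMM051
SYNIMM052
SYNIMM053
SYNIMM054
SYNIMM055
SYNIMM056
SYNIMM057
SYNIMM058
SYNIMM059
SYNIMM060
SYNIMM061
SYNIMM062
SYNIMM063
SYNIMM064
SYNIMM065
SYNIMM066
SYNIMM067
SYNIMM068
SYNIMM069
SYNIMM070
SYNIMM071
SYNIMM072
SYNIMM073
SYNIMM074
SYNIMM075
SYNIMM076
SYNIMM077
SYNIMM078
SYNIMM079
SYNIMM080
SYNIMM081
SYNIMM082
SYNIMM083
SYNIMM084
SYNIMM085
SYNIMM086
SYNIMM087
SYNIMM088
SYNIMM089
SYNIMM090
SYNIMM091
SYNIMM092
SYNIMM093
SYNIMM094
SYNIMM095
SYNIMM096
SYNIMM097
SYNIMM098
SYNIMM099
SYNIMM100
SYNIMM101
SYNIMM102
SYNIMM103
SYNIMM104
SYNIMM105
SYNIMM106
SYNIMM107
SYNIMM108
SYNIMM109
SYNIMM110
SYNIMM111
SYNIMM112
SYNIMM113
SYNIMM114
SYNIMM115
SYNIMM116
SYNIMM117
SYNIMM118
SYNIMM119
SYNIMM120
SYNIMM121
SYNIMM122
SYNIMM123
SYNIMM124
SYNIMM125
SYNIMM126
SYNIMM127
SYNIMM128
SYNIMM129
SYNIMM130
SYNIMM131
SYNIMM132
SYNIMM133
SYNIMM134
SYNIMM135
SYNIMM136
SYNIMM137
SYNIMM138
SYNIMM139
SYNIMM140
SYNIMM141
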