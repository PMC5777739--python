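>stromal_signature_synthetic
SYNSTRO001
SYNSTRO002
SYNSTRO003
SYNSTRO004
SYNSTRO005
SYNSTRO006
SYNSTRO007
SYNSTRO008
SYNSTRO009
SYNSTRO010
SYNSTRO011
SYNSTRO012
SYNSTRO013
SYNSTRO014
SYNSTRO015
SYNSTRO016
SYNSTRO017
SYNSTRO018
SYNSTRO019
SYNSTRO020
SYNSTRO021
SYNSTRO022
SYNSTRO023
SYNSTRO024
SYNSTRO025
SYNSTRO026
SYNSTRO027
SYNSTRO028
SYNSTRO029
SYNSTRO030
SYNSTRO031
SYNSTRO032
SYNSTRO033
SYNSTRO034
SYNSTRO035
SYNSTRO036
SYNSTRO037
SYNSTRO038
SYNSTRO039
SYNSTRO040
SYNSTRO041
SYNSTRO042
SYNSTRO043
SYNSTRO044
SYNSTRO045
SYNSTRO046
SYNSTRO047
SYNSTRO048
SYNSTRO049
SYNSTRO050
SYNSTRO051
SYNSTRO052
SYNSTRO053
SYNSTRO054
SYNSTRO055
SYNSTRO056
SYNSTRO057
SYNSTRO058
SYNSTRO059
SYNSTRO060
SYNSTRO061
SYNSTRO062
SYNSTRO063
SYNSTRO064
SYNSTRO065
SYNSTRO066
SYNSTRO067
SYNSTRO068
SYNSTRO069
SYNSTRO070
SYNSTRO071
SYNSTRO072
SYNSTRO073
SYNSTRO074
SYNSTRO075
SYNSTRO076
SYNSTRO077
SYNSTRO078
SYNSTRO079
SYNSTRO080
SYNSTRO081
SYNSTRO082
SYNSTRO083
SYNSTRO084
SYNSTRO085
SYNSTRO086
SYNSTRO087
SYNSTRO088
SYNSTRO089
SYNSTRO090
SYNSTRO091
SYNSTRO092
SYNSTRO093
SYNSTRO094
SYNSTRO095
SYNSTRO096
SYNSTRO097
SYNSTRO098
SYNSTRO099
SYNSTRO100
SYNSTRO101
SYNSTRO102
SYNSTRO103
SYNSTRO104
SYNSTRO105
SYNSTRO106
SYNSTRO107
SYNSTRO108
SYNSTRO109
SYNSTRO110
SYNSTRO111
SYNSTRO112
SYNSTRO113
SYNSTRO114
SYNSTRO115
SYNSTRO116
SYNSTRO117
SYNSTRO118
SYNSTRO119
SYNSTRO120
SYNSTRO121
SYNSTRO122
SYNSTRO123
SYNSTRO124
SYNSTRO125
SYNSTRO126
SYNSTRO127
SYNSTRO128
SYNSTRO129
SYNSTRO130
SYNSTRO131
SYNSTRO132
SYNSTRO133
SYNSTRO134
SYNSTRO135
SYNSTRO136
SYNSTRO137
SYNSTRO138
SYNSTRO139
SYNSTRO140
SYNSTRO141
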