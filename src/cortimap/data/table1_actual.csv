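height,sector,group,n,mean,ci_low,ci_high
total,medial,young_men,12,5.7,5.4,6.0
total,medial,young_women,19,5.1,4.7,5.5
total,medial,elderly_men,29,5.7,5.5,5.9
total,medial,elderly_women,25,5.6,5.5,5.8
total,lateral,young_men,12,6.2,5.5,6.8
total,lateral,young_women,19,4.7,4.5,5.0
total,lateral,elderly_men,29,5.6,5.4,5.8
total,lateral,elderly_women,25,5.4,5.2,5.6
total,anterior,young_men,12,10.2,8.9,11.5
total,anterior,young_women,19,8.2,7.7,8.8
total,anterior,elderly_men,29,7.9,7.5,8.2
total,anterior,elderly_women,25,7.3,7.0,7.6
total,posterior,young_men,12,6.4,5.9,6.8
total,posterior,young_women,19,5.8,5.3,6.3
total,posterior,elderly_men,29,5.3,5.2,5.5
total,posterior,elderly_women,25,5.0,4.8,5.1
proximal,medial,young_men,12,5.1,4.8,5.3
proximal,medial,young_women,19,4.6,4.3,4.9
proximal,medial,elderly_men,29,5.6,5.4,5.8
proximal,medial,elderly_women,25,5.5,5.3,5.7
proximal,lateral,young_men,12,5.5,4.9,6.1
proximal,lateral,young_women,19,4.2,4.0,4.4
proximal,lateral,elderly_men,29,5.5,5.3,5.7
proximal,lateral,elderly_women,25,5.3,5.0,5.6
proximal,anterior,young_men,12,8.9,7.4,10.3
proximal,anterior,young_women,19,7.3,6.7,8.0
proximal,anterior,elderly_men,29,7.3,7.0,7.7
proximal,anterior,elderly_women,25,7.1,6.8,7.4
proximal,posterior,young_men,12,6.2,5.7,6.7
proximal,posterior,young_women,19,5.4,4.9,5.8
proximal,posterior,elderly_men,29,5.3,5.1,5.4
proximal,posterior,elderly_women,25,5.1,4.9,5.3
central,medial,young_men,12,5.9,5.4,6.4
central,medial,young_women,19,5.3,4.8,5.8
central,medial,elderly_men,29,5.7,5.4,6.0
central,medial,elderly_women,25,5.7,5.4,5.9
central,lateral,young_men,12,6.6,5.7,7.5
central,lateral,young_women,19,5.1,4.6,5.5
central,lateral,elderly_men,29,5.4,4.9,5.8
central,lateral,elderly_women,25,5.4,5.1,5.7
central,anterior,young_men,12,11.3,10.0,12.6
central,anterior,young_women,19,9.3,8.6,10.0
central,anterior,elderly_men,29,8.3,7.8,8.8
central,anterior,elderly_women,25,7.2,6.5,7.9
central,posterior,young_men,12,6.7,6.2,7.2
central,posterior,young_women,19,6.2,5.6,6.7
central,posterior,elderly_men,29,5.3,5.1,5.5
central,posterior,elderly_women,25,4.8,4.7,4.9
distal,medial,young_men,12,6.3,5.9,6.8
distal,medial,young_women,19,5.9,5.3,6.5
distal,medial,elderly_men,29,6.1,5.8,6.4
distal,medial,elderly_women,25,5.9,5.7,6.1
distal,lateral,young_men,12,6.7,5.9,7.5
distal,lateral,young_women,19,5.2,4.8,5.6
distal,lateral,elderly_men,29,5.9,5.5,6.3
distal,lateral,elderly_women,25,5.6,5.3,6.0
distal,anterior,young_men,12,11.0,9.6,12.3
distal,anterior,young_women,19,8.4,7.8,9.0
distal,anterior,elderly_men,29,8.9,8.3,9.5
distal,anterior,elderly_women,25,7.6,7.2,8.1
distal,posterior,young_men,12,6.2,5.7,6.7
distal,posterior,young_women,19,6.0,5.5,6.6
distal,posterior,elderly_men,29,5.6,5.3,5.8
distal,posterior,elderly_women,25,4.8,4.7,4.9
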