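height,sector,group,n,mean,ci_low,ci_high
total,medial,young_men,12,15.7,14.6,16.7
total,medial,young_women,19,15.9,14.4,17.3
total,medial,elderly_men,29,17.3,16.7,18.0
total,medial,elderly_women,25,18.1,17.5,18.7
total,lateral,young_men,12,17.0,15.0,19.0
total,lateral,young_women,19,14.7,13.8,15.5
total,lateral,elderly_men,29,17.0,16.3,17.7
total,lateral,elderly_women,25,17.4,16.6,18.2
total,anterior,young_men,12,28.1,24.6,31.7
total,anterior,young_women,19,25.5,23.6,27.4
total,anterior,elderly_men,29,23.8,22.7,25.0
total,anterior,elderly_women,25,23.5,22.5,24.5
total,posterior,young_men,12,17.5,16.5,18.5
total,posterior,young_women,19,18.0,16.3,19.8
total,posterior,elderly_men,29,16.1,15.7,16.6
total,posterior,elderly_women,25,16.0,15.5,16.5
proximal,medial,young_men,12,14.0,13.1,14.9
proximal,medial,young_women,19,14.1,13.2,15.1
proximal,medial,elderly_men,29,16.9,16.2,17.6
proximal,medial,elderly_women,25,17.9,17.1,18.6
proximal,lateral,young_men,12,15.1,13.3,17.0
proximal,lateral,young_women,19,12.8,12.3,13.4
proximal,lateral,elderly_men,29,16.7,16.1,17.4
proximal,lateral,elderly_women,25,17.1,16.2,18.0
proximal,anterior,young_men,12,24.5,20.5,28.5
proximal,anterior,young_women,19,22.7,20.7,24.7
proximal,anterior,elderly_men,29,22.3,21.1,23.4
proximal,anterior,elderly_women,25,22.9,21.8,23.9
proximal,posterior,young_men,12,17.1,16.0,18.2
proximal,posterior,young_women,19,16.7,15.1,18.3
proximal,posterior,elderly_men,29,16.0,15.4,16.5
proximal,posterior,elderly_women,25,16.4,15.6,17.2
central,medial,young_men,12,16.3,14.5,18.1
central,medial,young_women,19,16.3,14.6,18.0
central,medial,elderly_men,29,17.4,16.4,18.4
central,medial,elderly_women,25,18.2,17.4,19.1
central,lateral,young_men,12,18.3,15.7,20.8
central,lateral,young_women,19,15.6,14.1,17.1
central,lateral,elderly_men,29,16.2,14.8,17.6
central,lateral,elderly_women,25,17.4,16.4,18.4
central,anterior,young_men,12,31.1,27.6,34.7
central,anterior,young_women,19,28.8,26.4,31.2
central,anterior,elderly_men,29,25.2,23.7,26.7
central,anterior,elderly_women,25,23.7,22.5,24.9
central,posterior,young_men,12,18.4,17.3,19.6
central,posterior,young_women,19,19.1,17.1,21.2
central,posterior,elderly_men,29,16.1,15.5,16.6
central,posterior,elderly_women,25,15.4,15.0,15.9
distal,medial,young_men,12,17.5,16.1,18.9
distal,medial,young_women,19,18.3,16.2,20.4
distal,medial,elderly_men,29,18.6,17.7,19.4
distal,medial,elderly_women,25,18.9,18.2,19.5
distal,lateral,young_men,12,18.4,16.2,20.6
distal,lateral,young_women,19,16.1,14.9,17.3
distal,lateral,elderly_men,29,17.8,16.7,19.0
distal,lateral,elderly_women,25,18.1,16.9,19.3
distal,anterior,young_men,12,30.2,26.5,34.0
distal,anterior,young_women,19,26.0,24.0,28.0
distal,anterior,elderly_men,29,26.8,25.1,28.6
distal,anterior,elderly_women,25,24.6,23.1,26.1
distal,posterior,young_men,12,17.1,15.9,18.4
distal,posterior,young_women,19,18.7,16.8,20.7
distal,posterior,elderly_men,29,16.8,16.2,17.5
distal,posterior,elderly_women,25,15.6,15.1,16.0
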