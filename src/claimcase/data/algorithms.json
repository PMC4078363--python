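[
 {
  "algorithm_id": "h1_ever",
  "dsl": "1H",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_er1",
  "dsl": "1H | 1E",
  "age_subset": null
 },
 {
  "algorithm_id": "p1_ever",
  "dsl": "1P",
  "age_subset": null
 },
 {
  "algorithm_id": "p1_spec_ever",
  "dsl": "1P(spec>=1)",
  "age_subset": null
 },
 {
  "algorithm_id": "p2_any_1y",
  "dsl": "2P/1y",
  "age_subset": null
 },
 {
  "algorithm_id": "p2_any_2y",
  "dsl": "2P/2y",
  "age_subset": null
 },
 {
  "algorithm_id": "p2_any_3y",
  "dsl": "2P/3y",
  "age_subset": null
 },
 {
  "algorithm_id": "p3_any_1y",
  "dsl": "3P/1y",
  "age_subset": null
 },
 {
  "algorithm_id": "p3_any_2y",
  "dsl": "3P/2y",
  "age_subset": null
 },
 {
  "algorithm_id": "p3_any_3y",
  "dsl": "3P/3y",
  "age_subset": null
 },
 {
  "algorithm_id": "p2_spec_1y",
  "dsl": "2P(spec>=1)/1y",
  "age_subset": null
 },
 {
  "algorithm_id": "p2_spec_2y",
  "dsl": "2P(spec>=1)/2y",
  "age_subset": null
 },
 {
  "algorithm_id": "p2_spec_3y",
  "dsl": "2P(spec>=1)/3y",
  "age_subset": null
 },
 {
  "algorithm_id": "p3_spec_1y",
  "dsl": "3P(spec>=1)/1y",
  "age_subset": null
 },
 {
  "algorithm_id": "p3_spec_2y",
  "dsl": "3P(spec>=1)/2y",
  "age_subset": null
 },
 {
  "algorithm_id": "p3_spec_3y",
  "dsl": "3P(spec>=1)/3y",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_spec_1y",
  "dsl": "1H | 2P(spec>=1)/1y",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_spec_2y",
  "dsl": "1H | 2P(spec>=1)/2y",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_spec_3y",
  "dsl": "1H | 2P(spec>=1)/3y",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p3_spec_1y",
  "dsl": "1H | 3P(spec>=1)/1y",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p3_spec_2y",
  "dsl": "1H | 3P(spec>=1)/2y",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p3_spec_3y",
  "dsl": "1H | 3P(spec>=1)/3y",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_gap8w_2y",
  "dsl": "1H | 2P(gap>=56d)/2y",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_gap8w_2y_exAB",
  "dsl": "1H | 2P(gap>=56d)/2y excl(A,B)",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_gap8w_3y_exAB",
  "dsl": "1H | 2P(gap>=56d)/3y excl(A,B)",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_gap8w_4y_exAB",
  "dsl": "1H | 2P(gap>=56d)/4y excl(A,B)",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_gap8w_5y_exAB",
  "dsl": "1H | 2P(gap>=56d)/5y excl(A,B)",
  "age_subset": null
 },
 {
  "algorithm_id": "h1_or_p2_gap8w_2y_exA",
  "dsl": "1H | 2P(gap>=56d)/2y excl(A)",
  "age_subset": null
 },
 {
  "algorithm_id": "p1_rx_ever",
  "dsl": "1P(rx>=1)",
  "age_subset": 65
 },
 {
  "algorithm_id": "p2_rx_ever",
  "dsl": "2P(rx>=1)",
  "age_subset": 65
 },
 {
  "algorithm_id": "p2_gap60_rx_ever",
  "dsl": "2P(gap>=60d,rx>=1)",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p2_rx_1y",
  "dsl": "1H | 2P(rx>=1)/1y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p2_rx_2y",
  "dsl": "1H | 2P(rx>=1)/2y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p2_rx_3y",
  "dsl": "1H | 2P(rx>=1)/3y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p2_spec_rx_1y",
  "dsl": "1H | 2P(spec>=1,rx>=1)/1y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p2_spec_rx_2y",
  "dsl": "1H | 2P(spec>=1,rx>=1)/2y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p2_spec_rx_3y",
  "dsl": "1H | 2P(spec>=1,rx>=1)/3y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p3_rx_1y",
  "dsl": "1H | 3P(rx>=1)/1y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p3_rx_2y",
  "dsl": "1H | 3P(rx>=1)/2y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p3_rx_3y",
  "dsl": "1H | 3P(rx>=1)/3y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p3_spec_rx_1y",
  "dsl": "1H | 3P(spec>=1,rx>=1)/1y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p3_spec_rx_2y",
  "dsl": "1H | 3P(spec>=1,rx>=1)/2y",
  "age_subset": 65
 },
 {
  "algorithm_id": "h1_or_p3_spec_rx_3y",
  "dsl": "1H | 3P(spec>=1,rx>=1)/3y",
  "age_subset": 65
 }
]
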