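channel,compartment,control_mean_mm2,treated_mean_mm2,n_control,n_treated,percent_change,ci_low,ci_high
edu,proliferating,326.8900387,174.8711237,2,2,46.50460309,,
protein,proliferating,362.7633542,86.0778837,2,2,76.27161544,,
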